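"""Genotype panel container and GeneNetwork-style ``.geno`` dialect I/O.

The dialect: lines starting with ``@`` carry key:value metadata, lines
starting with ``#`` are comments, then one tab-delimited header row
(``Chr  Locus  cM  Mb  <strain...>``) followed by one row per marker with
single-letter allele codes per strain. ``B`` and ``D`` are the two parental
homozygotes; ``H``/``U`` (heterozygote / unknown) load as missing, since a
fully inbred panel carries no heterozygous calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -128  # sentinel in the coded matrix

_CODE_TO_INT = {"B": 1, "D": -1}


@dataclass
class GenotypePanel:
    """Strain x marker homozygous allele matrix with a marker map.

    ``markers`` columns: chrom (str), locus (str), cm (float), mb (float),
    sorted by (chrom, cm). ``calls`` is an int8 matrix of shape
    (n_markers, n_strains) coded B=+1, D=-1, missing=MISSING.
    """

    markers: pd.DataFrame
    strains: list[str]
    calls: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.markers), len(self.strains)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.strains)} strains"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if not grp["cm"].is_monotonic_increasing:
                raise ValueError(f"markers on chromosome {chrom} not sorted by cM")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.markers["chrom"].to_numpy() == chrom)

    def subset_strains(self, names: list[str]) -> "GenotypePanel":
        idx = [self.strains.index(n) for n in names]
        return GenotypePanel(
            self.markers.reset_index(drop=True), list(names),
            self.calls[:, idx], dict(self.meta),
        )

    def allele_codes(self) -> np.ndarray:
        """Float matrix with missing calls as NaN (markers x strains)."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out


def read_geno(path: str | Path) -> GenotypePanel:
    """Parse a ``.geno`` dialect file into a :class:`GenotypePanel`."""
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows = []
    calls = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("@"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            chrom, locus, cm, mb = parts[0], parts[1], float(parts[2]), float(parts[3])
            rows.append((chrom, locus, cm, mb))
            coded = [_CODE_TO_INT.get(c.strip(), MISSING) for c in parts[4:]]
            calls.append(coded)
    if header is None:
        raise ValueError(f"{path}: no header row found")
    strains = header[4:]
    markers = pd.DataFrame(rows, columns=["chrom", "locus", "cm", "mb"])
    matrix = np.array(calls, dtype=np.int8).reshape(len(rows), len(strains))
    return GenotypePanel(markers, strains, matrix, meta)


def write_geno(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel in the ``.geno`` dialect (codes B/D, missing as U)."""
    int_to_code = {1: "B", -1: "D", MISSING: "U"}
    with open(path, "w") as fh:
        for key, value in panel.meta.items():
            fh.write(f"@{key}:{value}\n")
        fh.write("#spectroqtl genotype panel\n")
        fh.write("Chr\tLocus\tcM\tMb\t" + "\t".join(panel.strains) + "\n")
        for i, row in panel.markers.iterrows():
            codes = "\t".join(int_to_code[int(c)] for c in panel.calls[i])
            fh.write(
                f"{row['chrom']}\t{row['locus']}\t{row['cm']:g}\t{row['mb']:g}\t{codes}\n"
            )
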