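"""Band integration above a local linear baseline and the per-tissue trait
menu (composite areas and band-area ratios).

Each named band is integrated border-to-border as the signed trapezoidal
area between the spectrum and the straight line joining its values at the
two borders (endpoint-anchored baseline, no clipping of negative lobes).
Borders falling between grid points use linearly interpolated endpoint
values. This construction is linear in the spectrum and invariant under
adding a constant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    UndefinedRatioError,
    UndefinedTraitError,
    UnknownTissueError,
)
from .spectrum import GRID_MAX, GRID_MIN, Spectrum

_BAND_RE = re.compile(r"A\w+")


@dataclass(frozen=True)
class BandDefinition:
    """A named integration window for one tissue."""

    name: str
    lower: float
    upper: float
    tissue: str

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower border must be < upper")
        if self.lower < GRID_MIN or self.upper > GRID_MAX:
            raise ValueError(f"{self.name}: borders outside [{GRID_MIN:g}, {GRID_MAX:g}]")


class BandRegistry:
    """Per-tissue band windows plus composite and ratio trait definitions.

    Loaded from a versioned TSV shipped with the package so the definitions
    live in exactly one place.
    """

    #: trait name -> composite name; emitted only if the tissue defines it
    COMPOSITE_TRAITS = {
        "total_fat": "A_FAT",
        "saturated_fat": "A_SATF",
        "unsaturated_fat": "A_UNSATF",
        "collagen": "A_COL",
        "glycogen": "A_GLYC",
    }
    RATIO_TRAITS = (
        "saturated_to_unsaturated_fat_ratio",
        "acyl_chain_length",
        "collagen_integrity",
        "lipid_to_protein_ratio",
    )

    def __init__(self, table: pd.DataFrame):
        self.bands: dict[str, dict[str, BandDefinition]] = {}
        self.composites: dict[str, dict[str, list[str]]] = {}
        self.ratios: dict[str, dict[str, tuple[list[str], list[str]]]] = {}
        for _, row in table.iterrows():
            tissue, kind, name, definition = (
                row["tissue"], row["kind"], row["name"], row["definition"],
            )
            if kind == "band":
                lo, hi = (float(x) for x in definition.split(":"))
                self.bands.setdefault(tissue, {})[name] = BandDefinition(name, lo, hi, tissue)
            elif kind == "composite":
                self.composites.setdefault(tissue, {})[name] = _BAND_RE.findall(definition)
            elif kind == "ratio":
                num, _, den = definition.partition("/")
                self.ratios.setdefault(tissue, {})[name] = (
                    _BAND_RE.findall(num), _BAND_RE.findall(den),
                )
            else:
                raise ValueError(f"unknown registry row kind {kind!r}")

    @classmethod
    def default(cls) -> "BandRegistry":
        with resources.files("spectroqtl.data").joinpath("band_registry.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t"))

    @classmethod
    def from_file(cls, path: str | Path) -> "BandRegistry":
        return cls(pd.read_csv(path, sep="\t"))

    def tissues(self) -> list[str]:
        return list(self.bands)

    def band(self, tissue: str, name: str) -> BandDefinition:
        if tissue not in self.bands:
            raise UnknownTissueError(f"unknown tissue {tissue!r}")
        try:
            return self.bands[tissue][name]
        except KeyError:
            raise UndefinedTraitError(f"band {name!r} not defined for {tissue}") from None

    def trait_names(self, tissue: str) -> list[str]:
        """The trait menu for one tissue, in a fixed report order."""
        if tissue not in self.bands:
            raise UnknownTissueError(f"unknown tissue {tissue!r}")
        names = [
            t for t, comp in self.COMPOSITE_TRAITS.items()
            if comp in self.composites.get(tissue, {})
        ]
        names += [t for t in self.RATIO_TRAITS if t in self.ratios.get(tissue, {})]
        return names


_default_registry: BandRegistry | None = None


def default_registry() -> BandRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = BandRegistry.default()
    return _default_registry


# ---------------------------------------------------------------------------
# integration

def band_area(s: Spectrum, band: BandDefinition) -> float:
    """Signed trapezoidal integral of (absorbance - endpoint baseline).

    The baseline is the straight line joining the spectrum's (interpolated)
    values at the two borders; the integral runs border-to-border.
    """
    if band.lower < s.wavenumbers[0] or band.upper > s.wavenumbers[-1]:
        raise CoverageError(
            f"band {band.name} [{band.lower}, {band.upper}] outside spectrum coverage"
        )
    inner = (s.wavenumbers > band.lower) & (s.wavenumbers < band.upper)
    x = np.concatenate([[band.lower], s.wavenumbers[inner], [band.upper]])
    y_lo = s.value_at(band.lower)
    y_hi = s.value_at(band.upper)
    y = np.concatenate([[y_lo], s.absorbance[inner], [y_hi]])
    raw = float(np.trapezoid(y, x))
    baseline = 0.5 * (y_lo + y_hi) * (band.upper - band.lower)
    return raw - baseline


def composite_area(
    s: Spectrum, tissue: str, name: str, registry: BandRegistry | None = None
) -> float:
    """Sum of member band areas of a named composite for one tissue."""
    reg = registry or default_registry()
    if tissue not in reg.bands:
        raise UnknownTissueError(f"unknown tissue {tissue!r}")
    members = reg.composites.get(tissue, {}).get(name)
    if members is None:
        raise UndefinedTraitError(f"composite {name!r} not defined for {tissue}")
    return sum(band_area(s, reg.band(tissue, m)) for m in members)


def ratio_trait(
    s: Spectrum, tissue: str, name: str, registry: BandRegistry | None = None
) -> float:
    """A band-area ratio trait (dimensionless)."""
    reg = registry or default_registry()
    if tissue not in reg.bands:
        raise UnknownTissueError(f"unknown tissue {tissue!r}")
    parts = reg.ratios.get(tissue, {}).get(name)
    if parts is None:
        raise UndefinedTraitError(f"ratio {name!r} not defined for {tissue}")
    num_members, den_members = parts
    num = sum(band_area(s, reg.band(tissue, m)) for m in num_members)
    den = sum(band_area(s, reg.band(tissue, m)) for m in den_members)
    if den == 0.0:
        raise UndefinedRatioError(
            f"{name}: zero denominator for {s.sample_id}", sample_id=s.sample_id
        )
    return num / den


def extract_traits(
    s: Spectrum, tissue: str, registry: BandRegistry | None = None
) -> dict[str, float]:
    """Compute the full trait menu for one tissue from one spectrum."""
    reg = registry or default_registry()
    out: dict[str, float] = {}
    for trait in reg.trait_names(tissue):
        if trait in reg.RATIO_TRAITS:
            out[trait] = ratio_trait(s, tissue, trait, reg)
        else:
            out[trait] = composite_area(s, tissue, reg.COMPOSITE_TRAITS[trait], reg)
    return out
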