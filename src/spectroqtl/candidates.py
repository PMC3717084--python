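"""Candidate-gene filter cascade over a user-supplied annotation table.

The cascade is a sequence of pure boolean predicates per gene: physical
location in the QTL interval, expression in the target tissue, coding
variant load (nsSNPs + InDels above a minimum count), a cis-acting
expression QTL, and a function-keyword match. All inputs come from a
plain TSV so the cascade runs offline and deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = [
    "symbol", "chrom", "start_mb", "end_mb", "expressed_tissues",
    "nssnp_count", "indel_count", "cis_eqtl", "keywords",
]

FILTERS = ["location", "expression", "variants", "cis_eqtl", "function"]


@dataclass
class FilterConfig:
    tissue: str
    min_variant_count: int = 1
    keywords: list[str] = field(default_factory=list)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return table


def genes_in_interval(
    genes: pd.DataFrame, chrom: str, start_mb: float, end_mb: float
) -> pd.DataFrame:
    """Genes overlapping the half-open interval [start, end) on a chromosome.

    Any overlap counts: a gene is kept when gene.start < end and
    gene.end >= start.
    """
    if not start_mb < end_mb:
        raise ValueError("interval start must be < end")
    on_chrom = genes["chrom"].astype(str) == str(chrom)
    overlap = (genes["start_mb"] < end_mb) & (genes["end_mb"] >= start_mb)
    return genes[on_chrom & overlap].reset_index(drop=True)


def _split_list(cell) -> set[str]:
    if pd.isna(cell) or not str(cell).strip():
        return set()
    return {t.strip().lower() for t in str(cell).split(",") if t.strip()}


def filter_candidates(
    genes: pd.DataFrame, config: FilterConfig
) -> pd.DataFrame:
    """Apply the filter cascade to genes already restricted to an interval.

    Returns one row per gene (sorted by symbol) with a boolean column per
    filter, ``rank`` = number of filters passed, and ``retained`` = passed
    all. Missing annotation fields fail the corresponding filter with a
    warning rather than erroring.
    """
    rows = []
    for _, g in genes.iterrows():
        passes = {"location": True}  # membership in the interval is filter 1

        expressed = _split_list(g.get("expressed_tissues"))
        if not expressed and pd.isna(g.get("expressed_tissues")):
            logger.warning("%s: no expression annotation; failing expression filter",
                           g["symbol"])
        passes["expression"] = config.tissue.lower() in expressed

        ns = g.get("nssnp_count")
        ind = g.get("indel_count")
        if pd.isna(ns) or pd.isna(ind):
            logger.warning("%s: missing variant counts; failing variant filter",
                           g["symbol"])
            passes["variants"] = False
        else:
            passes["variants"] = (int(ns) + int(ind)) >= config.min_variant_count

        cis = g.get("cis_eqtl")
        passes["cis_eqtl"] = bool(cis) and not pd.isna(cis)

        kw = _split_list(g.get("keywords"))
        wanted = {k.lower() for k in config.keywords}
        passes["function"] = bool(kw & wanted) if wanted else bool(kw)

        rows.append({
            "symbol": g["symbol"],
            **{f: passes[f] for f in FILTERS},
            "rank": sum(passes.values()),
            "retained": all(passes.values()),
        })
    report = pd.DataFrame(rows, columns=["symbol", *FILTERS, "rank", "retained"])
    return report.sort_values("symbol", kind="stable").reset_index(drop=True)
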