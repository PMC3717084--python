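"""Single-marker regression QTL scans on strain means, permutation-derived
genome-wide thresholds, LOD/LRS conversion, and support intervals."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .geno import GenotypePanel

logger = logging.getLogger(__name__)

#: exact conversion, ~4.605; rounded to 4.6 only for display
LRS_PER_LOD = 2.0 * np.log(10.0)

DEFAULT_LRS_CAP = 1e4
_PERFECT_FIT_EPS = 1e-12


def lod_to_lrs(lod: float) -> float:
    """LRS = 2 ln(10) x LOD."""
    if lod < 0:
        raise ValueError("LOD must be >= 0")
    return LRS_PER_LOD * lod


def lrs_to_lod(lrs: float) -> float:
    """LOD = LRS / (2 ln 10)."""
    if lrs < 0:
        raise ValueError("LRS must be >= 0")
    return lrs / LRS_PER_LOD


def display_lrs_per_lod(ndigits: int = 1) -> float:
    """The conversion factor as printed in reports (4.6 at one decimal)."""
    return round(LRS_PER_LOD, ndigits)


# ---------------------------------------------------------------------------
# scan core

def _lrs_for_marker(
    x: np.ndarray, Y: np.ndarray, cap: float = DEFAULT_LRS_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """LRS of phenotype rows ``Y`` (P x n) on one genotype vector ``x`` (n).

    Uses the regression identity LRS = n ln(RSS0/RSS1) with RSS0 about the
    grand mean and RSS1 from the least-squares line. Returns (lrs, perfect)
    arrays of length P.
    """
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = yc @ xc
    rss1 = syy - sxy**2 / sxx
    lrs = np.zeros(Y.shape[0])
    perfect = np.zeros(Y.shape[0], dtype=bool)
    nz = syy > 0
    perfect[nz] = rss1[nz] <= _PERFECT_FIT_EPS * syy[nz]
    ok = nz & ~perfect
    lrs[ok] = n * np.log(syy[ok] / rss1[ok])
    lrs[perfect] = cap
    return lrs, perfect


@dataclass
class ScanResult:
    """Per-marker scan statistics for one trait."""

    trait: str
    table: pd.DataFrame  # chrom, locus, cm, mb, lrs, lod, additive, increasing_allele, n, skipped, perfect_fit
    n_strains: int
    lrs_cap: float = DEFAULT_LRS_CAP

    def max_lrs(self) -> float:
        valid = self.table.loc[~self.table["skipped"], "lrs"]
        return float(valid.max()) if len(valid) else 0.0

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


def _match(panel: GenotypePanel, strain_means: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    means = strain_means.dropna()
    shared = [s for s in panel.strains if s in means.index]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} strains shared between panel and trait table"
        )
    idx = [panel.strains.index(s) for s in shared]
    G = panel.allele_codes()[:, idx]
    y = means.loc[shared].to_numpy(dtype=float)
    return G, y


def marker_regression_scan(
    panel: GenotypePanel,
    strain_means: pd.Series,
    trait: str = "",
    min_per_class: int = 2,
    lrs_cap: float = DEFAULT_LRS_CAP,
) -> ScanResult:
    """Regress strain means on genotype (B=+1, D=-1) at every marker.

    Strains are matched by name; missing genotypes drop that strain at that
    marker; markers with fewer than ``min_per_class`` strains in either
    genotype class are skipped with a flag. Perfect fits (zero residual)
    are capped at ``lrs_cap`` and flagged.
    """
    G, y = _match(panel, strain_means)
    rows = []
    for j in range(panel.n_markers):
        g = G[j]
        use = ~np.isnan(g)
        x = g[use]
        yy = y[use]
        n_b = int(np.sum(x > 0))
        n_d = int(np.sum(x < 0))
        marker = panel.markers.iloc[j]
        base = {
            "chrom": marker["chrom"], "locus": marker["locus"],
            "cm": marker["cm"], "mb": marker["mb"],
        }
        if n_b < min_per_class or n_d < min_per_class:
            rows.append({**base, "lrs": np.nan, "lod": np.nan, "additive": np.nan,
                         "additive_signed": np.nan, "increasing_allele": "",
                         "n": n_b + n_d, "skipped": True, "perfect_fit": False})
            continue
        lrs_arr, perfect = _lrs_for_marker(x, yy[None, :], cap=lrs_cap)
        lrs = float(lrs_arr[0])
        mean_b = float(yy[x > 0].mean())
        mean_d = float(yy[x < 0].mean())
        signed = (mean_b - mean_d) / 2.0
        rows.append({
            **base, "lrs": lrs, "lod": lrs / LRS_PER_LOD,
            "additive": abs(signed), "additive_signed": signed,
            "increasing_allele": "B6" if signed >= 0 else "D2",
            "n": n_b + n_d, "skipped": False, "perfect_fit": bool(perfect[0]),
        })
    table = pd.DataFrame(rows)
    if table["skipped"].all():
        raise InsufficientDataError("every marker was skipped")
    return ScanResult(trait, table, n_strains=int(y.size), lrs_cap=lrs_cap)


# ---------------------------------------------------------------------------
# permutation thresholds

@dataclass
class Thresholds:
    significant: float  # genome-wide p < 0.05
    suggestive: float   # genome-wide p < 0.63
    n_perm: int
    seed: int
    max_lrs_sample: np.ndarray = field(repr=False, default=None)


def _order_statistic(sample: np.ndarray, q: float) -> float:
    """The ceil(q*n)-th order statistic (1-indexed) of a sample."""
    srt = np.sort(sample)
    k = int(np.ceil(q * sample.size))
    return float(srt[max(k, 1) - 1])


def permutation_thresholds(
    panel: GenotypePanel,
    strain_means: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    significance: float = 0.05,
    suggestive: float = 0.63,
    min_per_class: int = 2,
    lrs_cap: float = DEFAULT_LRS_CAP,
) -> Thresholds:
    """Genome-wide LRS thresholds from the permutation null.

    Phenotype values are shuffled across strain labels ``n_perm`` times;
    the maximum LRS over markers of each permuted scan forms the null
    sample, and thresholds are its upper order statistics
    (ceil((1-p) * n_perm), 1-indexed).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; thresholds will be noisy", n_perm)
    G, y = _match(panel, strain_means)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)])
    max_lrs = np.zeros(n_perm)
    for j in range(panel.n_markers):
        g = G[j]
        use = ~np.isnan(g)
        x = g[use]
        if np.sum(x > 0) < min_per_class or np.sum(x < 0) < min_per_class:
            continue
        lrs, _ = _lrs_for_marker(x, perms[:, use], cap=lrs_cap)
        np.maximum(max_lrs, lrs, out=max_lrs)
    sig = _order_statistic(max_lrs, 1.0 - significance)
    sug = _order_statistic(max_lrs, 1.0 - suggestive)
    return Thresholds(significant=sig, suggestive=sug, n_perm=n_perm,
                      seed=seed, max_lrs_sample=max_lrs)


# ---------------------------------------------------------------------------
# support intervals

@dataclass
class SupportInterval:
    chrom: str
    peak_locus: str
    peak_cm: float
    peak_mb: float
    left_cm: float
    right_cm: float
    left_mb: float
    right_mb: float
    drop: float


def support_interval(
    scan: ScanResult, chrom: str, drop: float = 1.5 * LRS_PER_LOD
) -> SupportInterval | None:
    """Drop-off support interval around the chromosome's LRS peak.

    Walk outward from the peak until the LRS falls below peak - drop;
    each bound is placed by linear interpolation in position between the
    bracketing markers and truncated at the chromosome ends. Returns None
    for a flat (all-skipped) chromosome.
    """
    sub = scan.chromosome(chrom)
    sub = sub[~sub["skipped"]].reset_index(drop=True)
    if sub.empty:
        return None
    lrs = sub["lrs"].to_numpy()
    peak = int(np.argmax(lrs))
    level = lrs[peak] - drop

    def cross(inner: int, outer: int, col: str) -> float:
        f = (lrs[inner] - level) / (lrs[inner] - lrs[outer])
        return float(sub[col].iloc[inner] + f * (sub[col].iloc[outer] - sub[col].iloc[inner]))

    left_cm, left_mb = float(sub["cm"].iloc[0]), float(sub["mb"].iloc[0])
    for i in range(peak - 1, -1, -1):
        if lrs[i] < level:
            left_cm = cross(i + 1, i, "cm")
            left_mb = cross(i + 1, i, "mb")
            break
    right_cm, right_mb = float(sub["cm"].iloc[-1]), float(sub["mb"].iloc[-1])
    for i in range(peak + 1, len(sub)):
        if lrs[i] < level:
            right_cm = cross(i - 1, i, "cm")
            right_mb = cross(i - 1, i, "mb")
            break
    return SupportInterval(
        chrom=chrom, peak_locus=str(sub["locus"].iloc[peak]),
        peak_cm=float(sub["cm"].iloc[peak]), peak_mb=float(sub["mb"].iloc[peak]),
        left_cm=left_cm, right_cm=right_cm, left_mb=left_mb, right_mb=right_mb,
        drop=drop,
    )


# ---------------------------------------------------------------------------
# summary report

def summarize_qtls(
    scans: dict[str, ScanResult],
    thresholds: dict[str, Thresholds],
    drop: float = 1.5 * LRS_PER_LOD,
) -> pd.DataFrame:
    """Report every chromosome-wise LRS maximum above the suggestive
    threshold, with significance class (* suggestive, ** significant),
    increasing allele, additive effect, and support interval."""
    rows = []
    for trait, scan in scans.items():
        thr = thresholds[trait]
        for chrom in dict.fromkeys(scan.table["chrom"]):
            sub = scan.chromosome(chrom)
            sub = sub[~sub["skipped"]]
            if sub.empty:
                continue
            peak = sub.loc[sub["lrs"].idxmax()]
            if peak["lrs"] < thr.suggestive:
                continue
            ci = support_interval(scan, chrom, drop=drop)
            rows.append({
                "trait": trait, "chrom": chrom, "locus": peak["locus"],
                "cm": peak["cm"], "mb": peak["mb"],
                "lrs": peak["lrs"], "lod": peak["lrs"] / LRS_PER_LOD,
                "significance": "**" if peak["lrs"] >= thr.significant else "*",
                "increasing_allele": peak["increasing_allele"],
                "additive": peak["additive"],
                "ci_left_mb": ci.left_mb if ci else np.nan,
                "ci_right_mb": ci.right_mb if ci else np.nan,
                "ci_left_cm": ci.left_cm if ci else np.nan,
                "ci_right_cm": ci.right_cm if ci else np.nan,
            })
    columns = ["trait", "chrom", "locus", "cm", "mb", "lrs", "lod", "significance",
               "increasing_allele", "additive", "ci_left_mb", "ci_right_mb",
               "ci_left_cm", "ci_right_cm"]
    return pd.DataFrame(rows, columns=columns)
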