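"""Trait-table statistics: winsorization, strain summaries, correlation
matrices, broad-sense heritability, and ddCt relative expression."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# winsorization

def winsorize_trait(
    values: np.ndarray | pd.Series, z: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Replace values more than ``z`` SDs from the mean by the nearest
    non-outlier value on the same side.

    Mean and SD are computed once over all values (a single pass; the
    procedure is not re-iterated on the winsorized data). Returns
    ``(winsorized values, outlier flags)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("winsorization needs at least 3 values")
    mean = v.mean()
    sd = v.std(ddof=1)
    if sd == 0.0:
        logger.warning("zero SD: winsorization is a no-op")
        return v.copy(), np.zeros(v.size, dtype=bool)
    zscores = (v - mean) / sd
    flags = np.abs(zscores) > z
    out = v.copy()
    inliers = v[~flags]
    if flags.any() and inliers.size:
        hi_cap = inliers.max()
        lo_cap = inliers.min()
        out[flags & (zscores > 0)] = hi_cap
        out[flags & (zscores < 0)] = lo_cap
    return out, flags


def winsorize_table(
    table: pd.DataFrame, z: float = 3.0, value_col: str = "value"
) -> pd.DataFrame:
    """Winsorize a tidy (strain, animal, tissue, trait, value) table per
    (tissue, trait), across all animals of all strains."""
    out = table.copy()
    out["winsorized"] = False
    for _, idx in out.groupby(["tissue", "trait"]).groups.items():
        vals = out.loc[idx, value_col].to_numpy(dtype=float)
        if vals.size < 3:
            continue
        new, flags = winsorize_trait(vals, z=z)
        out.loc[idx, value_col] = new
        out.loc[idx, "winsorized"] = flags
    return out


# ---------------------------------------------------------------------------
# strain summaries

def strain_summary(
    table: pd.DataFrame,
    value_col: str = "value",
    exclude: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per (tissue, trait, strain): mean, SD, SE = SD/sqrt(n), n.

    ``exclude`` maps tissue -> strains to drop (e.g. strains whose mean
    spectrum failed quality control for that tissue).
    """
    rows = []
    for (tissue, trait, strain), grp in table.groupby(["tissue", "trait", "strain"]):
        if exclude and strain in exclude.get(tissue, []):
            continue
        v = grp[value_col].to_numpy(dtype=float)
        n = v.size
        if n == 1:
            logger.warning("strain %s %s/%s has a single animal; SD set to 0",
                           strain, tissue, trait)
            sd = 0.0
        else:
            sd = float(np.std(v, ddof=1))
        rows.append({
            "tissue": tissue, "trait": trait, "strain": strain,
            "mean": float(np.mean(v)), "sd": sd,
            "se": sd / np.sqrt(n), "n": n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations

@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    n: pd.DataFrame
    method: str = "holm"


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    """Holm or Bonferroni adjustment of a flat p-value vector."""
    p = np.asarray(pvals, dtype=float)
    m = np.sum(~np.isnan(p))
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method != "holm":
        raise ValueError(f"unknown adjustment method {method!r}")
    out = np.full_like(p, np.nan)
    order = np.argsort(np.where(np.isnan(p), np.inf, p))
    running = 0.0
    for rank, idx in enumerate(order):
        if np.isnan(p[idx]):
            continue
        adj = min((m - rank) * p[idx], 1.0)
        running = max(running, adj)
        out[idx] = running
    return out


def correlation_matrix(
    strain_means: pd.DataFrame, method: str = "holm", min_pairs: int = 3
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between trait columns.

    ``strain_means`` is a strain x trait frame. p-values come from the
    two-sided t transform; the upper triangle is adjusted by Holm
    (Bonferroni available) and mirrored.
    """
    traits = list(strain_means.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        n[i, i] = strain_means[traits[i]].notna().sum()
        for j in range(i + 1, k):
            sub = strain_means[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < min_pairs:
                continue
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue  # constant trait: r undefined, left missing
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    iu = np.triu_indices(k, 1)
    adj_flat = _adjust(p[iu], method)
    p_adj = np.full((k, k), np.nan)
    np.fill_diagonal(p_adj, 0.0)
    p_adj[iu] = adj_flat
    p_adj[(iu[1], iu[0])] = adj_flat
    mk = lambda a: pd.DataFrame(a, index=traits, columns=traits)  # noqa: E731
    return CorrelationMatrix(mk(r), mk(p), mk(p_adj), mk(n), method)


# ---------------------------------------------------------------------------
# heritability

@dataclass
class HeritabilityEstimate:
    trait: str
    ve: float
    vp: float
    h2: float | None


def broad_sense_heritability(
    animal_values: pd.DataFrame,
    isogenic_strains: list[str],
    trait: str = "",
    value_col: str = "value",
    vp_scope: str = "animals",
) -> HeritabilityEstimate:
    """H^2 = (Vp - Ve) / Vp, clipped to [0, 1].

    Ve is the df-weighted pooled within-strain variance of the isogenic
    groups (parental strains and F1, which share no genetic variation
    within a group). Vp is the phenotypic variance among the remaining
    (RI) animals, or among their strain means if ``vp_scope='strain_means'``.
    """
    iso = animal_values[animal_values["strain"].isin(isogenic_strains)]
    ri = animal_values[~animal_values["strain"].isin(isogenic_strains)]

    ss = 0.0
    df = 0
    for _, grp in iso.groupby("strain"):
        v = grp[value_col].to_numpy(dtype=float)
        if v.size >= 2:
            ss += float(np.sum((v - v.mean()) ** 2))
            df += v.size - 1
    if df == 0:
        raise ValueError("no isogenic group with >= 2 animals")
    ve = ss / df

    if vp_scope == "strain_means":
        means = ri.groupby("strain")[value_col].mean().to_numpy()
        vp = float(np.var(means, ddof=1)) if means.size >= 2 else 0.0
    else:
        v = ri[value_col].to_numpy(dtype=float)
        vp = float(np.var(v, ddof=1)) if v.size >= 2 else 0.0
    if vp == 0.0:
        logger.warning("%s: zero phenotypic variance, H2 undefined", trait)
        return HeritabilityEstimate(trait, ve, vp, None)
    h2 = float(np.clip((vp - ve) / vp, 0.0, 1.0))
    return HeritabilityEstimate(trait, ve, vp, h2)


# ---------------------------------------------------------------------------
# relative expression

def ddct_relative_quantity(
    target_ct: dict[str, list[float]],
    reference_ct: dict[str, list[float]],
    calibrator: str,
) -> dict[str, float]:
    """Relative quantity per group via the ddCt method.

    dCt = mean(target Ct) - mean(reference Ct) per group;
    ddCt = dCt(group) - dCt(calibrator); RQ = 2^(-ddCt). The calibrator's
    RQ is exactly 1.
    """
    if calibrator not in target_ct:
        raise ValueError(f"calibrator group {calibrator!r} missing from target Cts")
    missing = set(target_ct) - set(reference_ct)
    if missing:
        raise ValueError(f"reference gene Cts missing for groups {sorted(missing)}")
    dct = {}
    for group, cts in target_ct.items():
        t = np.asarray(cts, dtype=float)
        ref = np.asarray(reference_ct[group], dtype=float)
        if t.size == 0 or ref.size == 0 or not (
            np.all(np.isfinite(t)) and np.all(np.isfinite(ref))
        ):
            raise ValueError(f"group {group!r}: Ct values must be finite and non-empty")
        dct[group] = t.mean() - ref.mean()
    return {g: float(2.0 ** (-(d - dct[calibrator]))) for g, d in dct.items()}
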