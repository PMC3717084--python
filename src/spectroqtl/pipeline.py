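"""Pipeline orchestration: preprocess -> traits -> stats -> scan -> candidates.

Each stage communicates with the next only through its declared output
files under the run's output directory, so any stage can be re-run or
replaced independently. A run log records every artifact with a SHA-256
checksum plus the seed, making reruns byte-identical except timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidates as cand
from . import features, preprocess, qtl, traitstats
from .errors import StageFailureError, ValidationError
from .geno import read_geno
from .spectrum import Spectrum, read_spectrum, write_spectrum
from .synthetic import vapor_reference_spectrum

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    spectra_dir: str
    manifest: str
    geno: str
    out_dir: str
    tissues: list[str] = field(default_factory=lambda: ["adipose", "liver", "muscle"])
    quality: preprocess.QualityThresholds = field(default_factory=preprocess.QualityThresholds)
    winsor_z: float = 3.0
    n_perm: int = 1000
    seed: int = 0
    drop_lrs: float = 1.5 * qtl.LRS_PER_LOD
    significance: float = 0.05
    suggestive: float = 0.63
    isogenic_strains: list[str] = field(default_factory=lambda: ["B6", "D2", "F1"])
    exclude_strains: dict[str, list[str]] = field(default_factory=dict)
    gene_table: str | None = None
    filter_keywords: list[str] = field(default_factory=list)
    min_variant_count: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "quality" in raw:
            raw["quality"] = preprocess.QualityThresholds(**raw["quality"])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in [("spectra_dir", self.spectra_dir),
                         ("manifest", self.manifest), ("geno", self.geno)]:
            if not Path(p).exists():
                raise ValidationError(f"{label} does not exist: {p}")
        if self.gene_table is not None and not Path(self.gene_table).exists():
            raise ValidationError(f"gene_table does not exist: {self.gene_table}")
        if self.n_perm < 1 or self.winsor_z <= 0 or self.drop_lrs <= 0:
            raise ValidationError("n_perm, winsor_z and drop_lrs must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages

def stage_preprocess(config: PipelineConfig) -> dict[str, Path]:
    """Correct, quality-test, normalize and average every replicate.

    Writes per-sample mean spectra plus a sample manifest, per-strain mean
    spectra, and the quality report.
    """
    out = Path(config.out_dir)
    (out / "sample_spectra").mkdir(parents=True, exist_ok=True)
    (out / "strain_spectra").mkdir(exist_ok=True)
    manifest = pd.read_csv(config.manifest, sep="\t")
    reference = vapor_reference_spectrum()

    processed: list[Spectrum] = []
    reports: list[preprocess.QualityReport] = []
    qc_rows = []
    for _, row in manifest.iterrows():
        s = read_spectrum(
            Path(config.spectra_dir) / row["file"],
            strain=str(row["strain"]), animal=str(row["animal"]),
            tissue=str(row["tissue"]), replicate=int(row["replicate"]),
        )
        s = preprocess.correct_water_vapor(s, reference)
        report = preprocess.quality_test(s, config.quality)
        qc_rows.append({
            "file": row["file"], "strain": row["strain"], "animal": row["animal"],
            "tissue": row["tissue"], "replicate": row["replicate"],
            "passed": report.passed, "max_intensity": report.max_intensity,
            "vapor_residual": report.vapor_residual, "snr": report.snr,
            "failing": ";".join(report.failing),
        })
        if report.passed:
            s = preprocess.min_max_normalize(s)
        processed.append(s)
        reports.append(report)

    per_sample, per_strain = preprocess.average_replicates(processed, reports)

    sample_rows = []
    for (strain, animal, tissue), mean in sorted(per_sample.items(), key=str):
        fname = f"sample_spectra/{animal}_{tissue}.csv"
        write_spectrum(mean, out / fname)
        sample_rows.append({"file": fname, "strain": strain, "animal": animal,
                            "tissue": tissue, "n_replicates": mean.log["n_averaged"]})
    for (strain, tissue), mean in sorted(per_strain.items(), key=str):
        write_spectrum(mean, out / f"strain_spectra/{strain}_{tissue}.csv")

    samples_path = out / "samples.tsv"
    pd.DataFrame(sample_rows).to_csv(samples_path, sep="\t", index=False)
    qc_path = out / "quality_report.tsv"
    pd.DataFrame(qc_rows).to_csv(qc_path, sep="\t", index=False)
    return {"samples": samples_path, "quality_report": qc_path}


def stage_traits(config: PipelineConfig) -> dict[str, Path]:
    """Extract the per-tissue trait menu from every sample mean spectrum."""
    out = Path(config.out_dir)
    samples = pd.read_csv(out / "samples.tsv", sep="\t")
    registry = features.default_registry()
    rows = []
    for _, row in samples.iterrows():
        if row["tissue"] not in config.tissues:
            continue
        s = read_spectrum(out / row["file"], strain=str(row["strain"]),
                          animal=str(row["animal"]), tissue=str(row["tissue"]))
        for trait, value in features.extract_traits(s, row["tissue"], registry).items():
            rows.append({"strain": row["strain"], "animal": row["animal"],
                         "tissue": row["tissue"], "trait": trait, "value": value})
    path = out / "traits.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return {"traits": path}


def stage_stats(config: PipelineConfig) -> dict[str, Path]:
    """Winsorize, summarize per strain, correlate, and estimate H^2."""
    out = Path(config.out_dir)
    table = pd.read_csv(out / "traits.tsv", sep="\t")
    table["strain"] = table["strain"].astype(str)

    wtable = traitstats.winsorize_table(table, z=config.winsor_z)
    wtable.to_csv(out / "traits_winsorized.tsv", sep="\t", index=False)

    summary = traitstats.strain_summary(wtable, exclude=config.exclude_strains)
    summary_path = out / "trait_table.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)

    ri = summary[~summary["strain"].isin(config.isogenic_strains)]
    corr_paths = []
    for tissue, grp in ri.groupby("tissue"):
        wide = grp.pivot(index="strain", columns="trait", values="mean")
        cm = traitstats.correlation_matrix(wide)
        p = out / f"correlations_{tissue}.tsv"
        # r above, Holm-adjusted p below the diagonal
        merged = cm.r.where(np.triu(np.ones(cm.r.shape, dtype=bool), 1),
                            cm.p_adjusted)
        np.fill_diagonal(merged.values, 1.0)
        merged.to_csv(p, sep="\t")
        corr_paths.append(p)

    h2_rows = []
    wri = wtable
    for (tissue, trait), grp in wri.groupby(["tissue", "trait"]):
        try:
            est = traitstats.broad_sense_heritability(
                grp, config.isogenic_strains, trait=trait)
        except ValueError:
            continue
        h2_rows.append({"tissue": tissue, "trait": trait, "ve": est.ve,
                        "vp": est.vp, "h2": est.h2})
    h2_path = out / "heritability.tsv"
    pd.DataFrame(h2_rows).to_csv(h2_path, sep="\t", index=False)
    return {"trait_table": summary_path, "heritability": h2_path,
            **{p.name: p for p in corr_paths}}


def stage_scan(config: PipelineConfig) -> dict[str, Path]:
    """Marker-regression scans with per-trait permutation thresholds."""
    out = Path(config.out_dir)
    (out / "scans").mkdir(exist_ok=True)
    summary = pd.read_csv(out / "trait_table.tsv", sep="\t")
    summary["strain"] = summary["strain"].astype(str)
    panel = read_geno(config.geno)

    scans: dict[str, qtl.ScanResult] = {}
    thresholds: dict[str, qtl.Thresholds] = {}
    thr_rows = []
    for (tissue, trait), grp in summary.groupby(["tissue", "trait"]):
        key = f"{tissue}:{trait}"
        means = grp.set_index("strain")["mean"]
        scan = qtl.marker_regression_scan(panel, means, trait=key)
        thr = qtl.permutation_thresholds(
            panel, means, n_perm=config.n_perm, seed=config.seed,
            significance=config.significance, suggestive=config.suggestive)
        scans[key] = scan
        thresholds[key] = thr
        scan.table.to_csv(out / "scans" / f"{tissue}_{trait}.tsv", sep="\t", index=False)
        thr_rows.append({"tissue": tissue, "trait": trait,
                         "significant_lrs": thr.significant,
                         "suggestive_lrs": thr.suggestive,
                         "n_perm": thr.n_perm, "seed": thr.seed})

    report = qtl.summarize_qtls(scans, thresholds, drop=config.drop_lrs)
    report_path = out / "qtl_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    thr_path = out / "thresholds.tsv"
    pd.DataFrame(thr_rows).to_csv(thr_path, sep="\t", index=False)
    return {"qtl_report": report_path, "thresholds": thr_path}


def stage_candidates(config: PipelineConfig) -> dict[str, Path]:
    """Filter cascade on genes in each reported QTL interval."""
    out = Path(config.out_dir)
    report = pd.read_csv(out / "qtl_report.tsv", sep="\t")
    genes = cand.read_gene_table(config.gene_table)
    rows = []
    for _, hit in report.iterrows():
        if hit["significance"] != "**":
            continue
        tissue = str(hit["trait"]).split(":", 1)[0]
        in_iv = cand.genes_in_interval(
            genes, str(hit["chrom"]), hit["ci_left_mb"], hit["ci_right_mb"])
        rep = cand.filter_candidates(
            in_iv, cand.FilterConfig(tissue=tissue,
                                     min_variant_count=config.min_variant_count,
                                     keywords=config.filter_keywords))
        rep.insert(0, "trait", hit["trait"])
        rep.insert(1, "chrom", hit["chrom"])
        rows.append(rep)
    path = out / "candidates.tsv"
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["trait", "chrom", "symbol", *cand.FILTERS,
                              "rank", "retained"]).to_csv(path, sep="\t", index=False)
    return {"candidates": path}


# ---------------------------------------------------------------------------
# driver

STAGES = [
    ("preprocess", stage_preprocess),
    ("traits", stage_traits),
    ("stats", stage_stats),
    ("scan", stage_scan),
    ("candidates", stage_candidates),
]


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage in order and write a checksummed run log.

    Raises :class:`ValidationError` before any compute if the config is
    invalid, and :class:`StageFailureError` naming the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    for name, stage in STAGES:
        if name == "candidates" and config.gene_table is None:
            logger.info("no gene table configured; skipping candidate stage")
            continue
        logger.info("running stage %s", name)
        try:
            produced = stage(config)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageFailureError(name, str(exc)) from exc
        for label, path in produced.items():
            artifacts[label] = str(path)
    log = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "artifacts": {k: {"path": v, "sha256": _sha256(Path(v))}
                      for k, v in artifacts.items()},
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return artifacts
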