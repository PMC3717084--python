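"""Synthetic cohort generator: RI genotypes, genetic component amplitudes,
and realistic tissue spectra with planted ground truth.

The generator exists so every downstream stage (preprocessing, band
integration, trait statistics, QTL scans) can be exercised and verified
without downloading anything. Recombinant-inbred mosaics are drawn directly
under the sib-mating map-expansion law rather than by simulating the
breeding generations: the probability that two adjacent markers disagree in
a finished RI strain is R = 4r / (1 + 6r) for meiotic recombination
fraction r, which has the same marginal law at a fraction of the cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, MissingComponentError, UnknownLocusError
from .geno import GenotypePanel, write_geno
from .spectrum import CANONICAL_GRID, GRID_MAX, GRID_MIN, Spectrum, write_spectrum

# ---------------------------------------------------------------------------
# map functions

def haldane_r(d_cm: float) -> float:
    """Meiotic recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def spacing_from_r(r: float) -> float:
    """Inverse of :func:`haldane_r`: map distance (cM) giving fraction ``r``."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -50.0 * np.log(1.0 - 2.0 * r)


def ri_discordance(r: float) -> float:
    """Adjacent-marker discordance probability in a sib-mated RI strain.

    The map-expansion closed form R = 4r/(1+6r).
    """
    return 4.0 * r / (1.0 + 6.0 * r)


# ---------------------------------------------------------------------------
# domain types

@dataclass
class SubBand:
    center: float
    sigma: float
    weight: float


@dataclass
class ComponentModel:
    """A named spectral component built from weighted Gaussian sub-bands."""

    name: str
    sub_bands: list[SubBand]

    def __post_init__(self) -> None:
        if not self.sub_bands:
            raise ValueError(f"component {self.name!r} has no sub-bands")
        for b in self.sub_bands:
            if not (GRID_MIN <= b.center <= GRID_MAX):
                raise ValueError(
                    f"{self.name}: sub-band center {b.center} outside "
                    f"[{GRID_MIN:g}, {GRID_MAX:g}] cm^-1"
                )
            if b.sigma <= 0:
                raise ValueError(f"{self.name}: sigma must be > 0")
            if b.weight <= 0:
                raise ValueError(f"{self.name}: weights must be positive")
        total = sum(b.weight for b in self.sub_bands)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: sub-band weights sum to {total}, not 1")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-amplitude absorbance profile on a wavenumber grid."""
        out = np.zeros_like(grid, dtype=float)
        for b in self.sub_bands:
            out += b.weight * np.exp(-((grid - b.center) ** 2) / (2.0 * b.sigma**2))
        return out


@dataclass
class PlantedQTL:
    """Ground-truth additive locus acting on one spectral component."""

    chrom: str
    position_cm: float
    component: str
    effect: float  # amplitude units per allele substitution (+- coding)

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("QTL effect must be finite")


@dataclass
class PanelDesign:
    """Sampling and genetic design of a synthetic RI cohort."""

    n_strains: int = 30
    males_per_strain: int = 4
    replicates: int = 3
    chrom_lengths_cm: Mapping[str, float] = field(
        default_factory=lambda: {"1": 80.0, "2": 70.0, "3": 60.0}
    )
    marker_spacing_cm: float = 5.0
    strain_sd: float | Mapping[str, float] = 0.0
    env_sd: float | Mapping[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.males_per_strain < 1 or self.replicates < 1:
            raise InvalidDesignError("all counts must be >= 1")
        if self.marker_spacing_cm <= 0:
            raise InvalidDesignError("marker spacing must be positive")
        for sd in (self.strain_sd, self.env_sd):
            vals = sd.values() if isinstance(sd, Mapping) else [sd]
            if any(v < 0 for v in vals):
                raise InvalidDesignError("SDs must be >= 0")

    def sd_for(self, which: str, component: str) -> float:
        sd = self.strain_sd if which == "strain" else self.env_sd
        if isinstance(sd, Mapping):
            return float(sd.get(component, 0.0))
        return float(sd)


# ---------------------------------------------------------------------------
# default tissue component models

def _model(name: str, bands: Sequence[tuple[float, float, float]]) -> ComponentModel:
    return ComponentModel(name, [SubBand(c, s, w) for c, s, w in bands])


def default_component_models(tissue: str) -> dict[str, ComponentModel]:
    """Per-tissue Gaussian sub-band models for the main macromolecular
    components (CH-stretch lipids, ester carbonyl, olefinic lipid, amide,
    collagen side-chains, glycogen C-O, broad baseline hump)."""
    if tissue == "adipose":
        models = [
            _model("lipid_CH", [(2922, 8, 0.45), (2853, 6, 0.30), (2957, 5, 0.15), (1464, 6, 0.10)]),
            _model("ester", [(1743, 8, 0.70), (1160, 15, 0.30)]),
            _model("unsaturated", [(3006, 5, 1.0)]),
            _model("amide", [(1646, 22, 0.55), (1550, 18, 0.45)]),
            _model("collagen", [(1340, 3.5, 0.40), (1320, 4, 0.30), (1280, 3.5, 0.30)]),
            _model("baseline", [(2300, 600, 1.0)]),
        ]
    elif tissue == "liver":
        models = [
            _model("lipid_CH", [(2927, 9, 0.45), (2854, 6, 0.30), (2963, 5, 0.15), (1455, 9, 0.10)]),
            _model("ester", [(1745, 7, 1.0)]),
            _model("amide", [(1638, 22, 0.55), (1547, 18, 0.45)]),
            _model("collagen", [(1340, 3.5, 1.0)]),
            _model("glycogen", [(1154, 9, 0.35), (1081, 6, 0.35), (1044, 8, 0.30)]),
            _model("baseline", [(2300, 600, 1.0)]),
        ]
    elif tissue == "muscle":
        models = [
            _model("lipid_CH", [(2927, 9, 0.45), (2854, 6, 0.30), (2961, 5, 0.15), (1457, 6, 0.10)]),
            _model("ester", [(1741, 6, 1.0)]),
            _model("amide", [(1638, 22, 0.55), (1550, 18, 0.45)]),
            _model("collagen", [(1340, 5, 0.60), (1282, 4, 0.40)]),
            _model("glycogen", [(1081, 8, 0.50), (1046, 6, 0.50)]),
            _model("baseline", [(2300, 600, 1.0)]),
        ]
    else:
        raise ValueError(f"no default component model for tissue {tissue!r}")
    return {m.name: m for m in models}


DEFAULT_COMPONENT_MEANS: dict[str, dict[str, float]] = {
    "adipose": {
        "lipid_CH": 3.0, "ester": 1.5, "unsaturated": 0.3,
        "amide": 1.0, "collagen": 0.2, "baseline": 0.1,
    },
    "liver": {
        "lipid_CH": 1.0, "ester": 0.5, "amide": 2.0,
        "collagen": 0.3, "glycogen": 0.8, "baseline": 0.1,
    },
    "muscle": {
        "lipid_CH": 0.8, "ester": 0.4, "amide": 2.0,
        "collagen": 0.5, "glycogen": 0.4, "baseline": 0.1,
    },
}

# Fixed comb of narrow vapor lines in the 1900-1300 cm^-1 region; the
# generator scales this comb by one coefficient and the corrector removes it
# by fitting that same single coefficient.
VAPOR_LINES: list[tuple[float, float]] = [
    (1889, 0.60), (1870, 0.80), (1843, 1.00), (1828, 0.70), (1793, 0.50),
    (1772, 0.90), (1734, 0.40), (1700, 0.60), (1669, 0.80), (1653, 0.55),
    (1616, 0.90), (1576, 0.60), (1540, 0.50), (1508, 0.70), (1457, 0.60),
    (1419, 0.80), (1396, 0.50), (1340, 0.35),
]
VAPOR_SIGMA = 1.3


def vapor_reference_spectrum() -> Spectrum:
    """Unit-scale water-vapor line comb on the canonical grid."""
    grid = CANONICAL_GRID
    values = np.zeros_like(grid)
    for center, weight in VAPOR_LINES:
        values += weight * np.exp(-((grid - center) ** 2) / (2.0 * VAPOR_SIGMA**2))
    return Spectrum(grid.copy(), values, log={"kind": "vapor_reference"})


# ---------------------------------------------------------------------------
# genotype simulation

def simulate_ri_genotypes(design: PanelDesign, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Draw an RI genotype panel under the map-expansion discordance law.

    Each strain is an independent Markov chain along each chromosome: the
    first marker is B or D with probability 1/2, and each adjacent-marker
    transition flips the allele with probability 4r/(1+6r), r from the
    Haldane map function of the marker spacing.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    r = haldane_r(design.marker_spacing_cm)
    flip_p = ri_discordance(r)

    rows = []
    call_blocks = []
    for chrom, length in design.chrom_lengths_cm.items():
        n_pos = int(np.floor(length / design.marker_spacing_cm + 1e-9)) + 1
        positions = np.arange(n_pos) * design.marker_spacing_cm
        n = len(positions)
        calls = np.empty((n, design.n_strains), dtype=np.int8)
        calls[0] = rng.choice(np.array([1, -1], dtype=np.int8), size=design.n_strains)
        if n > 1:
            flips = rng.random((n - 1, design.n_strains)) < flip_p
            signs = np.where(flips, -1, 1).astype(np.int8)
            calls[1:] = calls[0] * np.cumprod(signs, axis=0)
        call_blocks.append(calls)
        for i, cm in enumerate(positions):
            rows.append((str(chrom), f"C{chrom}M{i + 1:03d}", float(cm), float(cm) / 2.0))

    markers = pd.DataFrame(rows, columns=["chrom", "locus", "cm", "mb"])
    strains = [f"BXD{i + 1:03d}" for i in range(design.n_strains)]
    panel = GenotypePanel(
        markers, strains, np.vstack(call_blocks),
        meta={"type": "riset", "mat": "B", "pat": "D", "seed": str(design.seed)},
    )
    return panel


def nearest_marker(panel: GenotypePanel, chrom: str, position_cm: float) -> int:
    """Row index of the panel marker nearest to a chromosome position."""
    idx = panel.chrom_index(chrom)
    if idx.size == 0:
        raise UnknownLocusError(f"chromosome {chrom!r} not in panel")
    cms = panel.markers["cm"].to_numpy()[idx]
    return int(idx[np.argmin(np.abs(cms - position_cm))])


# ---------------------------------------------------------------------------
# amplitude simulation

def simulate_amplitudes(
    panel: GenotypePanel,
    qtls: Sequence[PlantedQTL],
    design: PanelDesign,
    component_means: Mapping[str, float],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-animal component amplitudes under an additive genetic model.

    amplitude = component mean + sum of allele-coded QTL effects
    + strain deviate N(0, strain_sd) + animal deviate N(0, env_sd),
    floored at zero. Returns the amplitude table (one row per strain x
    animal, one column per component) and a ground-truth record.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    components = list(component_means)
    for q in qtls:
        if q.component not in component_means:
            raise MissingComponentError(
                f"QTL targets unknown component {q.component!r}"
            )
    qtl_markers = {id(q): nearest_marker(panel, q.chrom, q.position_cm) for q in qtls}

    genetic = {
        c: np.full(panel.n_strains, float(component_means[c])) for c in components
    }
    for q in qtls:
        g = panel.allele_codes()[qtl_markers[id(q)]]
        g = np.nan_to_num(g, nan=0.0)
        genetic[q.component] = genetic[q.component] + q.effect * g

    rows = []
    for c in components:
        sd_s = design.sd_for("strain", c)
        genetic[c] = genetic[c] + (rng.normal(0.0, sd_s, panel.n_strains) if sd_s > 0 else 0.0)
    for si, strain in enumerate(panel.strains):
        for a in range(design.males_per_strain):
            row: dict = {"strain": strain, "animal": f"{strain}-{a + 1}"}
            for c in components:
                sd_e = design.sd_for("env", c)
                noise = rng.normal(0.0, sd_e) if sd_e > 0 else 0.0
                row[c] = max(0.0, genetic[c][si] + noise)
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "qtls": [
            {
                "chrom": q.chrom, "position_cm": q.position_cm,
                "component": q.component, "effect": q.effect,
                "marker": panel.markers["locus"].iloc[qtl_markers[id(q)]],
            }
            for q in qtls
        ],
        "component_means": dict(component_means),
        "genetic_values": {c: genetic[c].tolist() for c in components},
        "strains": list(panel.strains),
    }
    return table, truth


def simulate_isogenic_amplitudes(
    qtls: Sequence[PlantedQTL],
    design: PanelDesign,
    component_means: Mapping[str, float],
    rng: np.random.Generator | None = None,
    groups: Sequence[str] = ("B6", "D2", "F1"),
) -> pd.DataFrame:
    """Amplitudes for the isogenic control groups.

    B6 carries +1 at every planted locus, D2 carries -1, F1 has zero net
    additive value; within-group variation is environmental only.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    coding = {"B6": 1.0, "D2": -1.0, "F1": 0.0}
    rows = []
    for group in groups:
        base = {c: float(component_means[c]) for c in component_means}
        for q in qtls:
            base[q.component] += q.effect * coding[group]
        for a in range(design.males_per_strain):
            row: dict = {"strain": group, "animal": f"{group}-{a + 1}"}
            for c in component_means:
                sd_e = design.sd_for("env", c)
                noise = rng.normal(0.0, sd_e) if sd_e > 0 else 0.0
                row[c] = max(0.0, base[c] + noise)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectrum synthesis

def synthesize_spectrum(
    amplitudes: Mapping[str, float],
    models: Mapping[str, ComponentModel],
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
    vapor_scale: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **metadata,
) -> Spectrum:
    """Compose a spectrum from component amplitudes plus instrument artifacts.

    spectrum = sum_c amplitude_c * component profile_c
               + linear baseline + vapor comb + white noise
    """
    grid = CANONICAL_GRID
    values = np.zeros_like(grid)
    for name, model in models.items():
        if name not in amplitudes:
            raise MissingComponentError(
                f"amplitude table is missing component {name!r}"
            )
        values += float(amplitudes[name]) * model.profile(grid)
    # normalized abscissa keeps slope magnitudes O(offset)
    values += baseline_offset + baseline_slope * (grid - GRID_MIN) / (GRID_MAX - GRID_MIN)
    if vapor_scale != 0.0:
        values += vapor_scale * vapor_reference_spectrum().absorbance
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        values += rng.normal(0.0, noise_sd, grid.size)
    return Spectrum(
        grid.copy(), values,
        strain=metadata.get("strain"), animal=metadata.get("animal"),
        tissue=metadata.get("tissue"), replicate=metadata.get("replicate"),
        log={
            "baseline_slope": baseline_slope, "baseline_offset": baseline_offset,
            "vapor_scale": vapor_scale, "noise_sd": noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# cohort writer

@dataclass
class ArtifactSettings:
    """Instrument artifact ranges used when writing a cohort to disk."""

    baseline_slope_sd: float = 0.02
    baseline_offset_sd: float = 0.02
    vapor_scale_sd: float = 0.005
    noise_sd: float = 0.002


def generate_cohort(
    design: PanelDesign,
    tissues: Sequence[str],
    qtls_by_tissue: Mapping[str, Sequence[PlantedQTL]],
    out_dir: str | Path,
    artifacts: ArtifactSettings | None = None,
    component_means: Mapping[str, Mapping[str, float]] | None = None,
) -> dict:
    """Simulate a full cohort and write it as text files.

    Writes ``panel.geno``, per-replicate two-column CSV spectra under
    ``spectra/``, a tab-delimited ``manifest.tsv`` (file, strain, animal,
    tissue, replicate) and ``truth.json`` with every generation parameter.
    """
    out_dir = Path(out_dir)
    (out_dir / "spectra").mkdir(parents=True, exist_ok=True)
    if artifacts is None:
        artifacts = ArtifactSettings()

    rng = np.random.default_rng(design.seed)
    panel = simulate_ri_genotypes(design, rng)
    write_geno(panel, out_dir / "panel.geno")

    manifest_rows = []
    truth: dict = {"seed": design.seed, "tissues": {}}
    for tissue in tissues:
        models = default_component_models(tissue)
        means = (component_means or DEFAULT_COMPONENT_MEANS)[tissue]
        qtls = list(qtls_by_tissue.get(tissue, []))
        amps, t_truth = simulate_amplitudes(panel, qtls, design, means, rng)
        iso = simulate_isogenic_amplitudes(qtls, design, means, rng)
        all_amps = pd.concat([iso, amps], ignore_index=True)
        for _, row in all_amps.iterrows():
            for rep in range(1, design.replicates + 1):
                spec = synthesize_spectrum(
                    {c: row[c] for c in means},
                    models,
                    baseline_slope=rng.normal(0.0, artifacts.baseline_slope_sd),
                    baseline_offset=abs(rng.normal(0.0, artifacts.baseline_offset_sd)),
                    vapor_scale=abs(rng.normal(0.0, artifacts.vapor_scale_sd)),
                    noise_sd=artifacts.noise_sd,
                    rng=rng,
                    strain=row["strain"], animal=row["animal"],
                    tissue=tissue, replicate=rep,
                )
                fname = f"spectra/{row['animal']}_{tissue}_r{rep}.csv"
                write_spectrum(spec, out_dir / fname)
                manifest_rows.append(
                    {"file": fname, "strain": row["strain"], "animal": row["animal"],
                     "tissue": tissue, "replicate": rep}
                )
        truth["tissues"][tissue] = t_truth

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return truth
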