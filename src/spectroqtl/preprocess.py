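"""Spectral preprocessing: water-vapor correction, quality test, min-max
normalization, and replicate averaging.

Pipeline order is fixed: correct -> quality test -> normalize -> average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateNormalizationError, DegenerateReferenceError
from .spectrum import Spectrum, read_spectrum  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

VAPOR_FIT_WINDOW = (1300.0, 1900.0)
VAPOR_QC_WINDOW = (1837.0, 1847.0)
NOISE_WINDOW = (2000.0, 2200.0)
AMIDE_WINDOW = (1500.0, 1700.0)
NORM_WINDOW = (1500.0, 1700.0)


def _second_diff(values: np.ndarray) -> np.ndarray:
    return values[2:] - 2.0 * values[1:-1] + values[:-2]


def correct_water_vapor(s: Spectrum, vapor_reference: Spectrum) -> Spectrum:
    """Subtract a scaled vapor reference, choosing the scale that makes the
    result smoothest over 1900-1300 cm^-1.

    The coefficient minimizes the sum of squared second differences of
    ``s - alpha * reference`` in the fit window; its closed form is the
    projection of the second differences of ``s`` onto those of the
    reference. The fitted alpha is recorded in the spectrum log.
    """
    lo, hi = VAPOR_FIT_WINDOW
    mask = s.window(lo, hi)
    ds = _second_diff(s.absorbance[mask])
    dv = _second_diff(vapor_reference.absorbance[mask])
    denom = float(dv @ dv)
    if denom <= 0.0:
        raise DegenerateReferenceError(
            "vapor reference has zero curvature in the fit window"
        )
    alpha = float(ds @ dv) / denom
    corrected = s.absorbance - alpha * vapor_reference.absorbance
    return s.with_absorbance(corrected, vapor_alpha=alpha)


@dataclass
class QualityThresholds:
    """Pass criteria for the spectral quality test.

    Defaults are calibrated once against the synthetic generator's default
    artifact settings (the acquisition software's thresholds are not
    published).
    """

    min_intensity: float = 0.01
    max_intensity: float = 50.0
    max_vapor_residual: float = 8e-3
    min_snr: float = 10.0


@dataclass
class QualityReport:
    passed: bool
    max_intensity: float
    vapor_residual: float
    snr: float
    failing: list[str] = field(default_factory=list)
    sample_id: str = ""


def _detrend(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coeffs = np.polyfit(x, y, 1)
    return y - np.polyval(coeffs, x)


def quality_test(s: Spectrum, thresholds: QualityThresholds | None = None) -> QualityReport:
    """Deterministic pass/fail on intensity range, vapor residual, and SNR.

    SNR is the peak baseline-corrected amide-region amplitude divided by the
    RMS of the detrended 2200-2000 cm^-1 segment (a signal-free region).
    The vapor residual is the RMS second difference in 1847-1837 cm^-1,
    where a strong vapor line sits but tissue bands do not.
    """
    if thresholds is None:
        thresholds = QualityThresholds()
    failing: list[str] = []

    max_int = float(np.max(s.absorbance))
    if not (thresholds.min_intensity <= max_int <= thresholds.max_intensity):
        failing.append("intensity")

    vap_mask = s.window(*VAPOR_QC_WINDOW)
    vapor_residual = float(np.sqrt(np.mean(_second_diff(s.absorbance[vap_mask]) ** 2)))
    if vapor_residual > thresholds.max_vapor_residual:
        failing.append("vapor")

    noise_mask = s.window(*NOISE_WINDOW)
    noise = float(
        np.sqrt(np.mean(_detrend(s.wavenumbers[noise_mask], s.absorbance[noise_mask]) ** 2))
    )
    am_mask = s.window(*AMIDE_WINDOW)
    am_w, am_a = s.wavenumbers[am_mask], s.absorbance[am_mask]
    baseline = np.interp(am_w, [am_w[0], am_w[-1]], [am_a[0], am_a[-1]])
    signal = float(np.max(am_a - baseline))
    snr = signal / noise if noise > 0 else np.inf
    if snr < thresholds.min_snr:
        failing.append("snr")

    return QualityReport(
        passed=not failing, max_intensity=max_int,
        vapor_residual=vapor_residual, snr=snr,
        failing=failing, sample_id=s.sample_id,
    )


def min_max_normalize(s: Spectrum) -> Spectrum:
    """Scale so the 1700-1500 cm^-1 window spans exactly [0, 1].

    The offset and scale are determined from the window's min and max but
    applied to the whole spectrum, keeping all bands on one scale.
    """
    mask = s.window(*NORM_WINDOW)
    lo = float(np.min(s.absorbance[mask]))
    hi = float(np.max(s.absorbance[mask]))
    if hi - lo <= 0.0:
        raise DegenerateNormalizationError(
            f"{s.sample_id}: constant over the normalization window"
        )
    return s.with_absorbance((s.absorbance - lo) / (hi - lo), norm_min=lo, norm_max=hi)


def average_spectra(spectra: list[Spectrum], **metadata) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing a grid."""
    if not spectra:
        raise ValueError("cannot average zero spectra")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise ValueError("spectra are not on a common grid")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    first = spectra[0]
    return Spectrum(
        grid.copy(), mean,
        strain=metadata.get("strain", first.strain),
        animal=metadata.get("animal", first.animal),
        tissue=metadata.get("tissue", first.tissue),
        replicate=None,
        log={"n_averaged": len(spectra)},
    )


def average_replicates(
    spectra: list[Spectrum],
    reports: list[QualityReport] | None = None,
) -> tuple[dict[tuple, Spectrum], dict[tuple, Spectrum]]:
    """Average technical replicates per sample, then samples per strain.

    Only quality-passing replicates enter the means (pass all if ``reports``
    is None). Samples with zero passing replicates are dropped with a logged
    warning. Returns ``(per_sample, per_strain)`` keyed by
    ``(strain, animal, tissue)`` and ``(strain, tissue)``.
    """
    if reports is not None and len(reports) != len(spectra):
        raise ValueError("one quality report per spectrum required")
    ok = [
        s for i, s in enumerate(spectra)
        if reports is None or reports[i].passed
    ]
    by_sample: dict[tuple, list[Spectrum]] = {}
    all_samples = {(s.strain, s.animal, s.tissue) for s in spectra}
    for s in ok:
        by_sample.setdefault((s.strain, s.animal, s.tissue), []).append(s)
    for key in sorted(all_samples - set(by_sample), key=str):
        logger.warning("sample %s dropped: no quality-passing replicates", key)

    per_sample = {
        key: average_spectra(group, strain=key[0], animal=key[1], tissue=key[2])
        for key, group in by_sample.items()
    }
    by_strain: dict[tuple, list[Spectrum]] = {}
    for (strain, _animal, tissue), mean in per_sample.items():
        by_strain.setdefault((strain, tissue), []).append(mean)
    per_strain = {
        key: average_spectra(group, strain=key[0], animal=None, tissue=key[1])
        for key, group in by_strain.items()
    }
    return per_sample, per_strain
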