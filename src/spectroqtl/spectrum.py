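"""Spectrum container, canonical wavenumber grid, and two-column text I/O.

All pipeline stages operate on spectra resampled to the canonical ascending
600-4000 cm^-1 grid with 1 cm^-1 point spacing, endpoints inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import CoverageError, SpectrumParseError

GRID_MIN = 600.0
GRID_MAX = 4000.0
GRID_STEP = 1.0

#: canonical ascending wavenumber grid (cm^-1)
CANONICAL_GRID = np.arange(GRID_MIN, GRID_MAX + GRID_STEP / 2, GRID_STEP)


@dataclass
class Spectrum:
    """An absorbance spectrum on a strictly ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers : ndarray
        Strictly monotone ascending grid in cm^-1.
    absorbance : ndarray
        Absorbance values, same length as ``wavenumbers``.
    strain, animal, tissue, replicate :
        Sample metadata; ``tissue`` is one of ``adipose``, ``liver``,
        ``muscle`` for real data but is not restricted here.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    strain: str | None = None
    animal: str | None = None
    tissue: str | None = None
    replicate: int | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if not (np.all(np.isfinite(self.wavenumbers)) and np.all(np.isfinite(self.absorbance))):
            raise ValueError("spectrum contains NaN or Inf")

    # -- basic algebra -------------------------------------------------
    def with_absorbance(self, values: np.ndarray, **log) -> "Spectrum":
        """Return a copy with new absorbance values and extra log entries."""
        s = replace(self, absorbance=np.asarray(values, dtype=float))
        s.log = {**self.log, **log}
        return s

    def value_at(self, wavenumber: float) -> float:
        """Linearly interpolated absorbance at an arbitrary wavenumber."""
        lo, hi = self.wavenumbers[0], self.wavenumbers[-1]
        if not (lo <= wavenumber <= hi):
            raise CoverageError(
                f"wavenumber {wavenumber} outside coverage [{lo}, {hi}]"
            )
        return float(np.interp(wavenumber, self.wavenumbers, self.absorbance))

    def window(self, lower: float, upper: float) -> np.ndarray:
        """Boolean mask of grid points inside [lower, upper]."""
        return (self.wavenumbers >= lower) & (self.wavenumbers <= upper)

    @property
    def sample_id(self) -> str:
        parts = [p for p in (self.strain, self.animal, self.tissue) if p is not None]
        if self.replicate is not None:
            parts.append(f"rep{self.replicate}")
        return "/".join(map(str, parts)) if parts else "<anonymous>"


def resample_to_canonical(wavenumbers: np.ndarray, absorbance: np.ndarray) -> np.ndarray:
    """Linear interpolation of (wavenumbers, absorbance) onto the canonical grid.

    Descending inputs are reversed first. Raises :class:`CoverageError` if the
    input does not cover the full canonical range.
    """
    w = np.asarray(wavenumbers, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if w.size >= 2 and w[0] > w[-1]:
        w, a = w[::-1], a[::-1]
    order = np.argsort(w, kind="stable")
    w, a = w[order], a[order]
    if w[0] > GRID_MIN or w[-1] < GRID_MAX:
        raise CoverageError(
            f"input covers [{w[0]:g}, {w[-1]:g}] cm^-1, canonical grid needs "
            f"[{GRID_MIN:g}, {GRID_MAX:g}]"
        )
    return np.interp(CANONICAL_GRID, w, a)


def read_spectrum(
    path: str | Path,
    strain: str | None = None,
    animal: str | None = None,
    tissue: str | None = None,
    replicate: int | None = None,
) -> Spectrum:
    """Read a two-column text spectrum and resample onto the canonical grid.

    Accepts comma-, tab- or whitespace-separated numeric columns; lines
    starting with ``#`` and a single non-numeric header line are skipped.
    """
    path = Path(path)
    ws: list[float] = []
    abss: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").replace(";", " ").split()
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}",
                    line=lineno,
                )
            try:
                w, a = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not ws:  # tolerate one header line
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {parts[:2]!r}", line=lineno
                ) from None
            ws.append(w)
            abss.append(a)
    if len(ws) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    values = resample_to_canonical(np.array(ws), np.array(abss))
    return Spectrum(
        CANONICAL_GRID.copy(), values,
        strain=strain, animal=animal, tissue=tissue, replicate=replicate,
        log={"source": str(path)},
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV (wavenumber, absorbance)."""
    arr = np.column_stack([spectrum.wavenumbers, spectrum.absorbance])
    np.savetxt(path, arr, fmt="%.6f,%.10g", header="wavenumber,absorbance", comments="")
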