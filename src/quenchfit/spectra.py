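"""Emission scans and excitation-emission matrices (EEMs).

An EEM is the 2-D fluorescence landscape recorded by scanning excitation
wavelength against emission wavelength; for a protein like human serum
albumin it shows a dominant tryptophan/tyrosine peak near
(lambda_ex, lambda_em) = (280, 335) nm, a weaker peptide-backbone peak,
and a first-order Rayleigh scatter ridge along lambda_ex = lambda_em
whose height grows with solute particle size.  This module holds the data
model for both kinds of spectrum, CSV I/O, peak detection away from the
scatter ridge, ridge location, and emission-maximum tracking (the blue
shift of the emission peak under ligand binding).

CSV layouts
-----------
EEM CSV: first row is the emission grid (cell (1,1) blank), first column
the excitation grid, body the intensities; UTF-8, dot decimal.
Emission-scan CSV: two columns ``wavelength_nm,intensity`` with header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EmissionScan",
    "EEM",
    "FluorPeak",
    "read_eem",
    "write_eem",
    "read_emission_scan",
    "write_emission_scan",
    "detect_fluorescence_peaks",
    "locate_rayleigh_ridge",
    "emission_maximum",
    "peak_shift",
]

#: default half-width (nm) of the band around lambda_ex = lambda_em that is
#: treated as first-order Rayleigh scatter (two 5-nm grid steps)
DEFAULT_RIDGE_HALFWIDTH_NM = 10.0
#: default peak-intensity floor as a fraction of the global matrix maximum
DEFAULT_MIN_PROMINENCE = 0.05


def _check_grid(grid: np.ndarray, name: str) -> None:
    if grid.ndim != 1 or grid.size < 2:
        raise ValidationError(f"{name} grid must be 1-D with >= 2 points")
    steps = np.diff(grid)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0))
        raise FormatError(
            f"{name} grid not strictly increasing at index {bad + 1} "
            f"(value {grid[bad + 1]!r} after {grid[bad]!r})"
        )
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(~np.isclose(steps, steps[0], rtol=1e-6, atol=1e-9)))
        raise FormatError(
            f"{name} grid step not uniform at index {bad + 1}: "
            f"step {steps[bad]} differs from {steps[0]}"
        )


@dataclass(frozen=True)
class EmissionScan:
    """A single emission scan at fixed excitation wavelength.

    Parameters
    ----------
    wavelengths : array-like
        Emission wavelengths in nm; strictly increasing, uniform step,
        at least 3 points.
    intensities : array-like
        Fluorescence intensities (arbitrary units), all >= 0.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.size < 3:
            raise ValidationError("emission scan needs >= 3 grid points")
        _check_grid(wl, "emission")
        if it.shape != wl.shape:
            raise ValidationError(
                f"intensity length {it.size} != wavelength length {wl.size}"
            )
        if np.any(it < 0):
            raise ValidationError("negative intensity in emission scan")
        if not np.all(np.isfinite(it)):
            raise ValidationError("non-finite intensity in emission scan")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix.

    ``intensity[i, j]`` is the reading at excitation ``excitation_grid[i]``
    and emission ``emission_grid[j]``; both grids are strictly increasing
    with uniform step, all intensities are >= 0.
    """

    excitation_grid: np.ndarray
    emission_grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation_grid, dtype=float)
        em = np.asarray(self.emission_grid, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        _check_grid(ex, "excitation")
        _check_grid(em, "emission")
        if z.shape != (ex.size, em.size):
            raise ValidationError(
                f"intensity shape {z.shape} != ({ex.size}, {em.size})"
            )
        if np.any(z < 0):
            i, j = np.argwhere(z < 0)[0]
            raise ValidationError(
                f"negative intensity at excitation {ex[i]} nm, emission {em[j]} nm"
            )
        if not np.all(np.isfinite(z)):
            raise ValidationError("non-finite intensity in EEM")
        object.__setattr__(self, "excitation_grid", ex)
        object.__setattr__(self, "emission_grid", em)
        object.__setattr__(self, "intensity", z)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class FluorPeak:
    """A located maximum in an EEM.

    ``kind`` is ``"fluorescence"`` for peaks away from the scatter band and
    ``"rayleigh_first_order"`` for the maximum of the elastic-scatter ridge
    along lambda_ex = lambda_em.
    """

    excitation_nm: float
    emission_nm: float
    intensity: float
    kind: Literal["fluorescence", "rayleigh_first_order"] = "fluorescence"

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError("peak intensity must be >= 0")
        if self.kind not in ("fluorescence", "rayleigh_first_order"):
            raise ValidationError(f"unknown peak kind {self.kind!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_eem(path: str | Path) -> EEM:
    """Read an EEM from CSV (row 1 = emission grid, column 1 = excitation grid).

    Raises
    ------
    FormatError
        Malformed or non-uniform grids, non-numeric cells.
    ValidationError
        Negative intensities.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, comment="#", float_precision="round_trip")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise FormatError(f"{path}: EEM CSV needs at least 2 rows and 2 columns")
    try:
        em = df.iloc[0, 1:].astype(float).to_numpy()
        ex = df.iloc[1:, 0].astype(float).to_numpy()
        body = df.iloc[1:, 1:].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell in EEM CSV: {exc}") from exc
    try:
        return EEM(excitation_grid=ex, emission_grid=em, intensity=body)
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def write_eem(eem: EEM, path: str | Path, header_comment: str | None = None) -> None:
    """Write an EEM in the layout :func:`read_eem` expects (lossless round-trip)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("," + ",".join(repr(float(v)) for v in eem.emission_grid) + "\n")
        for i, ex in enumerate(eem.excitation_grid):
            row = ",".join(repr(float(v)) for v in eem.intensity[i])
            fh.write(f"{float(ex)!r},{row}\n")


def read_emission_scan(path: str | Path) -> EmissionScan:
    """Read a two-column ``wavelength_nm,intensity`` CSV."""
    df = pd.read_csv(path, comment="#")
    required = {"wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: emission-scan CSV must have columns {sorted(required)}"
        )
    return EmissionScan(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
    )


def write_emission_scan(scan: EmissionScan, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": scan.wavelengths, "intensity": scan.intensities}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Peak machinery
# ---------------------------------------------------------------------------

def _rayleigh_band_mask(eem: EEM, halfwidth_nm: float) -> np.ndarray:
    """Boolean mask of cells with |lambda_ex - lambda_em| <= halfwidth."""
    diff = np.abs(eem.excitation_grid[:, None] - eem.emission_grid[None, :])
    return diff <= halfwidth_nm


def detect_fluorescence_peaks(
    eem: EEM,
    ridge_halfwidth_nm: float = DEFAULT_RIDGE_HALFWIDTH_NM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> list[FluorPeak]:
    """Find strict local maxima of the EEM outside the Rayleigh band.

    A cell is a peak when it is strictly greater than all of its 8
    neighbours (edge cells compare only against existing neighbours), lies
    outside the band ``|lambda_ex - lambda_em| <= ridge_halfwidth_nm`` and
    reaches at least ``min_prominence`` times the global matrix maximum.
    Peaks are returned sorted by decreasing intensity; ties are broken by
    (lower excitation, then lower emission) wavelength.
    """
    if eem.intensity.size == 0:
        raise ValidationError("empty EEM")
    if ridge_halfwidth_nm < 0:
        raise DomainError("ridge_halfwidth_nm must be >= 0")
    if not 0 < min_prominence < 1:
        raise DomainError("min_prominence must lie strictly between 0 and 1")

    z = eem.intensity
    # strict 8-neighbourhood maximum via -inf padding
    padded = np.full((z.shape[0] + 2, z.shape[1] + 2), -np.inf)
    padded[1:-1, 1:-1] = z
    is_max = np.ones(z.shape, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neighbour = padded[1 + di : 1 + di + z.shape[0], 1 + dj : 1 + dj + z.shape[1]]
            is_max &= z > neighbour

    is_max &= ~_rayleigh_band_mask(eem, ridge_halfwidth_nm)
    is_max &= z >= min_prominence * z.max()

    peaks = [
        FluorPeak(
            excitation_nm=float(eem.excitation_grid[i]),
            emission_nm=float(eem.emission_grid[j]),
            intensity=float(z[i, j]),
            kind="fluorescence",
        )
        for i, j in np.argwhere(is_max)
    ]
    peaks.sort(key=lambda p: (-p.intensity, p.excitation_nm, p.emission_nm))
    return peaks


def locate_rayleigh_ridge(
    eem: EEM, ridge_halfwidth_nm: float = DEFAULT_RIDGE_HALFWIDTH_NM
) -> FluorPeak:
    """Maximum-intensity cell within the first-order scatter band.

    Ties are broken toward (lower excitation, then lower emission), so the
    all-zero matrix returns the first in-band cell in grid order.
    """
    band = _rayleigh_band_mask(eem, ridge_halfwidth_nm)
    if not band.any():
        raise DomainError(
            "excitation and emission grids do not overlap within "
            f"{ridge_halfwidth_nm} nm of the lambda_ex = lambda_em diagonal"
        )
    z = np.where(band, eem.intensity, -np.inf)
    i, j = np.unravel_index(int(np.argmax(z)), z.shape)  # argmax = first max in C order
    return FluorPeak(
        excitation_nm=float(eem.excitation_grid[i]),
        emission_nm=float(eem.emission_grid[j]),
        intensity=float(eem.intensity[i, j]),
        kind="rayleigh_first_order",
    )


def emission_maximum(scan: EmissionScan) -> tuple[float, float]:
    """Wavelength and intensity of the scan's global maximum.

    Ties break toward the shorter wavelength; an all-equal scan logs a
    warning and returns the shortest wavelength.
    """
    it = scan.intensities
    if np.all(it == it[0]):
        logger.warning("emission scan is flat; returning shortest wavelength")
    idx = int(np.argmax(it))  # first occurrence = shortest wavelength
    return float(scan.wavelengths[idx]), float(it[idx])


def peak_shift(series) -> float:
    """Signed shift (nm) of the emission maximum across a titration.

    ``emission_maximum`` at the largest ligand concentration minus the same
    at zero ligand; negative values are blue shifts, the signature of a
    fluorophore moving into a less polar microenvironment on binding.

    Parameters
    ----------
    series : TitrationSeries
        Must carry full emission scans at C = 0 and at the largest C.
    """
    from .exceptions import CapabilityError  # local to avoid cycle noise

    scan0 = series.scan_at(0.0)
    scan_max = series.scan_at(series.concentrations[-1])
    if scan0 is None or scan_max is None:
        raise CapabilityError(
            "peak_shift needs full emission scans at C=0 and the largest C; "
            "this series is scalar-only — use the scalar titration pipeline"
        )
    return emission_maximum(scan_max)[0] - emission_maximum(scan0)[0]
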