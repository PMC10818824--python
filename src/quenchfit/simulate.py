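"""Synthetic titration series, emission scans and EEMs.

Every analysis stage in this package can be exercised without instrument
data: the generators here produce series and spectra with the statistical
structure the fitters assume, seeded and fully deterministic.

Two generative titration models are provided, one per fitter:

* ``modified_sv`` — mean intensity F(C) = F0 * (1 - fa*Ksv*C / (1 + Ksv*C)),
  whose transform F0/(F0-F) vs 1/C is an exact line with intercept 1/fa
  and slope 1/(fa*Ksv);
* ``lineweaver_burk`` — mean intensity F(C) = F0 / (1 + KA * C**n), whose
  transform lg((F0-F)/F) vs lg C is an exact line with intercept lg KA and
  slope n.

The two models are incompatible in general; pair each fitter with its
matching generator (cross-model fits are a robustness exercise only).
Noise is multiplicative Gaussian on F (a shot/gain approximation), with
an additive option.

The default concentration ladder reproduces a volume-mixing protocol in
which 5 mL of 1e-3 mol/L protein stock is mixed with 0, 1, 5, 10, 15, 20
and 30 mL of 1e-3 mol/L ligand stock, giving ligand concentrations from
0 to ~8.6e-4 mol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .exceptions import DomainError, ValidationError
from .spectra import EEM, EmissionScan
from .titration import TitrationSeries

__all__ = [
    "TitrationSimConfig",
    "EEMSimConfig",
    "GaussianPeak",
    "mixing_concentrations",
    "default_concentration_ladder",
    "simulate_titration_sv",
    "simulate_titration_lb",
    "simulate_titration_scans",
    "simulate_eem",
    "series_from_sv_line",
    "series_from_lb_line",
    "hsa_eem_config",
    "DEFAULT_STOCK_MOL_PER_L",
    "DEFAULT_LIGAND_VOLUMES_ML",
]

DEFAULT_STOCK_MOL_PER_L = 1e-3
DEFAULT_PROTEIN_VOLUME_ML = 5.0
#: ligand stock volumes (mL) of the 5:0 ... 5:30 mixing ladder
DEFAULT_LIGAND_VOLUMES_ML = (0.0, 1.0, 5.0, 10.0, 15.0, 20.0, 30.0)


def mixing_concentrations(v_protein: float, v_ligand: float,
                          stock_protein: float = DEFAULT_STOCK_MOL_PER_L,
                          stock_ligand: float = DEFAULT_STOCK_MOL_PER_L,
                          ) -> tuple[float, float]:
    """Post-mixing molar concentrations when two stocks are combined.

    ``c = stock * v / (v_protein + v_ligand)`` for each species.
    """
    if v_protein < 0 or v_ligand < 0:
        raise DomainError("volumes must be >= 0")
    total = v_protein + v_ligand
    if total == 0:
        raise DomainError("total volume is zero")
    if stock_protein <= 0 or stock_ligand <= 0:
        raise DomainError("stock concentrations must be > 0")
    return (stock_protein * v_protein / total, stock_ligand * v_ligand / total)


def default_concentration_ladder() -> np.ndarray:
    """Ligand molar concentrations of the default 7-point mixing ladder."""
    return np.array([
        mixing_concentrations(DEFAULT_PROTEIN_VOLUME_ML, v)[1]
        for v in DEFAULT_LIGAND_VOLUMES_ML
    ])


@dataclass(frozen=True)
class TitrationSimConfig:
    """Parameters of a simulated quenching titration.

    Parameters
    ----------
    model : {"modified_sv", "lineweaver_burk"}
    f0 : float
        Unquenched intensity (arbitrary units), > 0.
    fa, ksv : float
        Accessible fraction and quenching constant (L/mol); required for
        ``modified_sv``.
    ka, n_sites : float
        Binding constant (L/mol) and site number; required for
        ``lineweaver_burk``.
    conc_ladder : sequence of float
        Ligand concentrations (mol/L) starting at 0, then strictly
        increasing.  Defaults to the 5:0 ... 5:30 mixing ladder.
    noise_sigma : float
        Relative standard deviation of multiplicative Gaussian noise on F.
    noise_kind : {"multiplicative", "additive"}
        Additive noise uses ``noise_sigma * f0`` as absolute sigma.
    seed : int
    ligand_id : str
    """

    model: Literal["modified_sv", "lineweaver_burk"]
    f0: float = 1000.0
    fa: float | None = None
    ksv: float | None = None
    ka: float | None = None
    n_sites: float | None = None
    conc_ladder: Sequence[float] | None = None
    noise_sigma: float = 0.0
    noise_kind: Literal["multiplicative", "additive"] = "multiplicative"
    seed: int = 0
    ligand_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.model not in ("modified_sv", "lineweaver_burk"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.f0 <= 0:
            raise ValidationError("f0 must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.model == "modified_sv":
            if self.fa is None or self.ksv is None:
                raise ValidationError("modified_sv needs fa and ksv")
            if self.fa < 0 or self.ksv <= 0:
                raise ValidationError("fa must be >= 0 and ksv > 0")
        else:
            if self.ka is None or self.n_sites is None:
                raise ValidationError("lineweaver_burk needs ka and n_sites")
            if self.ka < 0 or self.n_sites <= 0:
                raise ValidationError("ka must be >= 0 and n_sites > 0")
        ladder = np.asarray(
            self.conc_ladder if self.conc_ladder is not None
            else default_concentration_ladder(), dtype=float)
        if ladder[0] != 0 or np.any(np.diff(ladder) <= 0):
            raise ValidationError(
                "conc_ladder must start at 0 and then strictly increase")
        object.__setattr__(self, "conc_ladder", ladder)


def _apply_noise(f: np.ndarray, cfg: TitrationSimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_sigma == 0:
        return f
    if cfg.noise_kind == "multiplicative":
        noisy = f * (1.0 + rng.normal(0.0, cfg.noise_sigma, size=f.shape))
    else:
        noisy = f + rng.normal(0.0, cfg.noise_sigma * cfg.f0, size=f.shape)
    if np.any(noisy <= 0):
        raise ValidationError(
            "noise drove an intensity to <= 0; reduce noise_sigma")
    return noisy


def _sv_mean(cfg: TitrationSimConfig, c: np.ndarray) -> np.ndarray:
    quench = cfg.fa * cfg.ksv * c / (1.0 + cfg.ksv * c)
    if np.any(quench >= 1.0):
        raise ValidationError(
            "fa*Ksv*C/(1+Ksv*C) >= 1 at some C: mean intensity non-positive; "
            "lower fa, Ksv or the top of the ladder")
    return cfg.f0 * (1.0 - quench)


def _lb_mean(cfg: TitrationSimConfig, c: np.ndarray) -> np.ndarray:
    out = np.full_like(c, cfg.f0)
    nz = c > 0
    out[nz] = cfg.f0 / (1.0 + cfg.ka * np.power(c[nz], cfg.n_sites))
    return out


def simulate_titration_sv(config: TitrationSimConfig) -> TitrationSeries:
    """Titration series under the modified Stern-Volmer quenching model.

    Noiseless output transforms to an exact line: fitting it with
    :class:`~quenchfit.models.ModifiedSternVolmer` returns the generator's
    (fa, Ksv) to floating-point accuracy.
    """
    if config.model != "modified_sv":
        raise ValidationError("config.model must be 'modified_sv'")
    c = np.asarray(config.conc_ladder, float)
    f = _sv_mean(config, c)
    f = _apply_noise(f, config, np.random.default_rng(config.seed))
    return TitrationSeries(config.ligand_id, c, f)


def simulate_titration_lb(config: TitrationSimConfig) -> TitrationSeries:
    """Titration series under the 1:n static-binding (double-log) model."""
    if config.model != "lineweaver_burk":
        raise ValidationError("config.model must be 'lineweaver_burk'")
    c = np.asarray(config.conc_ladder, float)
    f = _lb_mean(config, c)
    f = _apply_noise(f, config, np.random.default_rng(config.seed))
    return TitrationSeries(config.ligand_id, c, f)


DEFAULT_SCAN_GRID = np.arange(285.0, 430.0 + 1e-9, 5.0)


def simulate_titration_scans(config: TitrationSimConfig,
                             peak0_nm: float = 335.0,
                             peak_shift_total_nm: float = -25.0,
                             peak_width_nm: float = 20.0,
                             scan_grid: np.ndarray | None = None,
                             ) -> TitrationSeries:
    """Titration series carrying one Gaussian emission scan per point.

    Each scan is a Gaussian whose height equals that point's scalar
    intensity and whose centre moves linearly with the quenched fraction,
    from ``peak0_nm`` at C = 0 to ``peak0_nm + peak_shift_total_nm`` at the
    most-quenched point — the blue shift a binding titration shows when
    the fluorophore's microenvironment becomes less polar.
    """
    if peak_width_nm <= 0:
        raise DomainError("peak_width_nm must be > 0")
    grid = DEFAULT_SCAN_GRID if scan_grid is None else np.asarray(scan_grid, float)
    c = np.asarray(config.conc_ladder, float)
    mean = _sv_mean(config, c) if config.model == "modified_sv" else _lb_mean(config, c)
    f = _apply_noise(mean.copy(), config, np.random.default_rng(config.seed))

    # centres follow the noiseless quenched fraction, scaled so the
    # most-quenched rung reaches the full stated shift
    quenched = 1.0 - mean / config.f0
    max_quench = quenched.max()
    frac = quenched / max_quench if max_quench > 0 else np.zeros_like(quenched)
    centers = peak0_nm + peak_shift_total_nm * frac

    scans = []
    for amp, center in zip(f, centers):
        profile = amp * np.exp(-((grid - center) ** 2) / (2.0 * peak_width_nm ** 2))
        scans.append(EmissionScan(grid, profile))
    scalar = np.array([s.intensities.max() for s in scans])
    return TitrationSeries(config.ligand_id, c, scalar, tuple(scans))


# ---------------------------------------------------------------------------
# EEMs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianPeak:
    """A separable 2-D Gaussian fluorescence peak in an EEM."""

    excitation_nm: float
    emission_nm: float
    amplitude: float
    width_ex_nm: float = 12.0
    width_em_nm: float = 12.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("peak amplitude must be >= 0")
        if self.width_ex_nm <= 0 or self.width_em_nm <= 0:
            raise ValidationError("peak widths must be > 0")


@dataclass(frozen=True)
class EEMSimConfig:
    """Parameters of a simulated excitation-emission matrix.

    The Rayleigh ridge is a Gaussian of cross-width ``rayleigh_width_nm``
    around lambda_ex = lambda_em, modulated along the diagonal by a
    Gaussian profile centred at ``rayleigh_center_nm`` so the ridge has a
    single well-defined maximum.  ``baseline_sigma`` adds clipped
    (non-negative) Gaussian baseline noise.
    """

    peaks: tuple[GaussianPeak, ...] = ()
    rayleigh_amplitude: float = 0.0
    rayleigh_width_nm: float = 8.0
    rayleigh_center_nm: float = 290.0
    rayleigh_profile_width_nm: float = 30.0
    baseline_sigma: float = 0.0
    excitation_grid: Sequence[float] | None = None
    emission_grid: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rayleigh_amplitude < 0:
            raise ValidationError("rayleigh_amplitude must be >= 0")
        if self.rayleigh_width_nm <= 0 or self.rayleigh_profile_width_nm <= 0:
            raise ValidationError("ridge widths must be > 0")
        if self.baseline_sigma < 0:
            raise ValidationError("baseline_sigma must be >= 0")
        ex = (np.arange(200.0, 340.0 + 1e-9, 5.0)
              if self.excitation_grid is None
              else np.asarray(self.excitation_grid, float))
        em = (np.arange(270.0, 460.0 + 1e-9, 5.0)
              if self.emission_grid is None
              else np.asarray(self.emission_grid, float))
        object.__setattr__(self, "excitation_grid", ex)
        object.__setattr__(self, "emission_grid", em)
        object.__setattr__(self, "peaks", tuple(self.peaks))


def simulate_eem(config: EEMSimConfig) -> EEM:
    """Sum of separable Gaussian peaks plus a first-order Rayleigh ridge."""
    ex = config.excitation_grid[:, None]
    em = config.emission_grid[None, :]
    z = np.zeros((config.excitation_grid.size, config.emission_grid.size))
    for p in config.peaks:
        z += p.amplitude * np.exp(
            -((ex - p.excitation_nm) ** 2) / (2 * p.width_ex_nm ** 2)
            - ((em - p.emission_nm) ** 2) / (2 * p.width_em_nm ** 2))
    if config.rayleigh_amplitude > 0:
        cross = np.exp(-((ex - em) ** 2) / (2 * config.rayleigh_width_nm ** 2))
        along = np.exp(-(((ex + em) / 2 - config.rayleigh_center_nm) ** 2)
                       / (2 * config.rayleigh_profile_width_nm ** 2))
        z += config.rayleigh_amplitude * cross * along
    if config.baseline_sigma > 0:
        rng = np.random.default_rng(config.seed)
        z = np.clip(z + rng.normal(0.0, config.baseline_sigma, z.shape), 0.0, None)
    return EEM(config.excitation_grid, config.emission_grid, z)


def hsa_eem_config(baseline_sigma: float = 0.0, seed: int = 0) -> EEMSimConfig:
    """Preset emulating the intrinsic fluorescence landscape of HSA.

    Two fluorescence peaks — the peptide-backbone peak at
    (lambda_ex 235, lambda_em 325) nm with amplitude 362.3 and the
    tryptophan/tyrosine peak at (280, 335) nm with amplitude 1803 — plus a
    first-order Rayleigh ridge peaking at 290 nm with amplitude 1058.
    """
    return EEMSimConfig(
        peaks=(
            GaussianPeak(235.0, 325.0, 362.3),
            GaussianPeak(280.0, 335.0, 1803.0),
        ),
        rayleigh_amplitude=1058.0,
        baseline_sigma=baseline_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Series reconstructed from published fitted lines
# ---------------------------------------------------------------------------

def series_from_sv_line(slope: float, intercept: float, *, f0: float = 1000.0,
                        conc_ladder: Sequence[float] | None = None,
                        ligand_id: str = "from_line") -> TitrationSeries:
    """Noiseless series whose Stern-Volmer transform lies exactly on a line.

    Inverts ``F0/(F0-F) = slope/C + intercept`` point-wise, so refitting
    recovers ``slope`` and ``intercept`` to floating-point accuracy.  The
    line must give y > 1 at every rung (F between 0 and F0).
    """
    c = (default_concentration_ladder() if conc_ladder is None
         else np.asarray(conc_ladder, float))
    nz = c[c > 0]
    y = slope / nz + intercept
    if np.any(y <= 1):
        raise DomainError(
            "line gives F0/(F0-F) <= 1 at some rung; shrink the ladder")
    f = f0 * (1.0 - 1.0 / y)
    return TitrationSeries(ligand_id, c, np.concatenate([[f0], f]))


def series_from_lb_line(n_sites: float, lg_ka: float, *, f0: float = 1000.0,
                        conc_ladder: Sequence[float] | None = None,
                        ligand_id: str = "from_line") -> TitrationSeries:
    """Noiseless series whose double-log transform lies exactly on a line.

    Inverts ``lg((F0-F)/F) = n_sites * lg C + lg_ka`` point-wise.
    """
    c = (default_concentration_ladder() if conc_ladder is None
         else np.asarray(conc_ladder, float))
    nz = c[c > 0]
    ratio = 10.0 ** (n_sites * np.log10(nz) + lg_ka)  # (F0-F)/F
    f = f0 / (1.0 + ratio)
    return TitrationSeries(ligand_id, c, np.concatenate([[f0], f]))
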