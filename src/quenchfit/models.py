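"""Quenching and binding models fitted to titration data.

Two linearized models drive the analysis of a fluorescence quenching
titration of a protein (fluorophore) by a small-molecule quencher:

**Modified Stern-Volmer.**  With F0 the unquenched intensity, F the
intensity at quencher concentration C, fa the fraction of fluorophores
accessible to the quencher and K_SV' the effective quenching constant,

    F0 / (F0 - F) = 1 / (fa * K_SV' * C) + 1 / fa

so an ordinary least-squares line of y = F0/(F0-F) against x = 1/C has
intercept 1/fa and slope 1/(fa*K_SV'); hence fa = 1/intercept and
K_SV' = intercept/slope.  Dividing K_SV' by the unquenched lifetime tau0
(~1e-8 s for biopolymers) gives the bimolecular quenching rate constant
Kq = K_SV'/tau0.  Kq above the diffusion-collision ceiling of about
2.0e10 L/(mol*s) cannot arise from collisional (dynamic) quenching and
indicates ground-state complex formation (static quenching).

**Double-logarithmic (Lineweaver-Burk-type) binding isotherm.**  For
independent binding to n equivalent sites with association constant KA,

    lg((F0 - F) / F) = lg KA + n * lg C

so the log-log line's slope is the apparent site number n and its
intercept is lg KA.

Both fits are exposed statsmodels-style: a model object built from a
:class:`~quenchfit.titration.TitrationSeries`, whose ``fit()`` returns a
results object with estimates, standard errors, R^2 and a ``summary()``
table.  Thin functional wrappers (`fit_modified_stern_volmer`,
`fit_lineweaver_burk`) cover script use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .exceptions import DomainError, FitInvalidError, InsufficientDataError
from .titration import TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ols_line",
    "ModifiedSternVolmer",
    "SternVolmerResults",
    "LineweaverBurk",
    "BindingResults",
    "QuenchMechanism",
    "fit_modified_stern_volmer",
    "fit_lineweaver_burk",
    "derive_sv_constants",
    "classify_quenching",
    "DEFAULT_TAU0_S",
    "DYNAMIC_QUENCHING_CEILING",
]

#: unquenched fluorescence lifetime assumed for biopolymers (s)
DEFAULT_TAU0_S = 1e-8
#: maximum diffusion-limited collisional quenching rate constant, L/(mol*s);
#: Kq above this is taken as evidence of static quenching
DYNAMIC_QUENCHING_CEILING = 2.0e10


class _OLSFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    intercept_stderr: float


def _ols(x: np.ndarray, y: np.ndarray) -> _OLSFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 points for a line fit, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise DomainError("x values are all equal; slope undefined")
    if np.ptp(y) == 0:
        # SS_tot = 0: a horizontal line fits exactly; R^2 := 1 by convention
        return _OLSFit(0.0, float(y[0]), 1.0, 0.0, 0.0)
    res = stats.linregress(x, y)
    return _OLSFit(float(res.slope), float(res.intercept), float(res.rvalue) ** 2,
                   float(res.stderr), float(res.intercept_stderr))


def ols_line(x, y) -> tuple[float, float, float]:
    """Ordinary least squares line; returns ``(slope, intercept, r_squared)``.

    ``r_squared = 1 - SS_res/SS_tot``; a constant-``y`` input has
    ``SS_tot = 0`` and returns slope 0 with ``r_squared = 1.0`` (the
    horizontal line reproduces the data exactly).
    """
    fit = _ols(np.asarray(x, float), np.asarray(y, float))
    return fit.slope, fit.intercept, fit.r_squared


def derive_sv_constants(slope: float, intercept: float,
                        tau0: float = DEFAULT_TAU0_S) -> tuple[float, float, float]:
    """Accessible fraction, quenching constant and rate constant from a fitted line.

    Parameters
    ----------
    slope, intercept : float
        Coefficients of the modified Stern-Volmer line
        ``F0/(F0-F) = slope * (1/C) + intercept``; both must be > 0.
    tau0 : float
        Unquenched lifetime in seconds (default 1e-8).

    Returns
    -------
    (fa, ksv_prime, kq)
        ``fa = 1/intercept`` (accessible fraction),
        ``ksv_prime = intercept/slope`` in L/mol,
        ``kq = ksv_prime/tau0`` in L/(mol*s).
    """
    if slope <= 0 or intercept <= 0 or tau0 <= 0:
        raise DomainError("slope, intercept and tau0 must all be > 0")
    fa = 1.0 / intercept
    ksv_prime = intercept / slope
    return fa, ksv_prime, ksv_prime / tau0


@dataclass(frozen=True)
class QuenchMechanism:
    """Static/dynamic call from the bimolecular quenching rate constant."""

    label: str  # "static" or "dynamic_consistent"
    kq: float
    threshold: float = DYNAMIC_QUENCHING_CEILING

    @property
    def is_static(self) -> bool:
        return self.label == "static"


def classify_quenching(kq: float,
                       threshold: float = DYNAMIC_QUENCHING_CEILING) -> QuenchMechanism:
    """Classify the quenching mechanism from Kq.

    ``static`` iff ``kq > threshold`` (strict: a Kq exactly at the
    diffusion ceiling is still consistent with dynamic quenching).
    """
    if kq <= 0:
        raise DomainError("kq must be > 0")
    label = "static" if kq > threshold else "dynamic_consistent"
    return QuenchMechanism(label=label, kq=float(kq), threshold=float(threshold))


def _usable_points(series: TitrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Points with C > 0 and F < F0; others cannot enter either transform."""
    c = series.concentrations
    f = series.intensities
    f0 = series.f0
    mask = (c > 0) & (f < f0)
    n_dropped = int(np.sum((c > 0) & (f >= f0)))
    if n_dropped:
        logger.warning(
            "series %s: dropped %d point(s) with F >= F0 (no quench signal)",
            series.ligand_id, n_dropped,
        )
    return c[mask], f[mask]


# ---------------------------------------------------------------------------
# Modified Stern-Volmer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SternVolmerResults:
    """Results of a modified Stern-Volmer fit.

    Attributes
    ----------
    slope : float
        Slope of F0/(F0-F) vs 1/C, units mol/L.
    intercept : float
        Dimensionless intercept (= 1/fa).
    r_squared : float
    fa : float
        Accessible fraction of fluorophores, 1/intercept.
    ksv_prime : float
        Effective quenching constant, L/mol.
    tau0 : float
        Lifetime used, s.
    kq : float
        Bimolecular quenching rate constant, L/(mol*s).
    slope_stderr, intercept_stderr : float
        OLS standard errors of the line coefficients.
    n_points_used : int
    ligand_id : str
    """

    ligand_id: str
    slope: float
    intercept: float
    r_squared: float
    fa: float
    ksv_prime: float
    tau0: float
    kq: float
    slope_stderr: float
    intercept_stderr: float
    n_points_used: int

    def __post_init__(self) -> None:
        # algebraic self-consistency of the derived constants
        if not math.isclose(self.kq * self.tau0 * self.slope, self.intercept,
                            rel_tol=1e-9):
            raise FitInvalidError("inconsistent Kq/tau0/slope/intercept")
        if not math.isclose(self.fa * self.intercept, 1.0, rel_tol=1e-9):
            raise FitInvalidError("fa is not the reciprocal of the intercept")
        if self.n_points_used < 3:
            raise InsufficientDataError("results built from < 3 points")

    @property
    def mechanism(self) -> QuenchMechanism:
        return classify_quenching(self.kq)

    @property
    def fitted_equation(self) -> str:
        return f"y = {self.slope:.7g}x + {self.intercept:.4g}"

    def summary(self) -> str:
        m = self.mechanism
        lines = [
            "Modified Stern-Volmer fit",
            "=" * 52,
            f"ligand:            {self.ligand_id}",
            f"points used:       {self.n_points_used}",
            f"fitted line:       {self.fitted_equation}   (y = F0/(F0-F), x = 1/C)",
            f"R^2:               {self.r_squared:.4f}",
            f"slope (mol/L):     {self.slope:.6g} +/- {self.slope_stderr:.2g}",
            f"intercept:         {self.intercept:.6g} +/- {self.intercept_stderr:.2g}",
            f"fa (accessible):   {self.fa:.4f}",
            f"K_SV' (L/mol):     {self.ksv_prime:.6g}",
            f"tau0 (s):          {self.tau0:.3g}",
            f"Kq (L/mol/s):      {self.kq:.3g}",
            f"mechanism:         {m.label} (threshold {m.threshold:.2g} L/mol/s)",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ligand_id": self.ligand_id, "model": "modified_stern_volmer",
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "fa": self.fa,
            "ksv_prime_L_per_mol": self.ksv_prime, "tau0_s": self.tau0,
            "kq_L_per_mol_s": self.kq, "mechanism": self.mechanism.label,
            "n_points_used": self.n_points_used,
        }


class ModifiedSternVolmer:
    """Modified Stern-Volmer quenching model for one titration series.

    Parameters
    ----------
    series : TitrationSeries
    tau0 : float
        Unquenched fluorophore lifetime in seconds; 1e-8 s is the standard
        biopolymer value.

    Examples
    --------
    >>> model = ModifiedSternVolmer(series, tau0=1e-8)
    >>> res = model.fit()
    >>> res.kq, res.mechanism.label
    """

    def __init__(self, series: TitrationSeries, tau0: float = DEFAULT_TAU0_S):
        if tau0 <= 0:
            raise DomainError("tau0 must be > 0")
        self.series = series
        self.tau0 = float(tau0)

    @classmethod
    def from_dataframe(cls, df, ligand_id=None, tau0: float = DEFAULT_TAU0_S):
        return cls(TitrationSeries.from_dataframe(df, ligand_id), tau0=tau0)

    def transform(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) = (1/C, F0/(F0-F)) over the usable points."""
        c, f = _usable_points(self.series)
        if c.size < 3:
            raise InsufficientDataError(
                f"series {self.series.ligand_id!r}: only {c.size} usable point(s) "
                "(need C > 0 and F < F0 at >= 3 points)"
            )
        f0 = self.series.f0
        return 1.0 / c, f0 / (f0 - f)

    def fit(self) -> SternVolmerResults:
        x, y = self.transform()
        fit = _ols(x, y)
        if fit.slope <= 0 or fit.intercept <= 0:
            raise FitInvalidError(
                f"series {self.series.ligand_id!r}: non-positive slope or intercept "
                f"({fit.slope:.4g}, {fit.intercept:.4g}) — quenching model violated"
            )
        fa, ksv_prime, kq = derive_sv_constants(fit.slope, fit.intercept, self.tau0)
        if fa > 1:
            logger.warning(
                "series %s: accessible fraction fa = %.3f exceeds 1 "
                "(intercept < 1); reported unconstrained", self.series.ligand_id, fa,
            )
        return SternVolmerResults(
            ligand_id=self.series.ligand_id, slope=fit.slope,
            intercept=fit.intercept, r_squared=fit.r_squared, fa=fa,
            ksv_prime=ksv_prime, tau0=self.tau0, kq=kq,
            slope_stderr=fit.slope_stderr, intercept_stderr=fit.intercept_stderr,
            n_points_used=x.size,
        )

    def plot(self, results: SternVolmerResults | None = None, ax=None):
        """Diagnostic plot of the transformed data and fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.transform()
        ax.plot(x, y, "o", label="data")
        if results is not None:
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, results.slope * xs + results.intercept, "-",
                    label=results.fitted_equation)
        ax.set_xlabel("1/C (L/mol)")
        ax.set_ylabel("F0 / (F0 - F)")
        ax.set_title(f"Modified Stern-Volmer: {self.series.ligand_id}")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Double-logarithmic binding isotherm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingResults:
    """Results of the double-logarithmic binding fit.

    ``n_sites`` is the slope (apparent number of binding sites), ``lg_ka``
    the intercept and ``ka = 10**lg_ka`` the association constant, reported
    in nominal L/mol.
    """

    ligand_id: str
    n_sites: float
    lg_ka: float
    ka: float
    r_squared: float
    slope_stderr: float
    intercept_stderr: float
    n_points_used: int

    def __post_init__(self) -> None:
        if not math.isclose(self.ka, 10.0 ** self.lg_ka, rel_tol=1e-12):
            raise FitInvalidError("ka must equal 10**lg_ka")
        if self.n_points_used < 3:
            raise InsufficientDataError("results built from < 3 points")

    @property
    def fitted_equation(self) -> str:
        return f"y = {self.n_sites:.4g}x + {self.lg_ka:.5g}"

    def summary(self) -> str:
        lines = [
            "Double-logarithmic binding fit",
            "=" * 52,
            f"ligand:            {self.ligand_id}",
            f"points used:       {self.n_points_used}",
            f"fitted line:       {self.fitted_equation}   (y = lg((F0-F)/F), x = lg C)",
            f"R^2:               {self.r_squared:.4f}",
            f"n (sites):         {self.n_sites:.4f} +/- {self.slope_stderr:.2g}",
            f"lg KA:             {self.lg_ka:.4f} +/- {self.intercept_stderr:.2g}",
            f"KA (L/mol):        {self.ka:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ligand_id": self.ligand_id, "model": "double_log_binding",
            "n_sites": self.n_sites, "lg_ka": self.lg_ka, "ka_L_per_mol": self.ka,
            "r_squared": self.r_squared, "n_points_used": self.n_points_used,
        }


class LineweaverBurk:
    """Double-logarithmic (Lineweaver-Burk-type) binding model.

    Fits ``lg((F0-F)/F)`` against ``lg C`` to estimate the binding
    constant KA and apparent site number n for one titration series.
    """

    def __init__(self, series: TitrationSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df, ligand_id=None):
        return cls(TitrationSeries.from_dataframe(df, ligand_id))

    def transform(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) = (lg C, lg((F0-F)/F)) over the usable points."""
        c, f = _usable_points(self.series)
        if c.size < 3:
            raise InsufficientDataError(
                f"series {self.series.ligand_id!r}: only {c.size} usable point(s) "
                "(need C > 0 and F < F0 at >= 3 points)"
            )
        f0 = self.series.f0
        return np.log10(c), np.log10((f0 - f) / f)

    def fit(self) -> BindingResults:
        x, y = self.transform()
        fit = _ols(x, y)
        if fit.slope <= 0:
            raise FitInvalidError(
                f"series {self.series.ligand_id!r}: non-positive site number "
                f"({fit.slope:.4g}) — binding model violated"
            )
        return BindingResults(
            ligand_id=self.series.ligand_id, n_sites=fit.slope,
            lg_ka=fit.intercept, ka=10.0 ** fit.intercept,
            r_squared=fit.r_squared, slope_stderr=fit.slope_stderr,
            intercept_stderr=fit.intercept_stderr, n_points_used=x.size,
        )

    def plot(self, results: BindingResults | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.transform()
        ax.plot(x, y, "o", label="data")
        if results is not None:
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, results.n_sites * xs + results.lg_ka, "-",
                    label=results.fitted_equation)
        ax.set_xlabel("lg C")
        ax.set_ylabel("lg((F0 - F)/F)")
        ax.set_title(f"Double-log binding: {self.series.ligand_id}")
        ax.legend()
        return ax


def fit_modified_stern_volmer(series: TitrationSeries,
                              tau0: float = DEFAULT_TAU0_S) -> SternVolmerResults:
    """Fit the modified Stern-Volmer model to a titration series."""
    return ModifiedSternVolmer(series, tau0=tau0).fit()


def fit_lineweaver_burk(series: TitrationSeries) -> BindingResults:
    """Fit the double-logarithmic binding model to a titration series."""
    return LineweaverBurk(series).fit()
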