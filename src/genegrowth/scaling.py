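"""Taylor's law, the growth laws, and the critical point.

Two empirical growth laws (exponential mean, linear mean-log) and the
lognormality of within-species length distributions pin down a Taylor
fluctuation-scaling law between per-species mean and second raw moment,

    <L^2> = sigma^2 + <L>^2 = a * <L>^beta,

with the bridge relations

    beta = 4 - 2 <log zeta> / (<zeta> - 1),
    a    = L0^(4 - beta) * exp(-2 G0).

(The prefactor follows from the lognormal moment identity
``<L^2> = <L>^4 exp(-2 <log L>)``: substituting the growth laws for
``<L>`` and ``<log L>`` and eliminating t gives ``exp(2 G0)`` in the
denominator; this reading also reproduces the reference value a = 0.21
from (L0=554, G0=6.18, beta=2.29).)

The algorithmic-complexity profile ``tau(L) = t(L)/L`` (evolutionary time
per base pair of mean gene length) is maximal where ``d tau/dL = 0``,
giving the critical mean gene length ``Lc = e * L0`` and, inverting the
mean growth law, the critical epoch ``tc = 1/(<zeta> - 1)`` sweeps (My)
after LUCA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from genegrowth.lengthstats import SpeciesSummary

logger = logging.getLogger(__name__)


@dataclass
class GrowthParams:
    """Parameters of the two gene-growth laws.

    ``L0`` (bp) and ``G0`` (dimensionless) are the mean gene length and the
    mean natural-log gene length of LUCA's genome; ``mean_zeta`` and
    ``meanlog_zeta`` are the mean and mean log of the stochastic
    multiplicative growth factor, with time measured in sweeps (My).
    """

    mean_zeta: float
    meanlog_zeta: float
    L0: float
    G0: float

    def validate(self) -> "GrowthParams":
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.mean_zeta <= 1.0:
            raise ValueError("growth regime requires <zeta> > 1")
        if not (0 < self.meanlog_zeta <= self.mean_zeta - 1.0):
            raise ValueError("need 0 < <log zeta> <= <zeta> - 1 (Jensen)")
        if math.log(self.L0) < self.G0:
            raise ValueError("need ln L0 >= G0 (Jensen)")
        return self

    @property
    def is_growth(self) -> bool:
        return self.mean_zeta > 1.0


#: reference estimates of the growth-law parameters for the empirical gene
#: corpus: LUCA mean gene length 554 bp, LUCA mean log-length 6.18, and the
#: multiplicative-factor moments fitted with time in My
REFERENCE_PARAMS = GrowthParams(mean_zeta=1.00101, meanlog_zeta=0.00087, L0=554.0, G0=6.18)

#: reference Taylor-law fit (second-raw-moment form) for the gene corpus
REFERENCE_TAYLOR = {"a": 0.21, "beta": 2.29}

#: adopted age of LUCA, in My
LUCA_AGE_MY = 3600.0

#: modern human mean gene length, bp
HUMAN_MEAN_GENE_LEN = 68287.0


@dataclass
class TaylorFit:
    """Power-law fit ``y = a * <L>^beta`` on log-log axes."""

    a: float
    beta: float
    r2: float
    form: str  # "raw_moment" | "variance"
    n: int


def _loglog_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of log y on log x; returns (intercept, slope, r2)."""
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise ValueError("degenerate input: all means identical, no spread to fit")
    A = np.column_stack([np.ones_like(lx), lx])
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
    resid = ly - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(coef[0]), float(coef[1]), r2


def fit_taylor(summaries: list[SpeciesSummary], form: str = "raw_moment") -> TaylorFit:
    """Fit Taylor's law across species by log-log least squares.

    ``form="raw_moment"`` regresses ``log <L^2>`` on ``log <L>``;
    ``form="variance"`` regresses ``log sigma^2`` (zero-variance species
    are excluded with a warning).  ``a = exp(intercept)``, ``beta`` is the
    slope, and ``r2`` refers to the log-log regression.
    """
    if form not in ("raw_moment", "variance"):
        raise ValueError("form must be 'raw_moment' or 'variance'")
    means = np.array([s.mean for s in summaries], dtype=float)
    if form == "raw_moment":
        y = np.array([s.second_raw_moment for s in summaries], dtype=float)
    else:
        y = np.array([s.var for s in summaries], dtype=float)
        keep = y > 0
        if not keep.all():
            logger.warning("fit_taylor: excluding %d zero-variance species", int((~keep).sum()))
        means, y = means[keep], y[keep]
    if means.size < 2:
        raise ValueError("need at least two usable species summaries")
    intercept, slope, r2 = _loglog_ols(means, y)
    return TaylorFit(a=math.exp(intercept), beta=slope, r2=r2, form=form, n=means.size)


def fit_growth_laws(
    group_points: np.ndarray | list[tuple[float, float, float]],
) -> tuple[GrowthParams, dict[str, float]]:
    """Fit the two growth laws to group-averaged points.

    ``group_points`` rows are ``(t, mean_len, mean_log_len)`` with t in My
    after LUCA.  OLS of ``ln(mean_len)`` on t gives ``ln L0`` (intercept)
    and ``<zeta> - 1`` (slope); OLS of ``mean_log_len`` on t gives ``G0``
    and ``<log zeta>``.  Returns the parameters plus diagnostics
    (per-fit R^2 and a ``growth`` flag; non-growth fits — slope <= 0 — are
    flagged rather than raised so callers can inspect them).
    """
    pts = np.asarray(group_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("group_points must be (t, mean_len, mean_log_len) rows")
    if pts.shape[0] < 3:
        raise ValueError("need at least three group points")
    t, mean_len, mean_log = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.any(mean_len <= 0):
        raise ValueError("mean lengths must be positive")
    if np.ptp(t) == 0:
        raise ValueError("group times must not all coincide")

    def _ols(y: np.ndarray) -> tuple[float, float, float]:
        A = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot
        return float(coef[0]), float(coef[1]), r2

    lnL0, rate, r2_mean = _ols(np.log(mean_len))
    G0, meanlog_zeta, r2_log = _ols(mean_log)
    params = GrowthParams(
        mean_zeta=1.0 + rate, meanlog_zeta=meanlog_zeta, L0=math.exp(lnL0), G0=G0
    )
    diagnostics = {"r2_mean": r2_mean, "r2_log": r2_log, "growth": params.is_growth}
    if not params.is_growth:
        logger.warning("fit_growth_laws: non-growth parameters (<zeta> <= 1)")
    return params, diagnostics


def beta_from_growth(params: GrowthParams) -> float:
    """Taylor exponent from the growth-law parameters:
    ``beta = 4 - 2 <log zeta>/(<zeta> - 1)``."""
    if params.mean_zeta == 1.0:
        raise ValueError("beta undefined at <zeta> = 1 (division by zero)")
    return 4.0 - 2.0 * params.meanlog_zeta / (params.mean_zeta - 1.0)


def a_from_growth(L0: float, G0: float, beta: float) -> float:
    """Taylor prefactor from the growth-law parameters:
    ``a = L0^(4 - beta) * exp(-2 G0)``."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    return L0 ** (4.0 - beta) * math.exp(-2.0 * G0)


def invert_eq5(
    a: float,
    beta: float,
    L0: float | None = None,
    G0: float | None = None,
    mean_zeta: float | None = None,
) -> dict[str, float]:
    """Complete the growth-law parameters from a fitted Taylor law.

    Given ``(a, beta)`` and one of the pair ``(L0, G0)``, solve
    ``a = L0^(4-beta) exp(-2 G0)`` for the other; if ``mean_zeta`` is also
    given, recover ``<log zeta> = (4 - beta)(<zeta> - 1)/2``.  The
    inversion is informative for ``2 < beta < 4``; at ``beta = 4`` the
    prefactor no longer depends on L0, which is then unidentifiable.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if (L0 is None) == (G0 is None):
        raise ValueError("provide exactly one of L0, G0")
    out: dict[str, float] = {"a": a, "beta": beta}
    if L0 is not None:
        if L0 <= 0:
            raise ValueError("L0 must be positive")
        out["L0"] = L0
        out["G0"] = 0.5 * ((4.0 - beta) * math.log(L0) - math.log(a))
    else:
        if beta == 4.0:
            raise ValueError("L0 unidentifiable at beta = 4")
        out["G0"] = G0
        out["L0"] = (a * math.exp(2.0 * G0)) ** (1.0 / (4.0 - beta))
    if mean_zeta is not None:
        out["mean_zeta"] = mean_zeta
        out["meanlog_zeta"] = 0.5 * (4.0 - beta) * (mean_zeta - 1.0)
    return out


def logmean_line(params: GrowthParams) -> tuple[float, float]:
    """Line relating ``ln <L>`` to ``<log L>`` across species.

    Eliminating t between the two growth laws gives
    ``ln <L> = slope * <log L> + intercept`` with
    ``slope = (<zeta> - 1)/<log zeta>`` and
    ``intercept = ln L0 - slope * G0``.
    """
    if params.meanlog_zeta == 0:
        raise ValueError("slope undefined at <log zeta> = 0")
    slope = (params.mean_zeta - 1.0) / params.meanlog_zeta
    return slope, math.log(params.L0) - slope * params.G0


def critical_length(L0: float) -> float:
    """Critical mean gene length ``Lc = e * L0`` (argmax of the tau profile)."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    return math.e * L0


def critical_time(params: GrowthParams, Lc: float | None = None) -> float:
    """Epoch (My after LUCA) at which the mean length first reaches ``Lc``.

    Inverts the exponential mean growth law:
    ``tc = ln(Lc/L0)/(<zeta> - 1)``; for ``Lc = e L0`` (the default) this
    is simply ``1/(<zeta> - 1)``.
    """
    if params.mean_zeta <= 1.0:
        raise ValueError("critical time requires <zeta> > 1")
    if Lc is None:
        Lc = critical_length(params.L0)
    if Lc <= params.L0:
        raise ValueError("Lc must exceed L0")
    return math.log(Lc / params.L0) / (params.mean_zeta - 1.0)


def calendar_date(tc: float, luca_age: float = LUCA_AGE_MY) -> float:
    """Convert an epoch after LUCA to a calendar date in My ago."""
    if not (0 <= tc <= luca_age):
        raise ValueError("tc must lie in [0, luca_age]")
    return luca_age - tc


def tau_profile(
    L_grid: np.ndarray, params: GrowthParams
) -> tuple[np.ndarray, np.ndarray]:
    """Algorithmic-complexity profile ``tau(L) = t(L)/L``.

    ``t(L) = ln(L/L0)/(<zeta>-1)`` is the time to reach mean length L, so
    ``tau(L) = ln(L/L0) / ((<zeta>-1) L)`` — time spent by evolution per
    nucleotide of mean gene length.  Grid points at or below L0 (where tau
    is non-positive) are excluded with a warning.  Returns the kept grid
    and the tau values.
    """
    if params.mean_zeta <= 1.0:
        raise ValueError("tau profile requires <zeta> > 1")
    L = np.asarray(L_grid, dtype=float)
    keep = L > params.L0
    if not keep.all():
        logger.warning("tau_profile: excluding %d grid points <= L0", int((~keep).sum()))
    L = L[keep]
    tau = np.log(L / params.L0) / ((params.mean_zeta - 1.0) * L)
    return L, tau
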