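"""Per-species length moments and right-skewed distribution comparison.

Each species is summarized by the population moments of its length vector
(mean ``<L>``, variance, second raw moment ``<L^2>``, mean natural
log-length ``<log L>``).  Length distributions are compared across six
right-skewed candidate families by maximum likelihood; the family with the
highest total log-likelihood wins (raw log-likelihoods, no information
criteria — all families here have two free parameters except the
one-parameter exponential, which is nested inside gamma and Weibull).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from genegrowth.annotations import LengthSample

#: fixed family order; also the tie-break order in :func:`best_fit`
FAMILIES = ("lognormal", "gamma", "weibull", "exponential", "loglogistic", "gumbel")

_SCIPY_DISTS = {
    "lognormal": st.lognorm,
    "gamma": st.gamma,
    "weibull": st.weibull_min,
    "exponential": st.expon,
    "loglogistic": st.fisk,
    "gumbel": st.gumbel_r,
}


@dataclass
class SpeciesSummary:
    """Population moments of one species' length vector."""

    taxon_id: str
    kind: str
    n: int
    mean: float
    var: float
    second_raw_moment: float
    mean_log: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("variance must be non-negative")


@dataclass
class DistFitResult:
    """Maximum-likelihood fit of one candidate family.

    ``params`` follows the scipy convention for the corresponding
    distribution ``(shape..., loc, scale)``; ``loglik`` is the maximized
    total log-likelihood, ``-inf`` with ``converged=False`` when the fit
    failed or the input is degenerate.
    """

    family: str
    params: tuple
    loglik: float
    converged: bool = True
    message: str = ""


def summarize(
    sample: LengthSample | np.ndarray,
    taxon_id: str = "",
    kind: str = "gene",
    population: bool = True,
) -> SpeciesSummary:
    """Compute the per-species moment summary.

    Population (divide-by-n) moments by default; set ``population=False``
    for the n-1 sample variance.  The log-moment uses natural logarithms.
    """
    if isinstance(sample, LengthSample):
        x = np.asarray(sample.lengths, dtype=float)
        taxon_id, kind = sample.taxon_id, sample.kind
    else:
        x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one length")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    ddof = 0 if population else 1
    mean = float(x.mean())
    var = float(x.var(ddof=ddof)) if x.size > ddof else 0.0
    return SpeciesSummary(
        taxon_id=taxon_id,
        kind=kind,
        n=int(x.size),
        mean=mean,
        var=var,
        second_raw_moment=var + mean * mean if population else float((x * x).mean()),
        mean_log=float(np.log(x).mean()),
    )


def fit_distribution(lengths: np.ndarray, family: str, min_n: int = 20) -> DistFitResult:
    """Maximum-likelihood fit of one family to a length vector.

    The lognormal is fitted in closed form on the log-lengths
    (``mu = mean(log x)``, ``s = std(log x)``); the exponential in closed
    form (scale = sample mean); gamma, Weibull and log-logistic numerically
    with the location pinned at zero (lengths are positive); the Gumbel on
    the raw lengths with free location.  A degenerate input (zero variance)
    or a failed optimization yields a flagged result with ``loglik=-inf``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    x = np.asarray(lengths, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} lengths to fit a distribution, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    if np.ptp(x) == 0:
        return DistFitResult(family, (), -np.inf, converged=False,
                             message="degenerate sample: zero variance")
    dist = _SCIPY_DISTS[family]
    try:
        if family == "lognormal":
            logx = np.log(x)
            mu, s = float(logx.mean()), float(logx.std())
            params = (s, 0.0, math.exp(mu))
        elif family == "exponential":
            params = (0.0, float(x.mean()))
        elif family == "gumbel":
            params = tuple(float(p) for p in dist.fit(x))
        else:
            params = tuple(float(p) for p in dist.fit(x, floc=0))
        loglik = float(dist.logpdf(x, *params).sum())
    except Exception as exc:  # scipy optimization failure
        return DistFitResult(family, (), -np.inf, converged=False, message=str(exc))
    if not np.isfinite(loglik):
        return DistFitResult(family, params, -np.inf, converged=False,
                             message="non-finite log-likelihood at fitted parameters")
    return DistFitResult(family, params, loglik)


def fit_all_families(lengths: np.ndarray, min_n: int = 20) -> list[DistFitResult]:
    """Fit all six candidate families; one result per family, in fixed order."""
    return [fit_distribution(lengths, fam, min_n=min_n) for fam in FAMILIES]


def loglik_differences(results: list[DistFitResult]) -> dict[str, float]:
    """Log-likelihood deficits relative to the lognormal fit.

    ``delta[f] = loglik(lognormal) - loglik(f)``; positive values mean the
    lognormal fits better.  The lognormal entry is identically zero.
    """
    by_family = {r.family: r for r in results}
    if "lognormal" not in by_family:
        raise ValueError("results must include the lognormal family")
    ref = by_family["lognormal"].loglik
    return {fam: 0.0 if fam == "lognormal" else ref - r.loglik for fam, r in by_family.items()}


def best_fit(results: list[DistFitResult]) -> str:
    """Family with the highest log-likelihood; ties go to the earlier family.

    The tie-break (and iteration) order is the fixed order of ``FAMILIES``.
    """
    converged = [r for r in results if r.converged and np.isfinite(r.loglik)]
    if not converged:
        raise ValueError("all distribution fits failed")
    order = {fam: i for i, fam in enumerate(FAMILIES)}
    converged.sort(key=lambda r: order[r.family])
    best = converged[0]
    for r in converged[1:]:
        if r.loglik > best.loglik:
            best = r
    return best.family
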