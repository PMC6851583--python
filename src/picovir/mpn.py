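"""Most Probable Number (MPN) estimation from serial-dilution well outcomes.

An endpoint-dilution assay inoculates ``n`` replicate wells at each of a
series of dilutions of a virus concentrate into exponentially growing host
culture; a well is scored positive when the host population lyses.  Under
the Poisson single-hit model a well at dilution ``d`` receiving inoculum
volume ``v`` (mL) is positive with probability ``1 - exp(-c * v * d)``
where ``c`` is the concentration of infectious units (mL^-1) in the
undiluted concentrate.  The MPN is the maximum-likelihood estimate of
``c``; its 95% confidence interval is computed on ``log(c)`` from the
observed Fisher information (Wald interval, exponentiated).

Dividing the MPN by the total (stain-counted) virion concentration gives
the infectivity, the fraction of particles able to complete an infection
cycle; multiplying infectivity by the total virus:host ratio gives the
multiplicity of infection (MOI) of an experiment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "DilutionAssay",
    "MPNEstimate",
    "InfectivityResult",
    "MOIResult",
    "MPNEstimator",
    "estimate_mpn",
    "infectivity",
    "compute_moi",
    "round_sig",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class DilutionAssay:
    """Well outcomes of one serial-dilution assay.

    Parameters
    ----------
    dilution : array-like
        Dilution factor applied to the concentrate at each level
        (e.g. 1e-6 means a 10^-6 dilution).  Strictly positive, distinct.
    positive : array-like of int
        Number of lysis-positive wells per level.
    total : array-like of int
        Number of wells inoculated per level.
    volume_ml : float or array-like
        Inoculum volume per well (mL); scalar or per level.
    """

    dilution: np.ndarray
    positive: np.ndarray
    total: np.ndarray
    volume_ml: np.ndarray

    def __init__(self, dilution, positive, total, volume_ml):
        self.dilution = np.asarray(dilution, dtype=float)
        self.positive = np.asarray(positive, dtype=int)
        self.total = np.asarray(total, dtype=int)
        self.volume_ml = np.broadcast_to(
            np.asarray(volume_ml, dtype=float), self.dilution.shape
        ).copy()
        self._validate()

    def _validate(self) -> None:
        if self.dilution.ndim != 1 or self.dilution.size == 0:
            raise ValueError("assay needs at least one dilution level")
        if np.any(self.dilution <= 0):
            raise ValueError("dilution factors must be strictly positive")
        if np.unique(self.dilution).size != self.dilution.size:
            raise ValueError("dilution factors must be distinct")
        if self.positive.shape != self.dilution.shape or self.total.shape != self.dilution.shape:
            raise ValueError("positive/total must match dilution shape")
        if np.any(self.total < 1):
            raise ValueError("each level needs at least one well")
        if np.any((self.positive < 0) | (self.positive > self.total)):
            raise ValueError("need 0 <= positive <= total at every level")
        if np.any(self.volume_ml <= 0):
            raise ValueError("inoculum volumes must be positive")

    @property
    def exposure(self) -> np.ndarray:
        """Effective volume of undiluted concentrate per well (mL): v * d."""
        return self.volume_ml * self.dilution


@dataclass(frozen=True)
class MPNEstimate:
    """MLE of infectious-unit concentration with 95% CI (all mL^-1)."""

    mpn: float
    ci_low: float
    ci_high: float
    loglik: float
    n_levels_used: int
    censored: str | None = None  # None | "upper" (all neg) | "lower" (all pos)


@dataclass(frozen=True)
class InfectivityResult:
    """Fraction of total virions that are infectious, with 95% CI."""

    infectivity: float
    ci_low: float
    ci_high: float
    total_virions: float
    censored: str | None = None
    flagged: bool = False  # point estimate > 1


@dataclass(frozen=True)
class MOIResult:
    """Multiplicity of infection (infectious virions per host cell)."""

    moi: float
    ci_low: float
    ci_high: float
    virus_host_ratio: float
    # 2-significant-figure presentation, matching how MOI is reported
    moi_rounded: float = field(default=float("nan"))
    ci_rounded: tuple = field(default=(float("nan"), float("nan")))


def round_sig(x: float, digits: int = 2) -> float:
    """Round ``x`` to ``digits`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (digits - 1))


def _log_likelihood(log_c: float, exposure: np.ndarray, positive: np.ndarray,
                    total: np.ndarray) -> float:
    m = np.exp(log_c) * exposure
    # p * log(1 - e^-m) - (n - p) * m ; log1p/expm1 keep small-m levels stable
    with np.errstate(divide="ignore"):
        log_p_pos = np.log(-np.expm1(-m))
    terms = positive * log_p_pos - (total - positive) * m
    return float(np.sum(terms))


class MPNEstimator(BaseEstimator):
    """Poisson single-hit maximum-likelihood MPN estimator.

    Parameters
    ----------
    conf_level : float, default 0.95
        Confidence level of the Wald interval on log concentration.
    bias_correction : bool, default False
        Apply a second-order (Salama-style) correction dividing the MLE by
        ``exp(SE_log^2 / 2)``; the uncorrected MLE of endpoint assays is
        biased upward on the concentration scale.

    Attributes
    ----------
    mpn_ : float
        MLE of the infectious-unit concentration (mL^-1).
    ci_low_, ci_high_ : float
        Confidence bounds (mL^-1).
    loglik_ : float
        Maximised log-likelihood.
    se_log_ : float
        Standard error of log(c) from observed Fisher information.
    censored_ : str or None
        "upper" when all wells are negative (mpn_ = 0, one-sided upper
        bound), "lower" when all are positive (mpn_ = inf, one-sided
        lower bound), else None.
    n_levels_used_ : int
    """

    def __init__(self, conf_level: float = 0.95, bias_correction: bool = False):
        self.conf_level = conf_level
        self.bias_correction = bias_correction

    # -- helpers -----------------------------------------------------------
    def _z(self) -> float:
        from scipy.stats import norm

        return float(norm.ppf(0.5 + self.conf_level / 2.0))

    def fit(self, X, y=None):
        """Fit from a :class:`DilutionAssay` (or arrays via ``DilutionAssay``)."""
        assay = X if isinstance(X, DilutionAssay) else DilutionAssay(*X)
        exposure = assay.exposure
        p, n = assay.positive, assay.total
        self.n_levels_used_ = int(len(exposure))
        alpha = 1.0 - self.conf_level

        if np.all(p == 0):
            # censored below detection: one-sided upper bound from
            # P(all wells negative | c) = alpha
            upper = -math.log(alpha) / float(np.sum(n * exposure))
            self.mpn_, self.ci_low_, self.ci_high_ = 0.0, 0.0, upper
            self.loglik_ = 0.0
            self.se_log_ = float("nan")
            self.censored_ = "upper"
            return self
        if np.all(p == n):
            # censored above: one-sided lower bound from
            # P(all wells positive | c) = alpha
            def log_p_all_pos(log_c: float) -> float:
                m = math.exp(log_c) * exposure
                return float(np.sum(n * np.log(-np.expm1(-m)))) - math.log(alpha)

            hi = math.log(50.0 / exposure.min())
            lo = hi - 60.0
            log_c = optimize.brentq(log_p_all_pos, lo, hi)
            self.mpn_ = float("inf")
            self.ci_low_, self.ci_high_ = math.exp(log_c), float("inf")
            self.loglik_ = 0.0
            self.se_log_ = float("nan")
            self.censored_ = "lower"
            return self

        # bracket the MLE: the transition happens where c * exposure ~ O(1)
        lo = math.log(1e-3 / float(np.max(exposure)))
        hi = math.log(1e3 / float(np.min(exposure)))
        grid = np.linspace(lo, hi, 400)
        ll = np.array([_log_likelihood(t, exposure, p, n) for t in grid])
        t0 = grid[int(np.argmax(ll))]
        res = optimize.minimize_scalar(
            lambda t: -_log_likelihood(t, exposure, p, n),
            bounds=(t0 - 0.2, t0 + 0.2),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(res.x)
        self.loglik_ = -float(res.fun)

        # observed Fisher information on log c (central difference)
        h = 1e-4
        d2 = (
            _log_likelihood(theta + h, exposure, p, n)
            - 2.0 * self.loglik_
            + _log_likelihood(theta - h, exposure, p, n)
        ) / h**2
        se = math.sqrt(-1.0 / d2) if d2 < 0 else float("inf")
        self.se_log_ = se
        if self.bias_correction and math.isfinite(se):
            theta = theta - se**2 / 2.0
        z = self._z()
        self.mpn_ = math.exp(theta)
        self.ci_low_ = math.exp(theta - z * se)
        self.ci_high_ = math.exp(theta + z * se)
        self.censored_ = None
        return self

    @property
    def result_(self) -> MPNEstimate:
        return MPNEstimate(
            mpn=self.mpn_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            loglik=self.loglik_,
            n_levels_used=self.n_levels_used_,
            censored=self.censored_,
        )


def estimate_mpn(assay: DilutionAssay, conf_level: float = 0.95,
                 bias_correction: bool = False) -> MPNEstimate:
    """MLE of infectious-unit concentration from a dilution assay."""
    return MPNEstimator(conf_level=conf_level, bias_correction=bias_correction).fit(assay).result_


def infectivity(mpn: MPNEstimate, total_virions: float) -> InfectivityResult:
    """Infectious fraction: MPN titer divided by total virion concentration."""
    if total_virions <= 0:
        raise ValueError("total_virions must be positive")
    frac = mpn.mpn / total_virions
    flagged = bool(np.isfinite(frac) and frac > 1.0)
    if flagged:
        warnings.warn("infectivity point estimate exceeds 1; MPN titer is larger "
                      "than the total virion count", stacklevel=2)
    return InfectivityResult(
        infectivity=frac,
        ci_low=mpn.ci_low / total_virions,
        ci_high=mpn.ci_high / total_virions if np.isfinite(mpn.ci_high) else float("inf"),
        total_virions=total_virions,
        censored=mpn.censored,
        flagged=flagged,
    )


def compute_moi(virus_host_ratio: float, infect: InfectivityResult) -> MOIResult:
    """MOI = total virus:host ratio x infectious fraction, CI scaled alike.

    The rounded fields carry the 2-significant-figure presentation used
    when reporting MOI.
    """
    if virus_host_ratio <= 0:
        raise ValueError("virus_host_ratio must be positive")
    moi = virus_host_ratio * infect.infectivity
    lo = virus_host_ratio * infect.ci_low
    hi = virus_host_ratio * infect.ci_high
    return MOIResult(
        moi=moi,
        ci_low=lo,
        ci_high=hi,
        virus_host_ratio=virus_host_ratio,
        moi_rounded=round_sig(moi, 2),
        ci_rounded=(round_sig(lo, 2), round_sig(hi, 2)),
    )
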