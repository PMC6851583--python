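"""Population-dynamics estimators for lytic infection time courses.

Quantities follow the standard batch-culture conventions:

* log2 fold change ``n_t = (ln N_t - ln N_i) / ln 2`` — generations since
  the reference timepoint (dawn for host cells, the first post-inoculation
  sample for virions);
* specific growth rate ``mu = ln(N_t / N_i) / dt`` in d^-1 (negative
  values are net mortality);
* viral production ``VP = N_t / N_i`` — fold change in free virions,
  identical to ``2**n_t``;
* latent period — the sampling interval in which the free-virion log2
  fold change first becomes significantly greater than zero (one-sample
  t-test across replicates);
* burst size — progeny per lysed cell, ``(V(t2) - V(t1)) / (H(t1) - H(t2))``
  per replicate over a late-infection window in which lysis dominates;
* light-sensitivity ratio — mean VP under limited light over mean VP
  under standard light at each timepoint after first progeny release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "log2_fold_change",
    "growth_rate",
    "viral_production",
    "sensitivity_ratio",
    "LatentPeriodEstimator",
    "latent_period",
    "BurstSizeEstimator",
    "burst_size",
    "test_protocol",
]

HOURS_PER_DAY = 24.0


def _ref_value(times: np.ndarray, values: np.ndarray, reference_time: float) -> float:
    times = np.asarray(times, dtype=float)
    idx = np.flatnonzero(np.isclose(times, reference_time))
    if idx.size == 0:
        raise ValueError(f"reference time {reference_time} h is not a sampled time")
    return float(np.asarray(values, dtype=float)[idx[0]])


def log2_fold_change(values, times=None, reference_time=None, reference_value=None):
    """Generations relative to a reference: ``(ln N_t - ln N_i)/ln 2``.

    Either ``reference_value`` or ``times``+``reference_time`` must be
    given.  Non-positive counts yield NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    if reference_value is None:
        reference_value = _ref_value(times, values, reference_time)
    if reference_value <= 0:
        raise ValueError("reference count must be positive")
    ok = values > 0
    if not np.all(ok):
        warnings.warn("non-positive counts: log2 fold change undefined (NaN)",
                      stacklevel=2)
    out = np.full(values.shape, np.nan)
    out[ok] = (np.log(values[ok]) - np.log(reference_value)) / np.log(2.0)
    return out


def growth_rate(times, values, t0: float, t1: float) -> float:
    """Specific growth rate ``mu = ln(N_t1/N_t0) / (t1 - t0)`` in d^-1."""
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    n0 = _ref_value(times, values, t0)
    n1 = _ref_value(times, values, t1)
    if n0 <= 0 or n1 <= 0:
        raise ValueError("counts must be positive for growth-rate estimation")
    return float(np.log(n1 / n0) / ((t1 - t0) / HOURS_PER_DAY))


def viral_production(values, times=None, reference_time=None, reference_value=None):
    """Per-time fold change ``VP = N_t / N_i`` (equals ``2**log2_fold_change``)."""
    values = np.asarray(values, dtype=float)
    if reference_value is None:
        reference_value = _ref_value(times, values, reference_time)
    if reference_value <= 0:
        raise ValueError("reference count must be positive")
    return values / reference_value


@dataclass(frozen=True)
class LatentInterval:
    """Half-open sampling interval (t_low, t_high] bracketing first release."""

    t_low: float
    t_high: float
    detected: bool


class LatentPeriodEstimator(BaseEstimator):
    """Latent period from replicate free-virion log2 fold changes.

    At each timepoint a one-sample t-test of the replicate log2 fold
    changes against zero is performed; the latent period is reported as
    the interval between the last non-significant and the first
    significant timepoint.  Significance requires a positive mean
    (release is directional) and, with the default two-sided test,
    p < alpha.

    Parameters
    ----------
    alpha : float, default 0.05
    sided : {"two", "one"}, default "two"
        One-sided halves the p-value for the positive direction.

    Attributes
    ----------
    interval_ : LatentInterval
        ``(t_prev, t_sig]``; if no timepoint is significant,
        ``(t_last, inf]`` with ``detected=False``.
    pvalues_ : pandas.Series indexed by time.
    """

    def __init__(self, alpha: float = 0.05, sided: str = "two"):
        self.alpha = alpha
        self.sided = sided

    def fit(self, X, y=None, times=None):
        """Fit from a (n_times, n_replicates) array of log2 fold changes."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need a (n_times, n_replicates) array with >= 2 replicates")
        times = np.asarray(times, dtype=float)
        if times.shape[0] != X.shape[0]:
            raise ValueError("times must match the first axis of X")
        order = np.argsort(times)
        times, X = times[order], X[order]

        pvals = np.full(times.shape, np.nan)
        sig = np.zeros(times.shape, dtype=bool)
        for i, reps in enumerate(X):
            reps = reps[np.isfinite(reps)]
            if reps.size < 2 or np.ptp(reps) == 0:
                # degenerate (identical replicates): significant only if
                # the common value is positive and exactly attested
                pvals[i] = 0.0 if (reps.size >= 2 and reps[0] > 0) else 1.0
                sig[i] = pvals[i] < self.alpha
                continue
            t, p = stats.ttest_1samp(reps, 0.0)
            if self.sided == "one":
                p = p / 2.0 if t > 0 else 1.0 - p / 2.0
            pvals[i] = p
            sig[i] = (p < self.alpha) and (np.mean(reps) > 0)
        self.pvalues_ = pd.Series(pvals, index=times, name="p")
        hits = np.flatnonzero(sig)
        if hits.size:
            j = int(hits[0])
            t_prev = float(times[j - 1]) if j > 0 else 0.0
            self.interval_ = LatentInterval(t_prev, float(times[j]), True)
        else:
            self.interval_ = LatentInterval(float(times[-1]), float("inf"), False)
        return self


def latent_period(log2fc_by_time, times, alpha: float = 0.05,
                  sided: str = "two") -> LatentInterval:
    est = LatentPeriodEstimator(alpha=alpha, sided=sided)
    est.fit(log2fc_by_time, times=times)
    if not est.interval_.detected:
        warnings.warn("no timepoint with log2 fold change significantly above "
                      "zero; latent period undetected", stacklevel=2)
    return est.interval_


class BurstSizeEstimator(BaseEstimator):
    """Burst size from paired virus/host series over a late-lysis window.

    Per replicate, ``b = (V(t2) - V(t1)) / (H(t1) - H(t2))`` where
    ``(t1, t2]`` is a window in which host loss is dominated by lysis.
    Replicates with net host gain over the window are excluded with a
    warning (the ratio is undefined for them).  The estimator is
    invariant to the concentration unit as long as both series share it.

    Attributes
    ----------
    burst_mean_, burst_sd_ : float
        Mean and sample SD across usable replicates.
    per_replicate_ : np.ndarray
        Burst estimate per usable replicate.
    n_used_, n_excluded_ : int
    """

    def __init__(self, window: tuple = (18.5, 24.5)):
        self.window = window

    def fit(self, X, y=None):
        """``X``: iterable of (times, virus_values, host_values) per replicate."""
        t1, t2 = self.window
        per_rep, excluded = [], 0
        for times, virus, host in X:
            v1 = _ref_value(times, virus, t1)
            v2 = _ref_value(times, virus, t2)
            h1 = _ref_value(times, host, t1)
            h2 = _ref_value(times, host, t2)
            host_loss = h1 - h2
            if host_loss <= 0:
                excluded += 1
                continue
            per_rep.append((v2 - v1) / host_loss)
        if excluded:
            warnings.warn(f"{excluded} replicate(s) showed net host gain over "
                          f"({t1}, {t2}] h; burst size undefined for them",
                          stacklevel=2)
        self.per_replicate_ = np.asarray(per_rep, dtype=float)
        self.n_used_ = len(per_rep)
        self.n_excluded_ = excluded
        if self.n_used_ == 0:
            self.burst_mean_ = float("nan")
            self.burst_sd_ = float("nan")
        else:
            self.burst_mean_ = float(np.mean(self.per_replicate_))
            self.burst_sd_ = (
                float(np.std(self.per_replicate_, ddof=1)) if self.n_used_ > 1 else 0.0
            )
        return self


def burst_size(replicates, window: tuple = (18.5, 24.5)):
    """Mean ± SD burst size across replicates; see :class:`BurstSizeEstimator`."""
    est = BurstSizeEstimator(window=window).fit(replicates)
    return est.burst_mean_, est.burst_sd_


def sensitivity_ratio(vp_ll, vp_sl, times, after_h: float = 8.5) -> pd.DataFrame:
    """Light-sensitivity of viral production: mean(VP_LL)/mean(VP_SL) per time.

    ``vp_ll`` and ``vp_sl`` are (n_times, n_replicates) arrays of viral
    production under limited and standard light.  Timepoints at or before
    ``after_h`` (before first progeny release) are excluded.  The SE of
    the ratio is first-order error propagation of the two independent
    replicate means; the p-value is Welch's two-sample t-test of the
    replicate VPs (LL vs SL).  A ratio of 1 means production is
    insensitive to the light (host growth-rate) condition.
    """
    vp_ll = np.asarray(vp_ll, dtype=float)
    vp_sl = np.asarray(vp_sl, dtype=float)
    times = np.asarray(times, dtype=float)
    rows = []
    for i, t in enumerate(times):
        if t < after_h:
            continue
        a, b = vp_ll[i], vp_sl[i]
        mb = np.mean(b)
        if mb == 0:
            warnings.warn(f"zero mean SL production at {t} h; ratio undefined",
                          stacklevel=2)
            rows.append((t, np.nan, np.nan, np.nan))
            continue
        ma = np.mean(a)
        ratio = ma / mb
        se_a = np.std(a, ddof=1) / np.sqrt(a.size)
        se_b = np.std(b, ddof=1) / np.sqrt(b.size)
        se = abs(ratio) * np.sqrt((se_a / ma) ** 2 + (se_b / mb) ** 2) if ma != 0 else np.nan
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        rows.append((t, ratio, se, p))
    return pd.DataFrame(rows, columns=["time_h", "ratio", "se", "p_welch"])


def test_protocol(table: pd.DataFrame, value: str = "value", group: str = "group",
                  time: str = "time_h", alpha: float = 0.05) -> pd.DataFrame:
    """Per-timepoint one-way ANOVA (Type II SS) with Tukey-adjusted pairs.

    ``table`` is tidy with one row per replicate observation.  Returns a
    DataFrame with one row per (timepoint, contrast): the ANOVA F and p
    for the treatment factor plus Tukey-adjusted pairwise p-values.
    Two-group contrasts additionally get Welch's t-test p-value.
    Timepoints with zero variance within every group are degenerate and
    reported with NaN p-values and ``degenerate=True``.
    """
    required = {value, group, time}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for t, sub in table.groupby(time, sort=True):
        counts = sub.groupby(group)[value].count()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError(f"need >= 2 groups with >= 2 replicates at t={t}")
        pooled_within_var = sub.groupby(group)[value].var(ddof=1).sum()
        if pooled_within_var == 0:
            for g1, g2 in _pairs(counts.index):
                rows.append(dict(time_h=t, contrast=f"{g1} vs {g2}", f_anova=np.nan,
                                 p_anova=np.nan, p_tukey=np.nan, p_welch=np.nan,
                                 significant=False, degenerate=True))
            continue
        model = ols(f"{value} ~ C({group})", data=sub).fit()
        an = anova_lm(model, typ=2)
        f_stat = float(an.loc[f"C({group})", "F"])
        p_anova = float(an.loc[f"C({group})", "PR(>F)"])
        tukey = pairwise_tukeyhsd(sub[value].to_numpy(), sub[group].to_numpy(),
                                  alpha=alpha)
        tk = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
        for _, r in tk.iterrows():
            g1, g2 = str(r["group1"]), str(r["group2"])
            a = sub.loc[sub[group] == g1, value].to_numpy()
            b = sub.loc[sub[group] == g2, value].to_numpy()
            p_welch = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            rows.append(dict(time_h=t, contrast=f"{g1} vs {g2}", f_anova=f_stat,
                             p_anova=p_anova, p_tukey=float(r["p-adj"]),
                             p_welch=p_welch,
                             significant=bool(p_anova < alpha and r["p-adj"] < alpha),
                             degenerate=False))
    return pd.DataFrame(rows)


def _pairs(groups):
    groups = sorted(groups)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            yield g1, g2
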