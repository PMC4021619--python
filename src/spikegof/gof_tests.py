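"""Kolmogorov-Smirnov machinery and the five subsampling goodness-of-fit
tests for repeated spike-train trials.

The plug-in problem and the subsampling remedy
----------------------------------------------
Every time-rescaling goodness-of-fit test needs the (unknown) compensator,
which is replaced by an estimate fitted from the data.  When the estimate
comes from the *same* points that enter the KS statistic, the statistic no
longer follows the tabulated KS null: the test on the full sample is badly
conservative, while estimating on one half and testing on the other is
anti-conservative.  The cure implemented here is subsampling: estimate on
the whole sample of n trials, but evaluate the KS statistic on only
p = floor(n^(2/3)) of them.  The estimation error, of order n^(-r), is then
asymptotically negligible at the subsample's sqrt(p) scale, and the
classical KS quantiles apply again.

The five tests:

1. exponentiality of the pooled interspike intervals (homogeneous Poisson
   null), rate estimated by 1/mean on all ISIs, KS on a subsample of ISIs;
2. uniformity of the p-trial aggregated process against the *empirical*
   c.d.f. of the full aggregated sample (Poisson null, no smoothing);
3. same as 2 with a smooth plug-in c.d.f. F = Lambda/Lambda(Tmax) from an
   adaptive intensity estimate fitted on all n trials;
4. uniformity of the *cumulated* time-rescaled subsample trials on a
   truncated interval [0, p*theta], each trial rescaled by its own fitted
   conditional compensator (general null, e.g. Hawkes);
5. the Poisson special case of 4, where one compensator serves all trials.

Aggregation dilutes within-trial dependence, so Tests 2-3 are blind to it;
cumulation preserves it, which is why Tests 4-5 detect Hawkes-type
dependence that Tests 2-3 miss.

Every test also reports the "by lower values" p-value (1 - p_upper):
rejection by lower values flags estimated and empirical distributions that
agree suspiciously well.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import special, stats

from .core import (CumulativeIntensity, SpikeTrain, TrialSet, aggregate_trials,
                   cumulate, interspike_intervals, time_rescale)

__all__ = [
    "TestResult",
    "SubsampleRule",
    "ks_statistic",
    "kolmogorov_sf",
    "kolmogorov_quantile",
    "finite_sample_ks_quantile",
    "ks_pvalue",
    "test1_isi_exponential",
    "test2_aggregated_empirical",
    "test3_aggregated_plugin",
    "test4_cumulated",
    "test5_poisson_cumulated",
    "classical_ks_uniformity",
    "chi2_poisson_counts",
    "bh_adjust",
]

logger = logging.getLogger(__name__)

#: sample size above which the asymptotic Kolmogorov distribution is used
#: in place of the exact finite-n KS null
ASYMPTOTIC_N = 45


@dataclass
class TestResult:
    """Outcome of one goodness-of-fit test.

    ``statistic`` is on the scale of the quantile reference recorded in
    ``method``: the raw sup-distance for Test 1 (finite-n reference at the
    subsample size) and the sqrt(count)-normalised sup for Tests 2-5
    (Kolmogorov reference).  ``p_lower = 1 - p_upper`` is the p-value of the
    companion test by lower values.
    """

    statistic: float
    p_upper: float
    p_lower: float
    n_effective: int
    method: str
    subsample_indices: np.ndarray | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_upper <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_upper": float(self.p_upper),
            "p_lower": float(self.p_lower),
            "n_effective": int(self.n_effective),
            "method": self.method,
            "subsample_indices": None if self.subsample_indices is None
            else [int(i) for i in self.subsample_indices],
            "settings": self.settings,
        }


@dataclass
class SubsampleRule:
    """How to pick the p = floor(n^exponent) subsample.

    Default: uniform random without replacement with a recorded seed
    (exchangeability of i.i.d. trials makes any exchangeable rule valid);
    ``mode="first"`` takes the leading block, which is convenient for
    deterministic toy examples.
    """

    exponent: float = 2.0 / 3.0
    mode: str = "random"
    seed: int = 0

    def size(self, n: int) -> int:
        if n < 1:
            raise ValueError("n must be >= 1")
        return min(n, max(1, math.floor(n ** self.exponent)))

    def select(self, n: int) -> np.ndarray:
        p = self.size(n)
        if self.mode == "first":
            return np.arange(p)
        if self.mode == "random":
            rng = np.random.default_rng(self.seed)
            return np.sort(rng.choice(n, size=p, replace=False))
        raise ValueError(f"unknown selection mode {self.mode!r}")


# ---------------------------------------------------------------------------
# KS primitives
# ---------------------------------------------------------------------------


def ks_statistic(sample, cdf: Callable) -> float:
    """sup_u |F_n(u) - F0(u)| for a continuous reference c.d.f.

    Computed exactly through the order statistics:
    max_i max(i/n - F0(x_(i)), F0(x_(i)) - (i-1)/n).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("ks_statistic needs a nonempty sample")
    F = np.asarray(cdf(x), dtype=float)
    i = np.arange(1, n + 1)
    return float(max(np.max(i / n - F), np.max(F - (i - 1) / n)))


def kolmogorov_sf(x) -> np.ndarray | float:
    """Survival function of the asymptotic Kolmogorov distribution,
    2 sum_{k>=1} (-1)^{k-1} exp(-2 k^2 x^2)."""
    return special.kolmogorov(x)


def kolmogorov_quantile(alpha: float) -> float:
    """The 1-alpha quantile k_tilde of the asymptotic Kolmogorov law."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(special.kolmogi(alpha))


def finite_sample_ks_quantile(n: int, alpha: float) -> float:
    """1-alpha quantile of the exact n-sample KS null distribution.

    Exact evaluation for n <= 45; beyond that the asymptotic approximation
    k_tilde_{1-alpha} / sqrt(n) is accurate and is used instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n <= ASYMPTOTIC_N:
        return float(stats.kstwo.isf(alpha, n))
    return kolmogorov_quantile(alpha) / math.sqrt(n)


def ks_pvalue(statistic: float, n: int) -> float:
    """Upper p-value of a raw KS sup-distance at sample size n."""
    if n <= ASYMPTOTIC_N:
        return float(np.clip(stats.kstwo.sf(statistic, n), 0.0, 1.0))
    return float(kolmogorov_sf(statistic * math.sqrt(n)))


def _step_sup_distance(times_a: np.ndarray, times_b: np.ndarray) -> float:
    """sup_x |F_a(x) - F_b(x)| for two empirical (cadlag step) c.d.f.s.

    The sup over the real line is attained at a jump point of either
    function, either as the value or as the left limit, so it suffices to
    compare both one-sided evaluations on the union of jump points.
    """
    a = np.sort(np.asarray(times_a, dtype=float))
    b = np.sort(np.asarray(times_b, dtype=float))
    xs = np.union1d(a, b)
    fa_r = np.searchsorted(a, xs, side="right") / a.size
    fb_r = np.searchsorted(b, xs, side="right") / b.size
    fa_l = np.searchsorted(a, xs, side="left") / a.size
    fb_l = np.searchsorted(b, xs, side="left") / b.size
    return float(max(np.max(np.abs(fa_r - fb_r)), np.max(np.abs(fa_l - fb_l))))


# ---------------------------------------------------------------------------
# the five tests
# ---------------------------------------------------------------------------


def test1_isi_exponential(trials: TrialSet, rule: SubsampleRule | None = None,
                          rate: float | None = None) -> TestResult:
    """Test 1: KS exponentiality of the pooled interspike intervals.

    The rate is estimated by 1/mean on *all* pooled ISIs (pass ``rate`` to
    plug a known value instead and recover the classical no-estimation KS
    test); the statistic is evaluated on a subsample of
    p = floor(ntot^(2/3)) ISIs and referred to the size-p KS null.
    """
    rule = rule or SubsampleRule()
    isi = interspike_intervals(trials)
    ntot = isi.size
    if ntot < 2:
        raise ValueError("need at least two pooled ISIs")
    lam = rate if rate is not None else 1.0 / float(isi.mean())
    idx = rule.select(ntot)
    sub = isi[idx]
    stat = ks_statistic(sub, lambda u: -np.expm1(-lam * u))
    p_upper = ks_pvalue(stat, sub.size)
    logger.info("test1: ntot=%d subsample=%d rate=%.4f stat=%.4f",
                ntot, sub.size, lam, stat)
    return TestResult(stat, p_upper, 1.0 - p_upper, sub.size, "test1-isi-exponential",
                      subsample_indices=idx,
                      settings={"rate": lam, "estimated": rate is None,
                                "exponent": rule.exponent, "mode": rule.mode,
                                "seed": rule.seed})


def test2_aggregated_empirical(trials: TrialSet, rule: SubsampleRule | None = None
                               ) -> TestResult:
    """Test 2: aggregated subsample vs the full-sample empirical c.d.f.

    statistic = sqrt(N_{a,p}) sup_x |F_{N_{a,p}}(x) - F_hat(x)| with F_hat
    the empirical c.d.f. of the aggregation of all n trials, the sup taken
    over the jump points of both step functions, referred to the Kolmogorov
    law (conditioning on the realised aggregated count N_{a,p}).
    """
    rule = rule or SubsampleRule()
    idx = rule.select(trials.n)
    full = aggregate_trials(trials)
    sub = aggregate_trials(trials, idx)
    if len(sub) == 0 or len(full) == 0:
        raise ValueError("aggregated subsample is empty")
    sup = _step_sup_distance(sub.times, full.times)
    n_eff = len(sub)
    stat = math.sqrt(n_eff) * sup
    p_upper = ks_pvalue(sup, n_eff)
    logger.info("test2: n=%d p=%d N_a_p=%d stat=%.4f", trials.n, idx.size,
                n_eff, stat)
    return TestResult(stat, p_upper, 1.0 - p_upper, n_eff, "test2-aggregated-empirical",
                      subsample_indices=idx,
                      settings={"exponent": rule.exponent, "mode": rule.mode,
                                "seed": rule.seed})


def _fit_plugin(trials: TrialSet, estimator) :
    """Resolve an estimator spec into an intensity estimate fitted on all trials."""
    from . import poisson_intensity as pi

    if isinstance(estimator, str):
        key = estimator.lower()
        if key == "haar":
            return pi.haar_estimate(trials, pi.HaarSpec())
        if key == "gl":
            return pi.gl_select(trials, pi.KernelSpec())
        if key in ("const", "constant", "homogeneous"):
            rate = trials.total_spikes() / (trials.n * trials.t_end)
            return pi.IntensityEstimate(
                density=lambda t, _r=rate: np.full_like(np.asarray(t, float), _r),
                cumulative=CumulativeIntensity.homogeneous(rate, trials.t_end),
                method="constant", params={"rate": rate})
        raise ValueError(f"unknown estimator {estimator!r}")
    if callable(estimator) and not hasattr(estimator, "cumulative"):
        return estimator(trials)
    return estimator


def test3_aggregated_plugin(trials: TrialSet, rule: SubsampleRule | None = None,
                            estimator="haar") -> TestResult:
    """Test 3: aggregated subsample vs a smooth plug-in c.d.f.

    The intensity is fitted on the full TrialSet by an adaptive estimator
    ("haar" thresholding or "gl" kernel; "const" gives the homogeneous-rate
    pathway, and any IntensityEstimate or fitting callable is accepted);
    F_hat = Lambda_hat / Lambda_hat(Tmax).  Same statistic and reference as
    Test 2.
    """
    rule = rule or SubsampleRule()
    est = _fit_plugin(trials, estimator)
    total = est.cumulative.total()
    if total <= 0:
        raise ValueError("plug-in compensator has Lambda(Tmax) = 0")
    idx = rule.select(trials.n)
    sub = aggregate_trials(trials, idx)
    if len(sub) == 0:
        raise ValueError("aggregated subsample is empty")
    n_eff = len(sub)
    sup = ks_statistic(sub.times, lambda x: est.cumulative(x) / total)
    stat = math.sqrt(n_eff) * sup
    p_upper = ks_pvalue(sup, n_eff)
    logger.info("test3[%s]: n=%d p=%d N_a_p=%d stat=%.4f", est.method,
                trials.n, idx.size, n_eff, stat)
    return TestResult(stat, p_upper, 1.0 - p_upper, n_eff, f"test3-plugin-{est.method}",
                      subsample_indices=idx,
                      settings={"estimator": est.method,
                                "exponent": rule.exponent, "mode": rule.mode,
                                "seed": rule.seed})


def test4_cumulated(trials, compensators: Sequence[CumulativeIntensity],
                    rule: SubsampleRule | None = None,
                    theta: float | None = None,
                    method: str = "test4-cumulated") -> TestResult:
    """Test 4: cumulated time-rescaled subsample trials, truncated at p*theta.

    Each of the p subsampled trials is rescaled by its *own* fitted
    compensator, the rescaled trials are concatenated end to end, points
    beyond the deterministic bound p*theta are discarded, and uniformity of
    X/(p*theta) is tested against the Kolmogorov reference.  The truncation
    bound must stay below the realised cumulated length; by default
    theta = 0.8 x (mean of Lambda_i(Tmax) over the subsample), a safety
    factor guarding the requirement E(Lambda(Tmax)) > theta.
    """
    rule = rule or SubsampleRule()
    n = trials.n if isinstance(trials, TrialSet) else len(list(trials))
    if len(compensators) != n:
        raise ValueError("need one compensator per trial")
    idx = rule.select(n)
    p = idx.size
    rescaled = [time_rescale(trials[i], compensators[i]) for i in idx]
    cum = cumulate(rescaled)
    length = cum.t_end
    if theta is None:
        theta = 0.8 * length / p
    bound = p * theta
    if bound >= length or bound <= 0:
        raise ValueError("p*theta must lie in (0, cumulated length): theta too large")
    kept = cum.times[cum.times <= bound]
    if kept.size == 0:
        raise ValueError("no points in [0, p*theta]")
    u = kept / bound
    sup = ks_statistic(u, lambda v: np.clip(v, 0.0, 1.0))
    n_eff = kept.size
    stat = math.sqrt(n_eff) * sup
    p_upper = ks_pvalue(sup, n_eff)
    logger.info("%s: n=%d p=%d theta=%.4f N_c_p=%d stat=%.4f", method, n, p,
                theta, n_eff, stat)
    return TestResult(stat, p_upper, 1.0 - p_upper, n_eff, method,
                      subsample_indices=idx,
                      settings={"theta": float(theta),
                                "cumulated_length": float(length),
                                "exponent": rule.exponent, "mode": rule.mode,
                                "seed": rule.seed})


def test5_poisson_cumulated(trials: TrialSet, rule: SubsampleRule | None = None,
                            estimator="haar", theta: float | None = None
                            ) -> TestResult:
    """Test 5: the Poisson special case of Test 4.

    Under a Poisson null the compensator is deterministic and common to all
    trials, so a single Lambda_hat from the full-sample intensity estimate
    rescales every subsampled trial.
    """
    est = _fit_plugin(trials, estimator)
    if est.cumulative.total() <= 0:
        raise ValueError("plug-in compensator has Lambda(Tmax) = 0")
    comps = [est.cumulative] * trials.n
    res = test4_cumulated(trials, comps, rule=rule, theta=theta,
                          method=f"test5-poisson-{est.method}")
    res.settings["estimator"] = est.method
    return res


# ---------------------------------------------------------------------------
# companions: classical aggregated KS, chi-square count test, BH layer
# ---------------------------------------------------------------------------


def classical_ks_uniformity(trials: TrialSet) -> TestResult:
    """Classical KS test of uniformity on the fully aggregated sample.

    Conditionally on the total count, the points of an aggregated
    homogeneous Poisson process are i.i.d. uniform on [0, Tmax]; no plug-in
    and no subsampling.  Aggregation dilutes within-trial dependence, so
    this test mainly detects nonstationarity.
    """
    agg = aggregate_trials(trials)
    if len(agg) == 0:
        raise ValueError("no spikes to test")
    sup = ks_statistic(agg.times, lambda x: np.clip(x / trials.t_end, 0.0, 1.0))
    n_eff = len(agg)
    p_upper = ks_pvalue(sup, n_eff)
    return TestResult(math.sqrt(n_eff) * sup, p_upper, 1.0 - p_upper, n_eff,
                      "classical-ks-uniformity")


def chi2_poisson_counts(trials: TrialSet, min_trials: int = 20,
                        min_expected: float = 5.0) -> TestResult:
    """Chi-square test that per-trial spike counts are Poisson distributed.

    The Poisson mean is estimated by the sample mean (one fitted parameter),
    count cells are merged from both tails until every expected count is at
    least ``min_expected``, and the statistic is referred to chi-square with
    #cells - 2 degrees of freedom.
    """
    counts = trials.spike_counts()
    n = counts.size
    if n < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    mean = counts.mean()
    if mean <= 0:
        raise ValueError("no spikes at all")
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    probs = stats.poisson.pmf(ks, mean)
    probs = np.append(probs, stats.poisson.sf(kmax, mean))  # tail cell
    observed = np.append(np.bincount(counts, minlength=kmax + 1).astype(float), 0.0)
    # greedy merge until each cell's expected count reaches the floor
    cells_obs, cells_exp = [], []
    acc_o = acc_e = 0.0
    for o, pr in zip(observed, probs * n):
        acc_o += o
        acc_e += pr
        if acc_e >= min_expected:
            cells_obs.append(acc_o)
            cells_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and cells_exp:
        cells_obs[-1] += acc_o
        cells_exp[-1] += acc_e
    if len(cells_exp) < 3:
        raise ValueError("fewer than 3 cells after merging; too few counts")
    obs = np.array(cells_obs)
    exp = np.array(cells_exp) * obs.sum() / sum(cells_exp)
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = len(cells_exp) - 2
    p_upper = float(stats.chi2.sf(statistic, df))
    return TestResult(statistic, p_upper, 1.0 - p_upper, n, "chi2-poisson-counts",
                      settings={"df": df, "cells": len(cells_exp),
                                "mean": float(mean)})


def bh_adjust(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
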