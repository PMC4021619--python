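"""Least-squares and Bernstein-weighted lasso inference for multivariate
Hawkes processes observed over repeated trials.

The conditional intensity of neuron m in a multivariate Hawkes process is

    lambda^(m)(t) = ( nu^(m) + sum_l  int_{-inf}^{t-} h_l^(m)(t-u) dN^(l)(u) )_+

where nu^(m) > 0 is the spontaneous rate and h_l^(m) the interaction function
by which past spikes of neuron l modulate neuron m's future rate (negative
values model inhibition/refractoriness; the positive-part clip keeps the
rate nonnegative).  Each interaction is parameterised as a piecewise-constant
function on K bins of width delta,

    h_l^(m) = sum_k a_{m,l,k} delta^{-1/2} 1((k-1)delta, k delta],

so that for fixed m the linear predictor is psi_t^(m) = (Rc_t)' a^(m) with
Rc_t the renormalised instantaneous counts

    Rc_t = (1, delta^{-1/2} N^(1)[t-delta,t), ..., N^(1)[t-K delta,t-(K-1)delta), ..., neuron M ...).

Minimising the empirical least-square contrast over trials yields the linear
system G a = b with G the integrated outer product of Rc_t and b the sum of
Rc over target spikes; the weighted-l1-penalised version (weights from a
Bernstein deviation bound) gives a sparse estimate whose support identifies
the functional connectivity graph, and re-fitting least squares on that
support removes most of the lasso shrinkage bias.

The count vectors b also admit a classical reading: their blocks are the
delay cross-correlograms n_bar_{m,l} (herringbone-partition variant of the
JPSTH), scaled by delta^{-1/2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import CumulativeIntensity, MultiTrialSet, SpikeTrain

__all__ = [
    "HawkesModel",
    "DesignSystem",
    "LassoWeights",
    "instantaneous_counts",
    "build_design",
    "crosscorr_counts",
    "ols_fit",
    "bernstein_weights",
    "lasso_fit",
    "two_step_fit",
    "predict_intensity",
    "hawkes_compensators",
]

COND_THRESHOLD = 1e10  # above this, G counts as numerically singular


@dataclass
class HawkesModel:
    """Piecewise-constant multivariate Hawkes model.

    Attributes
    ----------
    delta, K:
        Bin width (s) and number of bins; the interaction support is
        ``A = K * delta``.
    nu:
        Spontaneous rates nu^(m) in Hz, length M.
    interactions:
        Array (M, M, K): ``interactions[m, l, k]`` is the height (Hz) of
        h_l^(m) on the lag bin ``((k) delta, (k+1) delta]`` (0-based k).
    """

    delta: float
    K: int
    nu: np.ndarray
    interactions: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        M = self.nu.size
        if self.interactions.shape != (M, M, self.K):
            raise ValueError("interactions must have shape (M, M, K)")
        if self.delta <= 0 or self.K < 1:
            raise ValueError("need delta > 0 and K >= 1")

    @property
    def M(self) -> int:
        return int(self.nu.size)

    @property
    def support(self) -> float:
        return self.K * self.delta

    def coefficients(self) -> np.ndarray:
        """Stacked coefficient vectors a^(m), shape (M, 1 + M*K).

        Layout per target m: (mu^(m), a_{m,1,1..K}, ..., a_{m,M,1..K}),
        heights renormalised by delta^{1/2}.
        """
        M, K = self.M, self.K
        a = np.empty((M, 1 + M * K))
        a[:, 0] = self.nu
        a[:, 1:] = (self.interactions * np.sqrt(self.delta)).reshape(M, M * K)
        return a

    @classmethod
    def from_coefficients(cls, a: np.ndarray, delta: float, K: int,
                          **kw) -> "HawkesModel":
        a = np.atleast_2d(np.asarray(a, dtype=float))
        M = a.shape[0]
        if a.shape[1] != 1 + M * K:
            raise ValueError("coefficient vectors have wrong length")
        nu = a[:, 0].copy()
        inter = a[:, 1:].reshape(M, M, K) / np.sqrt(delta)
        return cls(delta=delta, K=K, nu=nu, interactions=inter, **kw)

    def spectral_radius(self) -> float:
        """Spectral radius of the mean interaction matrix (positive parts).

        >= 1 signals the explosive regime of the linear Hawkes process.
        """
        S = np.clip(self.interactions, 0.0, None).sum(axis=2) * self.delta
        return float(np.max(np.abs(np.linalg.eigvals(S))))


@dataclass
class DesignSystem:
    """Summed least-squares system over trials: minimise -2 a'b + a'Ga."""

    G: np.ndarray                 # (dim, dim), dim = 1 + M*K
    b: np.ndarray                 # (M, dim)
    window: tuple
    delta: float
    K: int
    M: int
    n_trials: int

    @property
    def dim(self) -> int:
        return int(self.G.shape[0])

    def crosscorr(self) -> np.ndarray:
        """n_bar_{m,l,k} read off the b vectors (times delta^{1/2})."""
        return self.b[:, 1:].reshape(self.M, self.M, self.K) * np.sqrt(self.delta)


@dataclass
class LassoWeights:
    """Positive penalty weights d^(m) from the Bernstein deviation bound."""

    d: np.ndarray                 # (M, dim)
    gamma: float


def _window_counts(spikes_by_neuron: Sequence[np.ndarray], ts: np.ndarray,
                   delta: float, K: int) -> np.ndarray:
    """Counts N^(l)([t-k delta, t-(k-1) delta)) for k=1..K, all l.

    Returns an array (len(ts), M*K), neuron-major then lag bin, matching the
    coefficient layout.  Bins are left-closed: a spike exactly at ``t - delta``
    is in bin k=1 (equivalently the lag delta lies in the basis bin (0, delta]).
    """
    cols = []
    for s in spikes_by_neuron:
        for k in range(1, K + 1):
            lo = np.searchsorted(s, ts - k * delta, side="left")
            hi = np.searchsorted(s, ts - (k - 1) * delta, side="left")
            cols.append(hi - lo)
    return np.stack(cols, axis=1).astype(float)


def instantaneous_counts(trial: Sequence[SpikeTrain], t: float, delta: float,
                         K: int) -> np.ndarray:
    """The renormalised instantaneous count vector Rc_t at one time point.

    Requires ``t >= K * delta`` so the full history window is observed.
    """
    if t < K * delta:
        raise ValueError("t must be >= K*delta (full history window)")
    spikes = [tr.times for tr in trial]
    c = _window_counts(spikes, np.array([float(t)]), delta, K)[0]
    return np.concatenate(([1.0], c / np.sqrt(delta)))


def _trial_breakpoints(spikes_all: np.ndarray, t1: float, t2: float,
                       delta: float, K: int) -> np.ndarray:
    """Times in (t1, t2) where some count window gains or loses a spike."""
    if spikes_all.size == 0:
        return np.array([t1, t2])
    offs = np.arange(K + 1) * delta
    bp = (spikes_all[:, None] + offs[None, :]).ravel()
    bp = bp[(bp > t1) & (bp < t2)]
    return np.unique(np.concatenate(([t1, t2], bp)))


def build_design(mts: MultiTrialSet, window: tuple, delta: float, K: int
                 ) -> DesignSystem:
    """Exact G and b summed over trials on the window [T1, T2].

    Rc_t is piecewise constant in t with breakpoints at spike times shifted
    by multiples of delta, so ``G = int Rc_t Rc_t' dt`` is computed exactly
    by summing (segment length) x (outer product) over the segments;
    ``b^(m) = sum_{target spikes T} Rc_T`` uses the left limit at each spike
    (the integrand is predictable: a spike never counts itself).
    """
    t1, t2 = float(window[0]), float(window[1])
    if t1 < K * delta - 1e-12:
        raise ValueError("T1 must be >= K*delta")
    if t2 <= t1 or t2 > mts.t_end + 1e-12:
        raise ValueError("need T1 < T2 <= t_end")
    M = mts.M
    dim = 1 + M * K
    G = np.zeros((dim, dim))
    b = np.zeros((M, dim))
    sq = np.sqrt(delta)
    for trial in mts:
        spikes = [tr.times for tr in trial]
        allspk = np.concatenate(spikes) if spikes else np.array([])
        bp = _trial_breakpoints(np.sort(allspk), t1, t2, delta, K)
        mids = 0.5 * (bp[:-1] + bp[1:])
        lens = np.diff(bp)
        C = _window_counts(spikes, mids, delta, K)
        R = np.concatenate([np.ones((mids.size, 1)), C / sq], axis=1)
        G += R.T @ (R * lens[:, None])
        for m in range(M):
            s = spikes[m]
            tgt = s[(s >= t1) & (s <= t2)]
            if tgt.size:
                Cm = _window_counts(spikes, tgt, delta, K)
                Rm = np.concatenate([np.ones((tgt.size, 1)), Cm / sq], axis=1)
                b[m] += Rm.sum(axis=0)
    return DesignSystem(G=G, b=b, window=(t1, t2), delta=delta, K=K, M=M,
                        n_trials=mts.n)


def crosscorr_counts(mts: MultiTrialSet, window: tuple, delta: float, K: int
                     ) -> np.ndarray:
    """Delay cross-correlogram counts n_bar_{m,l,k}, summed over trials.

    Entry k counts couples (x, y) with x a spike of neuron m in [T1, T2],
    y an *earlier* spike of neuron l, and lag x - y in ((k-1)delta, k delta].
    Computed by direct pair enumeration, independently of :func:`build_design`
    (whose b blocks equal these counts times delta^{-1/2}).
    """
    t1, t2 = float(window[0]), float(window[1])
    M = mts.M
    out = np.zeros((M, M, K))
    edges = np.arange(K + 1) * delta
    for trial in mts:
        for m in range(M):
            x = trial[m].times
            x = x[(x >= t1) & (x <= t2)]
            if x.size == 0:
                continue
            for l in range(M):
                y = trial[l].times
                if y.size == 0:
                    continue
                lags = x[:, None] - y[None, :]
                lags = lags[lags > 0]
                if lags.size:
                    hist, _ = np.histogram(lags, bins=edges)
                    out[m, l] += hist
    return out


def ols_fit(design: DesignSystem) -> HawkesModel:
    """Unpenalised least squares: a^(m) = G^{-1} b^(m) for each target m."""
    cond = np.linalg.cond(design.G)
    if not np.isfinite(cond) or cond > COND_THRESHOLD:
        raise np.linalg.LinAlgError(
            f"G is numerically singular (cond={cond:.2e}); "
            "use more trials, a smaller K, or the lasso fit"
        )
    a = np.linalg.solve(design.G, design.b.T).T
    return HawkesModel.from_coefficients(a, design.delta, design.K,
                                         diagnostics={"method": "ols",
                                                      "cond": float(cond)})


def _sliding_window_max(s: np.ndarray, delta: float, lo: float, hi: float) -> int:
    """Max count of spikes of one neuron in any half-open delta-window within [lo, hi]."""
    s = s[(s >= lo - delta) & (s <= hi)]
    if s.size == 0:
        return 0
    right = np.searchsorted(s, s + delta, side="left")
    return int(np.max(right - np.arange(s.size)))


def bernstein_weights(mts: MultiTrialSet, window: tuple, delta: float, K: int,
                      gamma: float = 1.0) -> LassoWeights:
    """Data-driven penalty weights d_{m,l,k} and d_{m,0}.

    d_{m,l,k} = sqrt(2 gamma ln(n(T2-T1)) Vhat_{m,l,k})
                + gamma ln(n(T2-T1)) Bhat_{l,k} / 3,

    with Vhat the sum over target spikes of the squared renormalised window
    counts and Bhat the renormalised sup of the window count, so that the
    penalty dominates the noise term of a Bernstein concentration bound.
    """
    t1, t2 = float(window[0]), float(window[1])
    M = mts.M
    dim = 1 + M * K
    logterm = np.log(mts.n * (t2 - t1))
    if logterm <= 0:
        raise ValueError("need n * (T2 - T1) > 1")
    V = np.zeros((M, M * K))
    agg_counts = np.zeros(M)
    B = np.zeros(M * K)
    sq = np.sqrt(delta)
    for trial in mts:
        spikes = [tr.times for tr in trial]
        for m in range(M):
            s = spikes[m]
            tgt = s[(s >= t1) & (s <= t2)]
            agg_counts[m] += tgt.size
            if tgt.size:
                C = _window_counts(spikes, tgt, delta, K)
                V[m] += (C ** 2).sum(axis=0) / delta
        col = 0
        for l in range(M):
            for k in range(1, K + 1):
                w = _sliding_window_max(spikes[l], delta, t1 - k * delta,
                                        t2 - (k - 1) * delta)
                B[col] = max(B[col], w / sq)
                col += 1
    d = np.empty((M, dim))
    d[:, 0] = np.sqrt(2.0 * gamma * logterm * agg_counts) + gamma * logterm / 3.0
    d[:, 1:] = np.sqrt(2.0 * gamma * logterm * V) + gamma * logterm * B[None, :] / 3.0
    return LassoWeights(d=d, gamma=gamma)


def _coordinate_descent(G: np.ndarray, b: np.ndarray, d: np.ndarray,
                        a0: np.ndarray | None = None, tol: float = 1e-8,
                        max_sweeps: int = 100_000):
    """Minimise -2 a'b + a'Ga + 2 d'|a| by cyclic soft-threshold updates."""
    dim = b.size
    a = np.zeros(dim) if a0 is None else a0.copy()
    diag = np.diag(G).copy()
    r = b - G @ a
    objs = []
    for sweep in range(max_sweeps):
        max_change = 0.0
        for j in range(dim):
            if diag[j] <= 0:
                continue  # empty coordinate: stays at its current (zero) value
            z = r[j] + diag[j] * a[j]
            new = np.sign(z) * max(abs(z) - d[j], 0.0) / diag[j]
            if new != a[j]:
                r -= G[:, j] * (new - a[j])
                max_change = max(max_change, abs(new - a[j]))
                a[j] = new
        objs.append(float(-2 * a @ b + a @ G @ a + 2 * d @ np.abs(a)))
        if max_change <= tol * max(1.0, float(np.max(np.abs(a)))):
            return a, objs
    raise RuntimeError(
        f"coordinate descent did not converge in {max_sweeps} sweeps "
        f"(last change {max_change:.3e})"
    )


def kkt_violation(G: np.ndarray, b: np.ndarray, d: np.ndarray, a: np.ndarray
                  ) -> float:
    """Max violation of the lasso stationarity conditions at ``a``.

    At a minimiser, |(Ga - b)_j| <= d_j on zero coordinates and
    (Ga - b)_j = -d_j sign(a_j) on active ones.
    """
    g = G @ a - b
    active = a != 0
    v_zero = np.max(np.clip(np.abs(g[~active]) - d[~active], 0.0, None),
                    initial=0.0)
    v_act = np.max(np.abs(g[active] + d[active] * np.sign(a[active])),
                   initial=0.0)
    return float(max(v_zero, v_act))


def lasso_fit(design: DesignSystem, weights: LassoWeights, tol: float = 1e-8,
              max_sweeps: int = 100_000, warm_start: np.ndarray | None = None
              ) -> HawkesModel:
    """Bernstein-weighted lasso estimate (the f_hat_B of the two-step scheme).

    The convex objective -2 a'b + a'Ga + 2 d'|a| is minimised per target
    neuron by cyclic coordinate descent with soft thresholding; the solution
    is certified through the KKT conditions (violation recorded in
    ``diagnostics``).
    """
    M = design.M
    a = np.zeros((M, design.dim))
    kkt = []
    objs = []
    for m in range(M):
        a0 = None if warm_start is None else warm_start[m]
        am, ob = _coordinate_descent(design.G, design.b[m], weights.d[m],
                                     a0=a0, tol=tol, max_sweeps=max_sweeps)
        # polish until the stationarity certificate holds at 1e-6
        viol = kkt_violation(design.G, design.b[m], weights.d[m], am)
        t = tol
        for _ in range(10):
            if viol <= 1e-6:
                break
            t /= 100.0
            am, extra = _coordinate_descent(design.G, design.b[m],
                                            weights.d[m], a0=am, tol=t,
                                            max_sweeps=max_sweeps)
            ob += extra
            viol = kkt_violation(design.G, design.b[m], weights.d[m], am)
        a[m] = am
        kkt.append(viol)
        objs.append(ob)
    return HawkesModel.from_coefficients(
        a, design.delta, design.K,
        diagnostics={"method": "lasso", "gamma": weights.gamma,
                     "kkt_violation": kkt, "objective_paths": objs})


def two_step_fit(design: DesignSystem, lasso_model: HawkesModel) -> HawkesModel:
    """OLS restricted to the lasso support (the debiased f_hat_BO).

    Lasso shrinkage biases the active coefficients toward zero; re-solving
    the unpenalised system on the selected support removes that bias while
    keeping the sparsity pattern.
    """
    a_lasso = lasso_model.coefficients()
    a = np.zeros_like(a_lasso)
    for m in range(design.M):
        supp = np.flatnonzero(a_lasso[m])
        if supp.size == 0:
            continue
        Gs = design.G[np.ix_(supp, supp)]
        cond = np.linalg.cond(Gs)
        if not np.isfinite(cond) or cond > COND_THRESHOLD:
            warnings.warn(
                f"restricted G singular for target {m}; keeping lasso solution",
                stacklevel=2)
            a[m] = a_lasso[m]
            continue
        a[m, supp] = np.linalg.solve(Gs, design.b[m][supp])
    return HawkesModel.from_coefficients(
        a, design.delta, design.K,
        diagnostics={"method": "two-step",
                     "support": [np.flatnonzero(a_lasso[m]).tolist()
                                 for m in range(design.M)]})


def predict_intensity(model: HawkesModel, trial: Sequence[SpikeTrain], t,
                      clip: bool = False) -> np.ndarray:
    """Linear predictors psi_t^(m) = Rc_t' a^(m) for all m at times ``t``.

    With ``clip=True`` returns the positive part, the nonnegative plug-in
    used by the cumulated goodness-of-fit test.  Shape (len(t), M).
    """
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    spikes = [tr.times for tr in trial]
    C = _window_counts(spikes, ts, model.delta, model.K)
    R = np.concatenate([np.ones((ts.size, 1)), C / np.sqrt(model.delta)], axis=1)
    psi = R @ model.coefficients().T
    return np.clip(psi, 0.0, None) if clip else psi


def hawkes_compensators(model: HawkesModel, mts: MultiTrialSet, m: int
                        ) -> list:
    """Per-trial exact compensators of neuron m under the fitted model.

    The clipped predictor (psi_t^(m))_+ is piecewise constant between
    breakpoints {spike + k delta}, so each compensator is an exact
    piecewise-linear cumulative, ready for time rescaling.
    """
    comps = []
    for trial in mts:
        spikes = [tr.times for tr in trial]
        allspk = np.sort(np.concatenate(spikes)) if spikes else np.array([])
        bp = _trial_breakpoints(allspk, 0.0, mts.t_end, model.delta, model.K)
        mids = 0.5 * (bp[:-1] + bp[1:])
        lam = predict_intensity(model, trial, mids, clip=True)[:, m]
        comps.append(CumulativeIntensity.from_step(bp, lam))
    return comps
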