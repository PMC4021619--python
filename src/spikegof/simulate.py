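"""Point-process simulators and the three benchmark scenarios.

The benchmarks, each observed on a 2 s window:

* ``S-HomPoi`` — homogeneous Poisson at 20 Hz; the simplest null.
* ``S-InPoi`` — inhomogeneous Poisson with a piecewise-continuous intensity
  made of three compactly supported bumps (two smooth bumps riding on
  plateaus plus one isolated bump), which mixes jumps and smooth features so
  that both histogram-type and kernel estimators are stressed.
* ``S-Haw`` — a bivariate Hawkes process with 20 Hz spontaneous rates,
  self-inhibition of both neurons over 5 ms (a refractory period), a one-way
  excitation of neuron 1 by neuron 2 (60 Hz over 10 ms) and no influence of
  neuron 1 on neuron 2.

Poisson processes are simulated by thinning (dominated rejection sampling);
the Hawkes simulator exploits that all interactions are piecewise constant,
so between events the conditional intensity only changes at spike-time plus
bin-edge offsets, and exact event scheduling over those breakpoints replaces
generic dominated thinning.
"""

from __future__ import annotations

import heapq
import warnings
from typing import Callable, Sequence

import numpy as np

from .core import MultiTrialSet, SpikeTrain, TrialSet
from .hawkes import HawkesModel

__all__ = [
    "SCENARIOS",
    "s_inpoi_intensity",
    "s_inpoi_max_rate",
    "s_haw_model",
    "simulate_homogeneous_poisson",
    "simulate_inhomogeneous_poisson",
    "simulate_hawkes",
    "make_scenario",
]

SCENARIOS = ("s-hompoi", "s-inpoi", "s-haw")
T_END = 2.0
HOMPOI_RATE = 20.0

# bump parameters of the S-InPoi intensity
_G = np.array([5.0, 30.0, 0.0])
_H = np.array([12.5, 15.0, 12.5])
_C = np.array([0.375, 1.25, 1.825])
_R = np.array([0.375, 0.5, 0.125])


def s_inpoi_intensity(t) -> np.ndarray:
    """The S-InPoi rate (Hz): three compactly supported smooth bumps.

    lambda(t) = sum_i [g_i + h_i exp(-4 (t-c_i)^2 / (r_i^2 - (t-c_i)^2))]
                on [c_i - r_i, c_i + r_i), zero outside every support.

    The exponent tends to -infinity at a support edge, so each bump decays
    to its plateau level g_i there; at the centre t = c_i it equals
    g_i + h_i.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any((t < 0) | (t > T_END)):
        raise ValueError("t must lie in [0, 2]")
    out = np.zeros_like(t)
    for g, h, c, r in zip(_G, _H, _C, _R):
        d = t - c
        inside = (d >= -r) & (d < r)
        di = d[inside]
        denom = r * r - di * di
        with np.errstate(over="ignore", divide="ignore"):
            expo = np.where(denom > 0, -4.0 * di * di / np.where(denom > 0, denom, 1.0),
                            -np.inf)
        out[inside] += g + h * np.exp(expo)
    return out[0] if scalar else out


def s_inpoi_max_rate() -> float:
    """A tight dominating rate for thinning: the global max is g2+h2 = 45 Hz."""
    return float((_G + _H).max())


def simulate_homogeneous_poisson(rate: float, t_end: float,
                                 rng: np.random.Generator) -> SpikeTrain:
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    n = rng.poisson(rate * t_end)
    return SpikeTrain(np.sort(rng.uniform(0.0, t_end, size=n)), t_end)


def simulate_inhomogeneous_poisson(rate_fn: Callable, rate_max: float,
                                   t_end: float,
                                   rng: np.random.Generator) -> SpikeTrain:
    """Thinning: dominate by a homogeneous Poisson(rate_max) and accept each
    candidate at time t with probability rate_fn(t) / rate_max."""
    if rate_max <= 0:
        raise ValueError("rate_max must be positive")
    n = rng.poisson(rate_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n))
    vals = np.asarray(rate_fn(cand), dtype=float) if n else np.array([])
    if vals.size and np.max(vals) > rate_max * (1.0 + 1e-9):
        raise ValueError("rate_fn exceeds rate_max: dominating rate invalid")
    keep = rng.uniform(0.0, rate_max, size=n) < vals
    return SpikeTrain(cand[keep], t_end)


def simulate_hawkes(model: HawkesModel, t_end: float,
                    rng: np.random.Generator,
                    max_events: int = 200_000) -> tuple:
    """Exact simulation of a piecewise-constant multivariate Hawkes process.

    The conditional intensity of each component is the positive part of
    nu^(m) plus the summed interaction heights of past spikes, and is
    piecewise constant between breakpoints (spike time + interaction bin
    edge).  Events are scheduled exactly: on each constant stretch the next
    event is exponential with the current total rate; if it lands past the
    next breakpoint the clock advances to the breakpoint and the intensity
    is refreshed.  Returns an M-tuple of :class:`SpikeTrain`.
    """
    M, K, delta = model.M, model.K, model.delta
    sr = model.spectral_radius()
    if sr >= 1.0:
        warnings.warn(f"mean interaction matrix has spectral radius {sr:.3f} >= 1: "
                      "explosive regime", stacklevel=2)
    # per (target m, source l): increments of h_l^(m) at lag offsets k*delta
    steps = []  # list over l of (offsets, increments[m, :])
    for l in range(M):
        h = model.interactions[:, l, :]          # (M, K) heights from source l
        padded = np.concatenate([np.zeros((M, 1)), h, np.zeros((M, 1))], axis=1)
        inc = np.diff(padded, axis=1)            # (M, K+1) changes at k*delta
        offsets = np.arange(K + 1) * delta
        keep = np.any(inc != 0.0, axis=0)
        steps.append((offsets[keep], inc[:, keep]))

    psi = model.nu.astype(float).copy()          # linear predictor per target
    heap: list = []                              # (time, tiebreak, increment vector)
    times = [[] for _ in range(M)]
    t = 0.0
    n_events = 0
    push_count = 0
    while True:
        lam = np.clip(psi, 0.0, None)
        total = float(lam.sum())
        t_break = heap[0][0] if heap else np.inf
        if total <= 0.0:
            if t_break >= t_end:
                break
            t = t_break
        else:
            w = rng.exponential(1.0 / total)
            if t + w >= min(t_break, t_end):
                if t_break >= t_end:
                    break
                t = t_break
            else:
                t = t + w
                m = int(rng.choice(M, p=lam / total))
                times[m].append(t)
                n_events += 1
                if n_events > max_events:
                    raise RuntimeError("event budget exceeded; process looks explosive")
                offs, inc = steps[m]
                for o, dv in zip(offs, inc.T):
                    push_count += 1
                    heapq.heappush(heap, (t + o, push_count, dv))
                continue
        # apply all increments scheduled at the current breakpoint
        while heap and heap[0][0] <= t + 1e-15:
            _, _, dv = heapq.heappop(heap)
            psi = psi + dv
    return tuple(SpikeTrain(np.array(ts), t_end) for ts in times)


def s_haw_model() -> HawkesModel:
    """The S-Haw benchmark: nu = (20, 20) Hz, h_1^(1) = h_2^(2) = -20 on
    (0, 5 ms], h_2^(1) = +60 on (0, 10 ms], h_1^(2) = 0."""
    delta, K = 0.005, 2
    inter = np.zeros((2, 2, K))
    inter[0, 0] = [-20.0, 0.0]   # self-inhibition of neuron 1
    inter[0, 1] = [60.0, 60.0]   # neuron 2 excites neuron 1 over 10 ms
    inter[1, 1] = [-20.0, 0.0]   # self-inhibition of neuron 2
    return HawkesModel(delta=delta, K=K, nu=np.array([20.0, 20.0]),
                       interactions=inter)


def make_scenario(name: str, n_trials: int, seed) :
    """Simulate ``n_trials`` i.i.d. trials of a named benchmark scenario.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  Each
    trial draws from its own deterministically spawned substream, so
    enlarging ``n_trials`` never reshuffles earlier trials.  Returns a
    :class:`TrialSet` (Poisson scenarios) or :class:`MultiTrialSet` (S-Haw).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    key = name.lower()
    if key not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(n_trials)]
    if key == "s-hompoi":
        return TrialSet([simulate_homogeneous_poisson(HOMPOI_RATE, T_END, r)
                         for r in rngs])
    if key == "s-inpoi":
        rmax = s_inpoi_max_rate()
        return TrialSet([simulate_inhomogeneous_poisson(s_inpoi_intensity, rmax,
                                                        T_END, r)
                         for r in rngs])
    model = s_haw_model()
    return MultiTrialSet([simulate_hawkes(model, T_END, r) for r in rngs])
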