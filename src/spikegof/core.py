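"""Point-process containers and the elementary transforms behind the tests.

Spike trains are modelled as simple point processes on an observation window
``[0, t_end]``.  Everything downstream — goodness-of-fit testing, intensity
estimation, Hawkes inference — acts on three containers:

* :class:`SpikeTrain` — one trial's sorted event times,
* :class:`TrialSet` — n i.i.d. trials of a single neuron,
* :class:`MultiTrialSet` — n i.i.d. trials of M simultaneously recorded
  neurons,

and on :class:`CumulativeIntensity`, a nondecreasing compensator evaluator
``t -> Lambda(t)`` used for time rescaling.

The transforms implemented here are *aggregation* (pooling the spikes of
several trials onto one time axis, which dilutes within-trial dependence),
*cumulation* (concatenating trials end to end, which preserves it), and
*time rescaling* (mapping each spike T to Lambda(T), which turns a process
with compensator Lambda into a unit-rate Poisson process).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "TrialSet",
    "MultiTrialSet",
    "CumulativeIntensity",
    "aggregate_trials",
    "empirical_cdf",
    "time_rescale",
    "cumulate",
    "interspike_intervals",
]


class SpikeTrain:
    """Sorted event times of one neuron in one trial on ``[0, t_end]``.

    Parameters
    ----------
    times:
        Event times in seconds.  Must lie in ``[0, t_end]``; they are sorted
        on construction.  Ties are tolerated internally (aggregated processes
        may carry them) but, for raw recordings, use :meth:`from_raw` which
        drops exact duplicates: a simple point process has a.s. distinct
        points, while 1 kHz-resolution data can tie.
    t_end:
        Window length in seconds.
    """

    __slots__ = ("times", "t_end")

    def __init__(self, times: Sequence[float], t_end: float):
        t = np.atleast_1d(np.asarray(times, dtype=float))
        t_end = float(t_end)
        if t_end < 0:
            raise ValueError("t_end must be nonnegative")
        if t.size and (np.any(np.diff(t) < 0)):
            t = np.sort(t)
        if t.size and (t[0] < 0 or t[-1] > t_end):
            raise ValueError("spike times must lie in [0, t_end]")
        self.times = t
        self.t_end = t_end

    @classmethod
    def from_raw(cls, times: Sequence[float], t_end: float) -> "SpikeTrain":
        """Build a train from raw data, dropping exact duplicate times."""
        t = np.sort(np.asarray(times, dtype=float))
        tu = np.unique(t)
        if tu.size < t.size:
            warnings.warn(
                f"dropped {t.size - tu.size} duplicate spike time(s) "
                "(simple point processes have distinct points)",
                stacklevel=2,
            )
        return cls(tu, t_end)

    def __len__(self) -> int:
        return int(self.times.size)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpikeTrain(n={len(self)}, t_end={self.t_end})"

    def count(self, a: float, b: float) -> int:
        """Number of events in the half-open interval ``[a, b)``."""
        lo, hi = np.searchsorted(self.times, [a, b], side="left")
        return int(hi - lo)

    def counting_process(self, t):
        """Right-continuous counting process N([0, t])."""
        return np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")


@dataclass(frozen=True)
class TrialSet:
    """n i.i.d. trials of one neuron, all observed on the same window."""

    trials: tuple
    t_end: float = field(init=False)

    def __init__(self, trials: Sequence[SpikeTrain]):
        trials = tuple(trials)
        if not trials:
            raise ValueError("TrialSet needs at least one trial")
        t_end = trials[0].t_end
        if any(tr.t_end != t_end for tr in trials):
            raise ValueError("all trials must share the same t_end")
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "t_end", t_end)

    @property
    def n(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i) -> SpikeTrain:
        return self.trials[i]

    def spike_counts(self) -> np.ndarray:
        return np.array([len(tr) for tr in self.trials])

    def total_spikes(self) -> int:
        return int(self.spike_counts().sum())


@dataclass(frozen=True)
class MultiTrialSet:
    """n i.i.d. trials of an M-variate point process (M neurons).

    ``trials[i]`` is an M-tuple of :class:`SpikeTrain`, one per neuron;
    the layout is rectangular (every trial has all M neurons, possibly
    with no spikes).
    """

    trials: tuple
    M: int = field(init=False)
    t_end: float = field(init=False)

    def __init__(self, trials: Sequence[Sequence[SpikeTrain]]):
        trials = tuple(tuple(tr) for tr in trials)
        if not trials:
            raise ValueError("MultiTrialSet needs at least one trial")
        M = len(trials[0])
        if M < 1 or any(len(tr) != M for tr in trials):
            raise ValueError("every trial must carry the same number of neurons")
        t_end = trials[0][0].t_end
        if any(s.t_end != t_end for tr in trials for s in tr):
            raise ValueError("all spike trains must share the same t_end")
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "t_end", t_end)

    @property
    def n(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def component(self, m: int) -> TrialSet:
        """The single-neuron TrialSet of neuron ``m`` (0-based)."""
        return TrialSet([tr[m] for tr in self.trials])


class CumulativeIntensity:
    """A nondecreasing compensator evaluator ``t -> Lambda(t)`` on [0, t_end].

    Stored as a piecewise-linear interpolant through knots ``(grid, values)``
    with ``Lambda(0) = 0``.  Exact for piecewise-constant intensities built
    through :meth:`from_step`; for densities given on a grid the cumulative
    uses trapezoidal integration (default grid step 1e-3 s, the usual data
    resolution).
    """

    def __init__(self, grid, values, density: Callable | None = None):
        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape or grid.size < 2:
            raise ValueError("grid and values must be 1-d arrays of equal length >= 2")
        if grid[0] != 0.0:
            raise ValueError("grid must start at 0")
        if abs(values[0]) > 1e-12:
            raise ValueError("Lambda(0) must be 0")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(values) < -1e-10 * max(1.0, float(values[-1]))):
            raise ValueError("compensator must be nondecreasing")
        self.grid = grid
        self.values = np.maximum.accumulate(values)  # iron out roundoff wiggles
        self.values[0] = 0.0
        self.density = density

    @property
    def t_end(self) -> float:
        return float(self.grid[-1])

    def __call__(self, t):
        return np.interp(np.asarray(t, dtype=float), self.grid, self.values)

    def total(self) -> float:
        """Lambda(t_end)."""
        return float(self.values[-1])

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_density(cls, density: Callable, t_end: float, step: float = 1e-3
                     ) -> "CumulativeIntensity":
        """Integrate a nonnegative rate function by the trapezoidal rule."""
        ngrid = max(2, int(np.ceil(t_end / step)) + 1)
        grid = np.linspace(0.0, t_end, ngrid)
        lam = np.asarray(density(grid), dtype=float)
        if np.any(lam < -1e-9):
            raise ValueError("intensity must be nonnegative")
        lam = np.clip(lam, 0.0, None)
        cum = np.concatenate(([0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * np.diff(grid))))
        return cls(grid, cum, density=density)

    @classmethod
    def from_step(cls, edges, heights) -> "CumulativeIntensity":
        """Exact compensator of a piecewise-constant intensity.

        ``heights[j]`` is the rate on ``[edges[j], edges[j+1])``; the
        cumulative is piecewise linear with knots at the edges, so linear
        interpolation reproduces it exactly.
        """
        edges = np.asarray(edges, dtype=float)
        heights = np.clip(np.asarray(heights, dtype=float), 0.0, None)
        if edges.size != heights.size + 1:
            raise ValueError("need len(edges) == len(heights) + 1")
        cum = np.concatenate(([0.0], np.cumsum(heights * np.diff(edges))))

        def density(t, _e=edges, _h=heights):
            idx = np.clip(np.searchsorted(_e, np.asarray(t, dtype=float), side="right") - 1,
                          0, _h.size - 1)
            return _h[idx]

        return cls(edges, cum, density=density)

    @classmethod
    def homogeneous(cls, rate: float, t_end: float) -> "CumulativeIntensity":
        """Lambda(t) = rate * t."""
        if rate < 0:
            raise ValueError("rate must be nonnegative")
        return cls(np.array([0.0, t_end]), np.array([0.0, rate * t_end]),
                   density=lambda t, _r=rate: np.full_like(np.asarray(t, dtype=float), _r))


# -- transforms -----------------------------------------------------------


def aggregate_trials(trials: TrialSet, subset: Sequence[int] | None = None) -> SpikeTrain:
    """Pool the spikes of the selected trials onto one axis (multiset union).

    The aggregated process of i.i.d. Poisson trials with compensator Lambda
    is again Poisson with compensator ``p * Lambda``; counts are additive on
    every interval, exactly.
    """
    if subset is None:
        subset = range(trials.n)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    if any(i < 0 or i >= trials.n for i in subset):
        raise IndexError("trial index out of range")
    times = np.sort(np.concatenate([trials[i].times for i in subset]))
    return SpikeTrain(times, trials.t_end)


def empirical_cdf(points, x):
    """Fraction of ``points`` that are <= x (vectorised in x)."""
    pts = np.sort(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("empirical_cdf needs a nonempty sample")
    return np.searchsorted(pts, np.asarray(x, dtype=float), side="right") / pts.size


def time_rescale(train: SpikeTrain, comp: CumulativeIntensity) -> SpikeTrain:
    """Map each spike T to Lambda(T); new window is ``[0, Lambda(t_end)]``.

    By the time-rescaling theorem the result is a unit-rate Poisson process
    when ``comp`` is the true compensator of ``train``.
    """
    if comp.t_end < train.t_end - 1e-9:
        raise ValueError("compensator not defined up to the train's t_end")
    new_times = comp(train.times)
    return SpikeTrain(new_times, comp(train.t_end))


def cumulate(rescaled: Sequence[SpikeTrain]) -> SpikeTrain:
    """Concatenate trains end to end; train i is shifted by sum_{j<i} L_j.

    Unlike aggregation, cumulation preserves within-trial dependence, and it
    applies even when the (rescaled) trials have different lengths.
    """
    rescaled = list(rescaled)
    if not rescaled:
        raise ValueError("nothing to cumulate")
    lengths = np.array([tr.t_end for tr in rescaled])
    for tr in rescaled:
        if len(tr) and tr.times[-1] > tr.t_end + 1e-12:
            raise ValueError("spike time exceeds its train length")
    offsets = np.concatenate(([0.0], np.cumsum(lengths)[:-1]))
    parts = [tr.times + off for tr, off in zip(rescaled, offsets)]
    return SpikeTrain(np.concatenate(parts), float(lengths.sum()))


def interspike_intervals(trials: TrialSet) -> np.ndarray:
    """Pooled within-trial ISIs; no interval straddles two trials.

    Under a homogeneous Poisson model the ISIs are i.i.d. exponential with
    the firing rate as parameter, the basis of the exponentiality test.
    """
    diffs = [np.diff(tr.times) for tr in trials if len(tr) >= 2]
    if not diffs:
        raise ValueError("need at least one trial with >= 2 spikes")
    return np.concatenate(diffs)
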