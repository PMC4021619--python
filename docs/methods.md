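# Methods

## Scope and model

`spikegof` treats repeated-trial spike trains as i.i.d. realisations of a
point process on a window `[0, Tmax]` described by its conditional
intensity λ(t): a constant λ (homogeneous Poisson), a deterministic
function λ(·) (inhomogeneous Poisson), or a multivariate Hawkes intensity

    λ^(m)(t) = ( ν^(m) + Σ_ℓ ∫_{-∞}^{t-} h_ℓ^(m)(t-u) dN^(ℓ)(u) )₊

with spontaneous rates ν^(m) (Hz) and interaction functions h_ℓ^(m)
supported on (0, A]; negative interactions model inhibition/refractoriness
and the positive-part clip keeps the rate nonnegative.

## Goodness-of-fit by subsampling

All tests reduce, through the time-rescaling theorem, to a
Kolmogorov–Smirnov test of uniformity or exponentiality with an estimated
transformation.  The plug-in step is what breaks the classical KS null:
estimating the model on the same points used in the statistic makes the
test badly conservative, while estimating on one half and testing on the
other makes it anti-conservative.  The package's resolution is to estimate
on the whole sample of n trials but evaluate the KS statistic on a
subsample of p = ⌊n^(2/3)⌋ of them: the estimation error, of order n^(-r)
with r the estimator's rate, is then negligible at the subsample's √p
scale, and the classical KS quantiles apply asymptotically.

Implemented statistics (all exposed in `gof_tests`):

1. **ISI exponentiality** — rate 1/mean on all pooled within-trial ISIs,
   KS on ⌊ntot^(2/3)⌋ ISIs against the fitted exponential, finite-sample
   KS reference at the subsample size.
2. **Aggregated, empirical c.d.f.** — F̂ is the empirical c.d.f. of the
   aggregation of all n trials; statistic √(N_{a,p}) · sup|F_{N_{a,p}} − F̂|
   over the p-trial aggregated subsample, sup taken at the jump points of
   both step functions, Kolmogorov reference.  Conditioning is on the
   realised aggregated count.
3. **Aggregated, smooth plug-in** — as 2 with F̂ = Λ̂/Λ̂(Tmax) from an
   adaptive intensity estimate fitted on the full sample.
4. **Cumulated, general plug-in** — each subsampled trial rescaled by its
   own fitted compensator Λ̂ᵢ, concatenated end to end, truncated at the
   deterministic bound pθ, and X/(pθ) tested for uniformity.
5. **Cumulated, Poisson plug-in** — the special case of 4 with one common
   Λ̂ from the full-sample intensity estimate.

Aggregation superimposes the trial-time structure and dilutes within-trial
dependence; cumulation preserves dependence but divides fixed shape
misfit across the p blocks.  Hence Tests 2–3 detect nonstationarity and
Tests 4–5 detect dependence through the dispersion of counts across and
within the rescaled blocks.

Design choices:

* Subsample selection is uniform without replacement with a recorded seed
  (any exchangeable rule is valid for i.i.d. trials); `mode="first"` is
  available for deterministic examples.
* θ defaults to 0.8 × the subsample mean of Λ̂ᵢ(Tmax).  The truncation
  bound pθ must stay below the realised cumulated length; the 0.8 safety
  factor guards that requirement and is recorded in the result.
* KS references: exact finite-n null (via `scipy.stats.kstwo`) up to
  n = 45, the asymptotic Kolmogorov law beyond.
* Every test reports `p_lower = 1 − p_upper`, the test by lower values,
  which flags estimated and empirical distributions that agree *too* well
  (the signature of under-dispersed, e.g. inhibited, data).
* Companion layers: a chi-square test on per-trial spike counts (one
  estimated parameter, cells merged to expected counts ≥ 5, df = cells − 2),
  the classical aggregated KS uniformity test, and Benjamini–Hochberg
  multiple-testing flags (via statsmodels).

## Adaptive intensity estimation

**Kernel + Goldenshluger–Lepski.**  λ̂_h is the Gaussian kernel estimate of
the aggregated sample divided by n.  The GL rule estimates the bias of
each h by comparing doubly smoothed against singly smoothed estimates over
the whole bandwidth family ℋ and penalising with
(1+η)(1+‖K‖₁)‖K‖₂√(N_{a,n})/(n√h); the selected ĥ minimises bias proxy +
penalty, ties toward the larger bandwidth.  Defaults: η = 0.5 and
ℋ = {1/D : D = 4,…,50} (20 values), a family that behaves robustly around
n ≈ 40 trials.  For the Gaussian kernel K_h ⋆ K_{h'} = K_{√(h²+h'²)}, so
the comparison norms have an exact pairwise closed form; above 600
aggregated spikes the same quantity is evaluated from an FFT
autocorrelation of 0.24 ms-binned counts (relative error ~10⁻³ on the
norms, irrelevant to the argmin).  Norms are taken over all of ℝ and the
sup in the bias proxy ranges over all of ℋ.  No boundary correction is
applied, so at large selected bandwidths roughly 0.4·ĥ of the boundary
kernels' mass lies outside the window; this matters only for flat
intensities, where the selected bandwidth is largest.

**Haar thresholding.**  Time is mapped affinely to [0, 1); empirical Haar
coefficients β̂_{j,k} of the aggregated sample (divided by n) are computed
by a count pyramid over 2^(j0+1) dyadic cells; details are kept when
|β̂_{j,k}| exceeds the Bernstein-style threshold
√(2γ ln(n) v̂_{j,k}) + γ ln(n) 2^(j/2)/(3n); the scaling (father)
coefficient is kept unconditionally, so γ → ∞ leaves the father-level
histogram rather than the zero function.  Defaults γ = 1 (smaller values
are known to undersmooth) and j0 = min(15, ⌊log₂ n⌋), reconciling the
resolution constraint 2^j0 ≤ n with a practical cap.  The reconstruction
is clipped at zero; its compensator is exact (piecewise linear).

Both estimators satisfy oracle inequalities up to unspecified constants;
the property test bounds the Monte Carlo risk ratio of the GL selection
against the best fixed bandwidth by 4 (measured ≈ 3.4 on the bumpy
benchmark at n = 200, where the best fixed bandwidth is the family
minimum because jumps dominate the bias).

## Hawkes inference

Interactions are piecewise constant on K bins of width δ (support
A = Kδ).  With the renormalised instantaneous counts Rc_t (windows
[t−kδ, t−(k−1)δ), left-closed — a spike exactly at t−δ lies in bin 1, its
lag δ in the basis bin (0, δ]), the least-squares contrast summed over
trials is −2a'b + a'Ga with G = Σᵢ ∫ Rc_t Rc_t' dt integrated exactly over
the constancy segments and b^(m) = Σ spikes of m of Rc evaluated at the
left limit (the integrand is predictable: a spike never counts itself).
The b blocks are, up to δ^(−1/2), the herringbone-partition delay
cross-correlograms n̄_{m,ℓ}; `crosscorr_counts` recomputes them by direct
pair enumeration as a cross-check.  The lag-bin orientation follows the
defining integral (past spikes of the source relative to each target
spike); the transposed convention that sometimes appears in correlogram
notation is *not* used.

* **OLS**: G a = b per target, refused when cond(G) > 10¹⁰.
* **Weighted lasso**: −2a'b + a'Ga + 2d'|a| with Bernstein weights
  d_{m,ℓ,k} = √(2γ ln(n(T2−T1)) V̂_{m,ℓ,k}) + γ ln(n(T2−T1)) B̂_{ℓ,k}/3
  (V̂ the summed squared renormalised counts at target spikes, B̂ the
  renormalised sliding-window sup); the spontaneous coordinate is
  penalised with its printed weight d_{m,0}.  Solved by cyclic coordinate
  descent with soft thresholding (the penalty is separable and G is small
  and dense), converged at relative change 10⁻⁸ and then polished until
  the KKT stationarity certificate holds at 10⁻⁶.
* **Two-step**: OLS restricted to the lasso support, which removes the
  shrinkage bias while keeping the sparsity pattern; zeros elsewhere.

Benchmark defaults: [T1, T2] = [Kδ, Tmax] with K = 8, δ = 5 ms, γ = 1.
The fitted model yields per-trial compensators (exact integrals of the
clipped piecewise-constant predictor) that plug into the cumulated test.

## Simulators

Poisson processes are simulated by thinning under a dominating constant
rate.  The bivariate Hawkes benchmark (ν = 20 Hz both neurons, −20 Hz
self-inhibition over 5 ms, one-way 60 Hz excitation over 10 ms, 2 s
window) is simulated *exactly*: all interactions are piecewise constant,
so between events the conditional intensity changes only at spike time +
bin edge; the simulator schedules exponential waiting times on each
constant stretch and refreshes at breakpoints kept in a heap.  Explosive
parameter sets (spectral radius of the mean interaction matrix ≥ 1) warn
and are stopped by an event budget.  Scenario generators draw each trial
from a deterministically spawned substream, so enlarging the trial count
never reshuffles earlier trials.

What the synthetic benchmarks do and do not emulate: they reproduce the
trial structure, rates, nonstationarity and short-range dependence typical
of sensory-motor single-unit recordings, but not slow nonstationarity
across trials, non-i.i.d. trial effects, or spike-sorting artefacts
(duplicate-time ties are handled at ingestion only).  Passing tests
therefore validate the statistics under their stated models, not the
biology of any particular recording.

## Numerical choices and degenerate inputs

* Compensators are piecewise-linear interpolants; densities given on a
  grid are integrated trapezoidally at 10⁻³ s (the usual 1 kHz data
  resolution), piecewise-constant densities exactly.
* Counting intervals are half-open [a, b).
* Empty aggregated samples: the GL selector warns and returns the zero
  intensity; the Haar estimator returns zero; tests requiring points raise.
* Duplicate spike times are dropped (with a warning) at ingestion;
  simple point processes have a.s. distinct points.
* GL ties break toward the larger (smoother) bandwidth.

## Replicate sizes in the validation suite

The acceptance experiments use the study conditions directly: 1000
replicates for the level experiments (n = 40), 11 replicates for the
median power pattern, and 12 replicates of n = 200 trials for Hawkes
recovery; the oracle-inequality and risk benchmarks use 12–30 replicates,
sizes chosen so Monte Carlo error is small against the asserted margins.

## Known limitations

* The cumulated tests' power against stationary dependence comes from
  count dispersion across rescaled blocks; dependence structures whose
  excitatory and inhibitory dispersion effects cancel (as they nearly do
  for the bivariate benchmark's first component, Fano ≈ 0.98) are hard to
  detect at n = 40 regardless of plug-in.
* The empirical-c.d.f. aggregated test is conservative at moderate n
  (measured level ≈ 0.01 at the nominal 0.05) because the full-sample
  c.d.f. shares ~p/n of its points with the subsample.
* No boundary correction in the kernel estimators (see above).
* Piecewise-polynomial penalised log-likelihood estimation and exact
  small-sample plug-in KS distributions are out of scope.
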