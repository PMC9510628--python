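# Methods

## Generative models

All data are multi-trial multivariate time series: `L` trials of `M`
degrees of freedom (DOFs — muscles' EMG envelopes, joint angles, force
components) sampled at `T` points over a fixed duration `T_s`. Five
decompositions are implemented as forward operators (`fada.models`):

| model | synthesis | invariants across trials |
|---|---|---|
| spatial | `x_l(m,t) = Σ_p W[m,p] C[l,p,t]` | spatial patterns `W` |
| temporal | `x_l(m,t) = Σ_p C[l,m,p] S[p,t]` | waveforms `S` |
| temporal + delays | `x_l(m,t) = Σ_p C[l,m,p] S[p, t−τ[l,m,p]]` | waveforms `S` |
| spatiotemporal | `x_l(m,t) = Σ_p C[l,p] Wt[p,m, t−τ[l,p]]` | time-varying modules `Wt` |
| space-by-time | `x_l(m,t) = Σ_{p,q} S[p, t−τ[l,p,q]] C[l,p,q] W[m,q]` | `S` and `W` |

Every model is a constrained anechoic mixture
`y_r(t) = Σ_u a_ru f_u(t−τ_ru)` over rows `r = l·M + m`; the `embed_*`
operations construct the explicit index bijections, tied/zeroed weight
patterns and tied delays, and the dual forward paths agree to machine
precision (a tested invariant). Delays are circular with period `T_s`
(applied as exact Fourier-domain phase ramps, fractional-sample delays
allowed) and canonicalized to `[−T_s/2, T_s/2)`. The circular convention
is a design choice: the phase-ramp representation of a delay is inherently
periodic, and fixing it removes edge ambiguity; data whose delayed content
runs off the trial edge are outside the model.

## The estimator (`fada.engine`)

Signals are represented by their first `K+1` Fourier coefficients
`c_rk` with `K ≪ T/2`. By default `K` is the smallest value retaining
99.99 % of the mean signal energy, capped at `⌊T/4⌋`. (A looser 99.9 %
rule measurably biases delay estimates on noiseless delayed data — a
truncated harmonic leaves an irreducible residual — hence the tight
default; it is configurable.)

One outer iteration consists of:

1. **Source update.** For fixed weights and delays the model is linear in
   the source coefficients per frequency; each `ν_{:,k}` is the exact
   complex least-squares solution (solved per independent block of rows and
   sources). Non-negative sources are maintained by clipping the
   reconstruction at zero and re-projecting onto the `K`-harmonic band.
2. **Weight/delay update.** Per signal (or per tied group), each source's
   delay is set to the peak of the circular cross-correlation between the
   source and the partial residual — evaluated on the sample grid and
   refined to sub-sample precision by Newton steps on the trigonometric
   polynomial — followed by a joint (non-negative) least-squares weight
   refit. Because this subproblem has many near-degenerate local optima
   (smooth sources resemble shifted copies of each other), the step is a
   *batched multistart*: several random delay initializations per row, with
   weights refit first so starts genuinely differ, keeping the best state
   per row; rows whose residual stays above 1e-7 of their energy receive an
   intensive final pass. Tied weights are solved exactly by grouped least
   squares; tied delays share one cross-correlation score summed over the
   group.

Initialization uses the delay-blind squared-magnitude identity
`|c_rk|² ≈ Σ_u |a_ru|² |ν_uk|²`: a non-negative factorization of the
`R×(K+1)` squared-magnitude matrix (multiplicative-update NMF with a
separable/successive-projection candidate, or a non-negative-ICA-style
whiten-and-rotate solver), made structure-aware (alternating NNLS over the
tie/zero pattern) for the constrained models. A short warm-up iterates
the closed-form per-frequency phase coordinate descent with magnitudes
anchored before the full least-squares refresh takes over.

Random restarts (default 5, stopping early once `R² ≥ 0.999`) guard
against basin misses; the run with the best explained variance wins, and
the convergence criterion is a relative objective change below `tol = 1e-5`
(at most 200 outer iterations; non-convergence is reported in the result,
not raised). All randomness derives from one integer seed; fits are
bitwise reproducible.

### Rotation fixing for synchronous models

With all delays zero and no sign constraints, the factorization `X = W C`
is only determined up to an invertible mixing of the components — the
reconstruction objective cannot distinguish rotations. The model's own
assumption that sources are uncorrelated *at every pair of time points*
supplies the missing criterion: after the least-squares fit, the
components are rotated by jointly diagonalizing (Jacobi angle sweeps)

* the per-frequency spectral covariances averaged over trials (by
  Parseval, this covers the cross-covariance at all circular lags), and
* fourth-order cumulant matrices of the whitened components — smooth
  oscillatory waveforms have strongly sub-Gaussian marginals, so cumulants
  carry rotation information even when the magnitude spectra overlap.

Non-negative synchronous fits are seeded from the rotation-fixed
unconstrained fit projected onto the non-negative orthant, which removes
the analogous non-uniqueness of dense non-negative factorizations.

### Space-by-time

The bilinear weight structure `a_{r,(p,q)} = C[l,p,q] W[m,q]` with sources
tied by temporal primitive gets a dedicated path: per-trial multistart
delay/weight fitting (batched over trials), per-DOF NNLS for the spatial
primitives, per-frequency least squares for the temporal primitives, in an
explore/exploit schedule (14 short restarts, the best four continued to
convergence, an adaptive second exploration wave if none converges well,
then an intensive polish).

## Synthetic benchmark (`fada.simulate`)

Defaults: `M=10`, `L=20`, `T=100` samples over `T_s=1 s`, `P=3`
primitives (`P_tp=P_sp=3`), sources band-limited to `K_gen=8` harmonics
with a `1/k` amplitude decay, mixing weights uniform (`U(0,1)` for
non-negative variants, `U(−1,1)` otherwise), delays uniform over ±15 % of
the trial, 20 realizations per condition, five signal-dependent noise
levels {0, 5, 15, 25, 35} %. These are desk-scale sizes representative of
multi-muscle EMG recordings; all are configurable.

* **Non-negative sources** are squares of signals band-limited to
  `⌊K_gen/2⌋` — exactly band-limited to `K_gen` *and* exactly
  non-negative, shaped like smooth EMG bursts.
* **Dissimilarity rejection.** Candidate sources whose absolute
  correlation with an accepted source exceeds 0.6 are redrawn. For models
  where sources enter with free delays the correlation is maximized over
  all circular lags first (the demixing assumption concerns all lag
  pairs); synchronous models use the zero-lag correlation.
* **Signal-dependent noise**: per sample `std = level·(|x| + 0.05·RMS(x))`
  — noise grows with activation, with a small floor so silent samples are
  not noise-free; non-negative data are clipped at zero afterwards. The
  empirical noise-to-signal RMS ratio is within a few percent of `level`.

What passing tests on these data do **not** show: real EMG/kinematic
recordings have non-band-limited content, trial-length variability,
sensor artifacts, and primitives that need not satisfy any dissimilarity
bound; recovery rates here are upper bounds on what identical settings
achieve on real data.

## Evaluation (`fada.evaluation`)

* `R² = 1 − SS_res/SS_tot` with `SS_tot` about the grand mean (centered,
  the stricter convention; an uncentered variant is available). A
  zero-variance dataset reconstructed exactly scores 1.
* Components are matched to ground truth by the Hungarian assignment under
  the appropriate raw similarity: max-over-circular-lag normalized
  cross-correlation for waveforms (delay- and offset-invariant, absolute
  value for sign-gauge invariance) and cosine for spatial vectors.
* The **normalized similarity** is `S_N = (S − S_base)/(1 − S_base)`,
  where `S_base` is the Monte-Carlo mean matched similarity between two
  independent parameter draws of the same model (default 100 pairs,
  seeded); chance maps to 0, perfection to 1, and values below chance
  clamp to 0 (the pre-clamp value is available).
* **Delays** are scored after removing one global circular offset per
  source (the shift gauge) as `1 − RMS/(T_s/4)`, clamped to [0,1], with
  the circular RMS error also reported in samples. Both the offset and
  the RMS are weighted by the magnitudes of the true mixing weights: the
  delay of a component mixed with weight ≈ 0 is unidentifiable and should
  not dominate the error. The `T_s/4` scale and the offset gauge are
  package conventions, configurable.
* For space-by-time fits the temporal and spatial primitive similarities
  are reported separately and `sn_primitives` is their mean.

## Model-order selection

`r2_curve` fits each order independently (no warm start, avoiding
order-dependent bias); `elbow_select` returns the smallest order from
which an ordinary least-squares line fits the tail of the `R²`-versus-order
curve with mean squared error below `1e-4` (suffixes down to two points
qualify; if none does, the largest order is returned).

## Known limitations

* **Unconstrained temporal model:** with a single realization of `T=100`
  samples and source correlations allowed up to 0.6, the component
  rotation is only weakly identified; both our combined second/fourth-order
  criterion and a reference ICA recover the waveforms to raw similarity
  ≈ 0.8–0.9, which the chance normalization (baseline ≈ 0.75 for matched
  smooth waveforms) maps to modest `S_N`. The spatial model does not
  suffer from this (its component time courses span all trials).
* **Space-by-time delays:** dense all-positive spatial primitives make the
  per-trial assignment of delayed source copies nearly degenerate;
  primitives and weights are recovered reliably, but a minority of delay
  cells can settle in alternative near-optimal assignments, inflating the
  delay RMS on some seeds, and occasional basin misses remain.
* Exactly periodic (circular) trials are assumed; non-periodic data should
  be padded or windowed upstream.
* Sampling is uniform and trials complete; no missing-data handling.
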