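# Methods

This note records the models implemented in `lfpdecode`, the assumptions
behind them, the defaults that matter, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was open.

## MISO identification of spike-related slow potentials

**Model.** Each low-frequency LFP channel is a linear time-invariant sum of
the recorded spike trains plus a DC offset:
`y_c[t] = b_c + Σ_u Σ_l h_{u,c}[l] x_u[t−l]`, with binned spike *counts*
`x_u` (not smoothed rates — the convolution model is taken literally) and an
acausal lag grid `l ∈ [−t_pre, t_post]`. Negative lags are LFP preceding the
spike. Defaults: 10 ms bins, ±0.5 s lags (101 taps) — wide enough to cover a
full 1–4 Hz submovement cycle either side of a spike.

**Solver.** The normal equations are assembled from input auto- and
cross-correlation functions: the Gram matrix is the block-Toeplitz matrix of
full (zero-padded) cross-correlations minus the outer products of the
2(K_pre+K_post) boundary rows whose lag window leaves the recorded span.
This is algebraically identical to ordinary least squares on the explicit
lagged design matrix over interior bins — the property test asserts
agreement to ~1e-15 — while costing one FFT-based correlation per input pair
plus a single Cholesky factorization shared by all output channels. Joint
estimation removes the contribution of correlated *recorded* spike trains
from each unit's kernel; correlated unrecorded neurons cannot be accounted
for and bias the kernels exactly like any other event-locked background —
which is why the noise-free recovery contract also switches the generator's
rotational LMP component off.

**Ridge.** Default λ=0; a singular system raises an error carrying a
suggested λ range scaled by trace(G)/n. The DC column is never penalized.

## Source decomposition and Wiener/FIR rate decoding

Per unit, the channel × lag SRSP matrix is decomposed by (uncentered) SVD
into orthonormal lag-space waveforms and channel loadings; 3 sources by
default. Source projections are the pseudoinverse of the loadings — the
least-squares demixing of the source time courses from the multichannel
LFP. Each projected source signal is deconvolved by its waveform with
frequency-domain Wiener regularization `H*/(|H|²+nsr)` (default nsr = 0.01;
the constant is applied to unit-norm waveforms so its scale is comparable
across units), and the deconvolved sources are combined per unit by OLS
against training rates — the only supervised step. The entire chain is then
collapsed into one acausal FIR filter bank per unit (taps spanning twice the
SRSP lag span, raised-cosine/Tukey tapered against truncation ripple), so
run-time estimation is pure filtering plus an offset and is linear in the
LFP. Estimates may go negative; clipping is optional and off by default to
preserve the linear contract.

Two consequences of the OLS recombination are worth stating plainly:

* the nsr → ∞ limit collapses the estimate to the constant mean rate only
  at nsr = ∞ exactly (zero Wiener gain); any finite gain is rescaled by the
  supervised step;
* per-unit accuracy is bounded by cross-talk. When several units' SRSPs
  share source subspaces, the LFP carries fewer independent temporal signals
  than units, and no linear estimator can separate them fully. Population
  components — projections of the rate vector onto its leading PCs — average
  over this cross-talk and are recovered with higher fidelity than the
  typical single unit; the test suite asserts that ordering rather than a
  near-perfect per-unit ceiling.

`stability_report` evaluates a frozen decoder on later sessions:
instantaneous per-unit Pearson R against Gaussian-smoothed (σ = 50 ms)
actual rates, plus the correlation of event-triggered averages.

## Rotational dynamics and areal velocity

The LMP is extracted with a 4th-order Butterworth low-pass at 5 Hz applied
forward–backward (zero phase — mandatory because areal velocity is
phase-sensitive). Derivatives are central differences (O(h²), local and
FIR-compatible; at sampling rate fs a pure tone at frequency f is scaled by
sin(2πf/fs)/(2πf/fs), the factor used as the analytic tolerance in the
circle tests). PCA removes per-channel means but never normalizes variance,
preserving the amplitude information the AV–speed relationship depends on;
component signs are fixed deterministically (largest-magnitude coefficient
positive).

jPCA fits `ẋ ≈ M x` with M constrained skew-symmetric, solved in closed form
over the K = n(n−1)/2 skew basis elements (no iterative optimization, hence
deterministic and oracle-checkable). Conjugate-imaginary eigenvalue pairs of
M give planes (orthonormalized real/imaginary eigenvector parts mapped back
to channel space), ordered by |eigenvalue|, with rotation frequency
|λ|/2π. Default pre-reduction: 6 PCs, 2 planes. Plane orientation is fixed
so the mean AV over the fitting span is non-negative.

Areal velocity is evaluated sample-wise; pairwise signals are computed only
for i<j (antisymmetry is structural). The pairwise decomposition identity
`AV_{u,v} = Σ_{i<j}(u_i v_j − u_j v_i) AV_{i,j}` is exact and is used as a
self-check (`plane_decomposition_check`, contract residual < 1e-9 of signal
scale). Banded AV band-passes zero-phase before projection; since the band
removes DC, the plane offset is not re-subtracted there.

## Submovement analysis

Speed peaks are detected on the |velocity| trace low-passed at 10 Hz, with a
relative threshold (10% of the 95th-percentile speed — detection counts are
invariant to uniform speed scaling) and a prominence requirement that
rejects numerical micro-peaks on flat speed. Direction is the angle of net
displacement between flanking speed minima.

For the AV–speed relationship the regression accepts either an AV signal
(bin metric = peak or integral of the average AV trace) or the plane-
projected 2-D trajectory, in which case the *trajectory* is averaged per
speed bin first and the AV of the averaged trajectory is used. The second
form is the preferred one: phase-incoherent background from neighbouring
submovements cancels in the trajectory average instead of inflating the
intercept. Speed bins are equal-count quantiles (default 5).

Direction decoding integrates the 3-PC AV vector over ±0.25 s around each
peak (one 1–4 Hz cycle), normalizes to a unit rotation axis, and fits an
orthogonal (Procrustes) map from axes to the unit vectors of the true
directions, 5-fold cross-validated. The angular coefficient of
determination is `1 − Σ d(θ̂,θ)² / Σ d(θ̄,θ)²` with wrapped differences and
circular-mean baseline — predicting the circular mean scores exactly 0,
perfect prediction 1. The null is the same decoder refitted on
`n_shuffles` seeded permutations of the event–direction pairing; the 95th
percentile is the significance threshold. This CoD definition and the
shuffle construction are declared package choices; circular-correlation
alternatives can be swapped behind the same interface.

## Synthetic generator

The generator emulates: submovements at 2.5/s (1–4/s band) toward 8 targets
with lognormal speeds; cosine-tuned units (baseline 5 Hz, peak 25 Hz) with
per-unit activation latencies (±0.12 s) and widths, spiking as inhomogeneous
Poisson by thinning; rank-3 SRSP kernels built from three Gabor sources
(1.5/2.5/3.5 Hz, delays 0/60/120 ms) mixed across channels as a blend of
shared array-wide profiles (weight 0.6) and per-unit exponentially-decaying
local profiles (weight 0.4) — the shared part reproduces why population
components decode well, the local part makes individual units partially
identifiable; an event-locked rotational LMP whose in-plane radius is
√speed (so AV ∝ speed by construction) and whose rotation axis tilts 10°
with submovement direction under a minimal (Rodrigues) rotation, keeping the
in-plane phase frame common to all directions; white and 1/f noise, optional
common mode. Anatomy (kernels, mixing, rotation frame) is drawn from the
seed alone; events/spikes/noise from a per-`session` stream, so later
sessions share the brain but not the realization.

Preset conditions: `miso_config` (noise and rotation off, 300 s) for kernel
recovery; `rotation_config` (rotation amplitude 1.2, spike kernels 0.03,
noise 0.05) for AV analyses — these amplitudes satisfy the variance-budget
ordering sin²(10°)·var_rotation > top spike-LFP direction, which is the
defining requirement for the direction tilt to appear in the third PC;
`default_config` exercises both pipelines at once (the bundled 120 s
fixture, seed 20160214).

What the generator does **not** emulate: biophysical volume conduction,
spike-waveform leakage into the LFP, electrode drift or unit loss over real
time, non-Poisson spiking statistics, behavioural learning. Passing tests
therefore demonstrate the correctness and statistical behaviour of the
algorithms under the stated generative assumptions, not performance on
monkey recordings. Two quantitative cautions: (1) overlapping submovement
envelopes at 2.5/s create same-frequency cross-terms that shift the naive
analytic AV–speed slope by ~10–15%, so slope recovery is checked against
the generator's rotation-component-in-isolation slope rather than the
closed-form value; (2) with 6 units sharing 3 sources in 8 channels,
per-unit rate estimates carry irreducible cross-talk (noise-free aligned-R
ceiling ≈ 0.5–0.95 per unit, not 1).

## Numerical choices and degenerate inputs

* Time is seconds, float64 throughout; channel order is header order and
  all pair indices refer to it.
* Uniform sampling is enforced at 1e-6 relative tolerance on successive
  intervals; fewer than 2 samples, zero-variance channels for PCA, i=j
  pairs, non-orthonormal planes, degenerate all-equal directions, and
  mismatched unit/channel sets all raise typed validation errors.
* Spike binning uses half-open bins with the final edge closed, conserving
  counts exactly.
* HDF5 model containers are written without modification-time tracking, so
  identical inputs produce byte-identical files; all CLI randomness flows
  through explicit `--seed` flags.

## Problem sizes

Tests and the acceptance script run on sessions of 60–300 s at 100 Hz with
6 units and 8 channels (the scale at which every contract above is sharp),
10-seed grids for the stochastic orderings, and 200–1000-permutation nulls
for direction decoding.
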