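# Methods

This note documents the models and procedures implemented in `tastemix`,
the parameter choices that matter, and what the synthetic-data tests do and
do not establish.

## Session data model

A session is a trial table plus per-unit spike-time lists on a common
session clock (seconds). Each trial records the mixture stimulus (s, in
%Sucrose, one of {0, 25, 35, 45, 55, 65, 75, 100}), the semantic choice
(`sucrose_side`/`nacl_side`; left/right counterbalancing is abstracted
away), the outcome, and the two anchor events: first central lick T and
first lateral lick D, with D > T. Only completed trials are representable —
a trial with no lateral lick has no D and is excluded at ingestion.
Outcomes are validated against stimulus side and choice. Times round-trip
through the CSV files bit-for-bit (shortest-repr writing, round-trip float
parsing).

## Event warping

Firing rates live on a 117-bin axis: 20 pre-T bins and 20 post-D bins of
fixed 50 ms, and 77 bins spanning [T, D), each (D−T)/77 long. The 77/50 ms
combination makes the middle bins average ~50 ms at the typical 3.85 s
inter-event interval; the 20-bin margins realize the 1 s of context on each
side used throughout the analyses. Binning is half-open with a spike at
exactly T entering the first middle bin. Per-bin rate is count/duration, so
Σ(rate·duration) over the middle bins equals the spike count in [T, D)
exactly; this conservation is asserted pre-smoothing. Smoothing uses an
acausal Gaussian kernel 11 bins wide; the kernel SD (2 bins) is a package
choice exposed as config, and the kernel is renormalized at the edges so
constants pass through unchanged. PSTHs are averaged per (stimulus,
outcome) and then smoothed; single-trial tensors can be produced smoothed
(default, used for auROC/profiles to match PSTH-level figures) or raw
(default for decoding) — the original analyses do not pin this down, so
both are one flag away.

## Single-unit statistics

The auROC between rates on predominantly-sucrose (s > 50) and
predominantly-NaCl (s < 50) correct trials is computed per bin as the
normalized Mann-Whitney U of the NaCl sample (ties count 1/2): 0 means
sucrose rates always higher, 1 the reverse. The preference label comes from
the bin maximizing |auROC − 0.5|; ties take the earliest bin and an all-0.5
time course is left unlabeled (both are degenerate cases the measure does
not resolve; fixing them keeps results deterministic). Responsivity
compares window means in sampling [T, T+0.5 s] or delay [D−0.5 s, D]
against baselines [T−3, T−2.5 s] and [D−5.5, D−5 s] (recorded-data mode) or
[T−0.5 s, T] (network mode, which has no long pre-stimulus epoch), two-sided
Mann-Whitney at α = 0.01; selectivity (sucrose vs NaCl sides within the
period) is tested only among responsive units, so the selective set is a
subset of the responsive set by construction.

## Decoding

At each bin, trials are population rate vectors. Leave-one-out
nearest-centroid: centroids are recomputed with the held-out trial removed,
assignment is by Euclidean distance, and distance ties break toward the
smallest label (ties have measure zero with real rates; the rule is for
determinism). Accuracy is class-balanced (mean of per-label hit rates), so
chance is 1/8 for stimulus and 1/2 for choice regardless of imbalance.
Labels left with a single trial are dropped — their centroid is undefined
after hold-out. The significance threshold is k/N with k the smallest hit
count whose binomial upper-tail probability at chance is below α = 0.01;
at N = 137 this gives 28/137 ≈ 0.204 (stimulus) and 83/137 ≈ 0.606
(choice). Sampling/delay summaries average the first 10 bins after T and
the last 10 before D.

## Demixed PCA

The condition tensor X̃ (neuron × 8 stimuli × 2 choices × 117 bins) is
centered per neuron and split into four additive marginalizations — time,
stimulus (+stimulus·time), choice (+choice·time), interaction — that sum
back to the centered data exactly (asserted to 1e−10). Each marginalization
X̃_φ is approximated by a rank-q map F_φD_φ minimizing
‖X̃_φ − FDX̃‖² + SQT‖FDC̃^{1/2}‖² + μ‖FD‖². The solution is closed-form: the
ridge-regularized full-rank regression B = X̃_φX̃ᵀ(X̃X̃ᵀ + SQT·C̃ + μI)⁻¹,
rank-truncated by projecting onto the leading left singular vectors of its
fitted values on the augmented design. At μ = 0, C̃ = 0 this is exact
reduced-rank least squares (verified against an SVD oracle). C̃ defaults to
the average of X̃_φX̃_φᵀ/SQT over marginalizations, as printed in the loss
definition; a single-trial residual covariance is available behind a flag
since the two readings are both defensible. μ is chosen by split-half
cross-validation over trials (deterministic given a seed), with μ = 0 as
the documented fallback when conditions are too thin. Sessions missing a
stimulus×choice condition are completed by per-neuron, per-bin regression
y = β0 + β1·stim + β2·choice + β3·stim·choice on the observed condition
means; single-trial conditions are duplicated first. The "principal" axis
per marginalization is the decoder row with maximal projected variance,
sign-oriented so stimulus projections correlate positively with %Sucrose
and sucrose-side choices project positive (signs are otherwise arbitrary).

## Coding-type classification

The response profile r(s) is the window- and trial-mean rate per stimulus
(correct trials; error trials give r_error). Two templates are fitted by
least squares: a line p1·s + p2 constrained to be nonnegative at the 8
stimulus points, and a step with plateau means and inflection p3 ∈
{40, 50, 60}. The constrained line is solved exactly by enumeration: the
OLS solution if feasible, else the best feasible single-active-constraint
solution (line pinned to zero at one stimulus) or the zero line — a 2-
parameter QP with 8 linear constraints needs no iterative solver. Each
template is scored by F = [(SSE_null − SSE_fit)/SSE_fit]·(Nd−Np)/(Np−1)
against the mean-only null with p from the F(Np−1, Nd−Np) upper tail; the
larger-F template wins if its p < 0.005 (0.01 Bonferroni-corrected for two
templates), else the window is "other". Degenerate cases: a perfect
template fit on a non-constant profile is accepted (F = ∞, p = 0); a
constant profile offers no improvement and is "other". Step winners with
p3 = 50 and δ_correct·δ_error < 0 are step-choice; consistent deltas are
step-perception; a missing error side leaves the step unresolved, and
unresolved steps count as neither subtype in summaries. Windows are 4 bins
(~200 ms warped) stepped by 4 over the 117 bins — 29 full windows plus a
final 1-bin window — plus the two fixed windows, taken as the 10 warped
bins adjacent to T and to D to stay consistent with the decoding windows.
Monte-Carlo on pure-noise profiles shows per-template false-assignment
rates at or below the nominal 0.005 (the winner-take-all competition makes
the step template conservative).

## Psychometrics

y(s) = (p1−p4)/(1+exp(−p2(s−p3))) + p4 is fitted by bounded least squares
(0 ≤ p1, p4 ≤ 1; 15 ≤ p3 ≤ 85; slope unbounded) to the 8 per-stimulus mean
responses, not trialwise likelihoods — curves are always fitted to
session-/model-averaged responses. A fixed multi-start over p2 ∈ {±0.02,
±0.1, ±0.5} makes the fit deterministic and reaches both curve
orientations. Curve comparison is the extra-sum-of-squares F-test of one
pooled curve (df1 = N−4) against separate curves (df2 = N−4k), with
p from the F(df1−df2, df2) upper tail and a K-choose-2 Bonferroni
multiplier; points are unweighted by trial counts (a weighting flag
exists).

## The constrained network

N = Nc + Nu units with Nu = round(5.88·Nc); the decision unit is external
to this count. Dynamics: τḣ = −h + m(x) + W_rec f(h+b) + η with
f(z) = min(max(z, 0), 80) (rates in Hz, capped at 80), m(x) = A²tanh(A¹x)
embedding the mixture as x = [%Suc, %NaCl]/100 (zero when off), and
τż = −z + w_zᵀf(h+b) for the decision unit, c = tanh(z). Integration is
forward Euler at α = dt/τ = 0.2; dt = 50 ms and τ = 250 ms realize the
5.9 s trial as 118 steps with stimulus onset at 1.0 s (on for 1.2 s) and
decision time at 4.9 s. The printed internal-noise formula σ_η = 0.05/α is
applied literally; since η enters the update multiplied by α, the effective
per-step SD is 0.05. The embedding's printed hidden widths are mutually
inconsistent (100 vs 300), so a single configurable width H = 100 is used.

Training minimizes L = 150·L_beh + L_neu: L_beh pins c² near zero over
[T−1 s, T] and (c−γ)² over [D−0.1 s, D] with γ = ±1 by stimulus side;
L_neu is the squared error of the constrained units' rates against the
correct-trial PSTHs, resampled onto the model clock by linear interpolation
assuming the 3.9 s average sampling-to-decision interval. Both are
normalized by their term counts. Gradients are hand-derived
backpropagation-through-time (the clip nonlinearity uses the zero
subgradient at its boundaries) and verified against central finite
differences to < 1e−4 relative error; optimization is Adam (lr 0.01) with
global-norm gradient clipping at 1.0, W_rec's diagonal re-zeroed after
every step, initializations A ~ N(0,1), W_rec ~ N(0, 0.1/N), w_z ~
N(0, 1/N), b = h0 = 0, running one noiseless presentation of each of the 8
stimuli per iteration (internal noise active; it can be disabled, and is
for gradient checks) for 2000 iterations or until L < 1. h0 is a single
trainable vector shared across stimuli.

## Simulations, calibration, ablations

Post-training simulations add persistent input noise ε ~ N(0, σ) to x at
every step (stimulus on or off); the choice is the sign of mean c over the
0.1 s decision window, with an exact 0 mapped to nacl_side (measure-zero,
logged). σ is calibrated per model: ascending grid 0.05–1.5 in steps of
0.05, 20 trials per stimulus per candidate with a fixed seed, first
candidate within 5 accuracy points of the session's accuracy wins;
bisection between the bracketing grid neighbors if none does. Batches of
160 trials (20/stimulus) are cast into the session data model (T = stimulus
onset, D = decision time; tensor bins read directly off the model clock) so
every analysis module applies unchanged. Ablations clamp a unit set's rates
to zero at every step — before both the recurrent input and the decision
readout — with seeds matched to control. Unit sets come from the
response-profile classifier run on the control batch (labeled in ≥ 1
moving window; "other" = never labeled); no separate labeling logic exists.
Models with fewer than 2 trials for either choice direction in any
condition are flagged excluded, since heavily biased behavior would force
imputation-dominated dPCA. The reported "separation" metric projects
condition means (centered across conditions) on the control axes, so a
blunted stimulus or choice signal reads as a drop toward zero.

## Synthetic sessions

The generator emulates the study conditions the analyses assume: 137 trials
over the 8 mixtures and 27 units per session by default; choices drawn from
a 4PL with (p1, p2, p3, p4) = (0.95, 0.08, 50, 0.05) — slope and lapses
chosen so expected overall accuracy is ≈ 0.78, typical for this task — and
inter-event intervals from a truncated normal (mean 3.85 s, SD 0.8 s,
minimum 1 s). Each unit is one of five types: linear (rate = baseline +
gain·s/100·env), step-perception (gain·1[s>50]·env, stimulus-locked in both
correct and error trials), step-choice (gain·1[choice = preferred]·env,
preferred side random per unit), other-responsive (stimulus-independent
event-locked bumps), other-flat. Baselines are drawn from 3–6 Hz and gains
from 8–14 Hz, firing-rate scales typical of cortical recordings that put
tuned responses well above Poisson noise at tens of trials per stimulus.
Envelopes are a Gaussian bump just after T (width 0.5 s) and/or a linear
ramp into D; the temporal profile is a modeling convenience — any smooth
envelope expressing tuning inside the analysis windows would do. Error
trials arise from the stochastic psychometric rather than injection, so
the step-choice consistency criterion is testable. Spiking is
time-discretized Poisson thinning on a 1 ms grid; 3.5 s of pre-T activity
is simulated so the long experimental baselines exist. Poisson variability
is an assumption, not a measured property of cortical data.

What passing tests establish: the pipeline recovers planted structure
(coding labels, psychometric parameters, demixed axes) under Poisson noise
at realistic rates and trial counts, and all algebraic contracts hold. What
they do not establish: behavior on real recordings with correlated noise,
non-Poisson spiking, drift, or unit instability — none of which the
generator models (inter-unit correlations beyond shared tuning are
deliberately absent).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen as the package's
own defaults: label-recovery suites use 400-trial/20-unit sessions
(≥ 15 correct trials per stimulus, the regime where template tests are
well-powered); the trained-network checks use Nc = 10 (N = 69) and Nc = 5
ensembles with the full 2000-iteration budget, which train in tens of
seconds in NumPy. Type-I calibration uses 10⁴ Monte-Carlo profiles.
Degenerate inputs are resolved explicitly throughout (ties to the earliest
bin / smallest label, empty samples to missing, zero vectors to errors) so
every reported number is deterministic given a seed.
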