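# Methods

This note documents the models, parameter choices, and numerical decisions
behind `hopfec`, and what the synthetic-cohort validation does and does not
establish about real data.

## Task design and sampling

The design template is fixed: 10 s fixation, then three identical 180-s
cycles of [8 × (5-s image + 5-s blank) encoding | 10-s counting baseline |
8 × (5-s image + 5-s blank) retrieval | 10-s counting baseline], total
550 s, 24 encoding and 24 retrieval trials. One acquisition per task holds
696 volumes at TR = 0.8 s (556.8 s); the 9 samples past 550 s are prompt-time
padding and belong to no analysis phase. The three within-acquisition cycles
are what "runs" of a task denote throughout: cycle averaging is the
run-averaging step.

Events (multiples of 5 s) do not align with the 0.8-s sampling grid, so a
sample belongs to an event iff its midpoint time falls inside the event.
This midpoint rule is deterministic, makes the three cycles congruent
(225 samples each, with identical relative phase masks: 100 storage, 100
recall samples per cycle), and partitions every sample into exactly one of
storage / recall / baseline / fixation / padding. Storage and recall masks
include the blank-screen halves of their trials: the 0.1-Hz rise-and-fall
that RMSSD measures spans them.

## Parcellation

The packaged scheme has the 360 HCP-MMP cortical region labels, 180 per
hemisphere, stored as a TSV (index, label, hemisphere, group) in the
canonical Glasser index order (left block then right block). Reduced schemes
are label subsets that always keep both hemispheres of a pair, so hemisphere
means and R−L laterality stay defined at any scale. The a-priori ROI sets
are: scene stream (VMV1, VMV2, VMV3, VVC, PHA1, PHA2, PHA3), semantic
(STGa, STSda, STSdp, STSvp, TGd, TGv, PSL), Broca (44, 45, 47l), reward
(d32, p24, pOFC, s32, 10d, 10pp, 11l, a10p, OFC, p10p), and intraparietal
(LIPv, MIP, VIP).

## Synthetic cohorts

Each region is a Stuart–Landau (Hopf normal form) oscillator, coupled
diffusively through a nonnegative directed matrix C oriented column→row and
driven by additive Gaussian noise (equations in the README). Integration is
Euler–Maruyama at dt = 0.1 s with a 60-s discarded burn-in; the x component
subsampled at TR is the BOLD-like signal. TR/dt must be an integer.

Defaults (per region unless noted): a = −0.02 (noise-driven regime),
f = 0.05 Hz (ω = 2π·0.05 rad/s), global coupling G = 1, noise σ = 0.01.
Explicit Euler inflates the noiseless limit-cycle radius by the rotation
error, r² ≈ a + ω²dt/2 — at dt = 0.1 and a = 0.04 the radius is ~6% high —
so the analytic amplitude check runs at dt = 0.01 (error ≈ 0.6%); for the
noise-driven default regime this bias is immaterial.

Task structure is injected additively: a boxcar over the 5-s image
presentations of the targeted phase, convolved with a canonical double-gamma
haemodynamic response (peak 6 s, undershoot 16 s, undershoot ratio 1/6,
kernel peak-normalized), scaled by `base_amplitude × gain` and a
per-participant log-normal jitter, added only to the targeted ROI, task,
phase, and hemisphere. `base_amplitude` defaults to 0.02, about half the
noise-driven signal SD (~0.04), giving comfortably detectable but not
saturating effects at n = 23. Untargeted regions are bit-identical before
and after injection. Per-participant heterogeneity is multiplicative
log-normal jitter on effect gains (SD 0.2) and on coupling entries (SD 0.1,
re-clipped to 0.2). Cohort generation is a pure function of
(specification, seed): per-participant × task sub-seeds come from a seed
sequence, and the manifest records a SHA-256 digest per file.

The generator emulates: parcellated region-level BOLD with a realistic
band-limited spectrum, paradigm-locked responses, known directed coupling,
between-participant variability, and the study geometry (23 participants ×
3 tasks × 696 samples). It does **not** emulate: haemodynamic convolution of
the intrinsic (non-task) dynamics, scanner drift and physiological noise,
head motion, regional haemodynamic variability, or spatial autocorrelation
between neighbouring parcels. Passing tests therefore establish internal
consistency and estimator correctness under the model's assumptions, not
performance on real scanner data.

## Activation (RMSSD)

Per participant, region, task, and phase:
linear detrend → second-order zero-phase Butterworth band-pass 0.05–0.15 Hz
(bracketing the 0.1-Hz trial fundamental; configurable) → average the three
cycle segments → mask the phase samples → RMSSD, √(mean (x_{t+1}−x_t)²).
Filters are applied forward–backward so no group delay shifts the signal
against the phase masks. On band-limited signals RMSSD is nearly
proportional to the SD of the same series (RMSSD = SD·√(2(1−r₁)) with lag-1
autocorrelation r₁ roughly common across regions), which is why the two
rank regions almost identically on synthetic cohorts. Hemisphere mean is
(L+R)/2 per label; laterality is plain R−L per label, with the grand-mean
activation reported separately as the conventional display baseline.

## Functional and effective connectivity

FC is the Pearson correlation of detrended, 0.008–0.08 Hz band-passed
signals over the full 696-sample run; lagged FC entry (i, j) is
corr(x_i(t), x_j(t+lag)). The nominal delay τ = 2.0 s becomes an integer lag
by rounding τ/TR half away from zero: 3 samples (2.4 s) at TR 0.8 s. No
fractional-lag interpolation is attempted. Group matrices are Fisher-z
averages across participants.

GEC fits C by stochastic moment matching, starting from C = 0. Each
iteration simulates the Hopf model with the current C (seeded from
(config seed, iteration)), passes the simulated series through the *same*
detrend + band-pass as the empirical data — without this the band-passed
empirical correlations exceed the raw simulated ones and the coupling
inflates into the cap — and updates every off-diagonal entry by
ε·[(FC_emp−FC_sim) + (lagFC_emp−lagFC_sim)], clipped to [0, 0.2].

Defaults: ε = 2×10⁻³, 300 iterations, 696 simulated samples per iteration.
Because the per-iteration mismatch is estimated from one finite simulation,
convergence is judged on a 10-iteration moving average (patience 100) and
the **final** iterate is returned; selecting the argmin of the raw error
sequence would pick whichever under-converged iterate drew the luckiest
simulation noise (measured: recovery 0.66 vs 0.73). The raw error trace and
its running minimum are kept in the diagnostics. All hyperparameters are
config-exposed; the defaults were set by ground-truth recovery experiments.

Orientation: matrices are read column→row. At τ ≈ 2 s the lagged-FC
asymmetry of this model family loads the reverse of the generative
direction (its correlation with the true asymmetry is negative), so with
`reverse_for_fmri` (default on) the fitted matrix is transposed before
reporting — on synthetic cohorts the transposed estimate, not the raw one,
recovers the generative coupling. The directional difference D = C − Cᵀ is
antisymmetric by construction; split-half reliability splits participants
into ⌊n/2⌋ and ⌈n/2⌉ by a seeded shuffle and correlates the off-diagonal
entries of the two halves' group estimates (both in the same orientation).

## Recovery benchmark

Direction is only identifiable when the linear relaxation time 1/|a| is
comparable to the lag. At the cohort default a = −0.02 (relaxation 50 s)
the 2.4-s lag carries essentially no directional information and only the
symmetric part of C is recoverable — a structural limitation of delayed
correlations near criticality, not an implementation artifact. The recovery
benchmark therefore runs at a = −0.2 (relaxation 5 s): a 10-region network,
edge density 0.3, edge weights uniform in [0.05, 0.2] (bounded away from
zero so every scored edge is detectable in principle), 23 participants of
696 samples. Under these frozen conditions the group estimate correlates
with the generative coupling at r ≈ 0.73, rising to ≈ 0.75 at 4× the data
length, and an empty network yields mean |EC| ≈ 0.002.

## Statistics

ROI mean is the unweighted mean over the ROI's regions (both hemispheres
unless scoped). The paired t-test uses t = mean(d)/(sd(d)/√n) with the
(n−1)-denominator SD and df = n−1; zero-variance differences report t = ±∞
with p = 0 (nonzero mean) or t = 0, p = 1 (all-zero). The packaged battery
tests the a-priori hypotheses (scene-stream selectivity for the location
tasks in storage and recall, semantic and Broca selectivity for word pairs,
reward-system selectivity for reward-location storage, intraparietal
selectivity for the location tasks, and storage-vs-recall effects for the
semantic, Broca, and reward systems) at the two-tailed p < 0.02 criterion.
No multiplicity correction is layered on top: the a-priori alpha is the
stated policy, and alpha is configurable. ROI means pool both hemispheres
by default; left-scoped variants are available through the hemisphere
scope, reflecting the left-hemisphere emphasis of the language contrasts.

## Problem sizes

The packaged default configuration runs the full pipeline on a reduced
76-region scheme (the 30 ROI labels plus early- and ventrolateral-visual
regions, hemisphere pairs intact) with 23 participants × 3 tasks — the full
simulate → report chain completes in well under a minute, and the recovery
benchmark in tens of seconds. The full 360-region scheme is supported
throughout; simulation and GEC fitting scale as the square of region count.

## Known limitations

- The lagged-correlation update recovers direction only away from
  criticality; near a = 0 the estimate is effectively symmetric.
- EC is constrained nonnegative with a hard 0.2 cap; inhibitory or stronger
  couplings are not representable.
- The Hopf signal is fitted directly to band-limited data; no haemodynamic
  forward model is applied to the intrinsic dynamics, so absolute coupling
  scales are model-relative.
- The estimator returns a stochastic fit: two configurations differing only
  in seed give slightly different matrices (split-half and seed-averaged
  checks quantify this).
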