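# Methods

This note records the models, estimators and design decisions behind
`popdim`, including choices that were genuinely open and what the synthetic
generator does and does not emulate.

## Task and data model

A session is a spike-count tensor (neurons × trials × bins) plus a trial
table. The task constants are fixed by design: 80-trial blocks, 12 blocks
per condition randomly interleaved, a reversal on a uniformly random trial
in [30, 50] (1-based; the phase is "reversal" from that trial onward), and
a 0.7/0.3 Bernoulli reward schedule on the chosen image (What) or saccade
direction (Where). Analysis bins are half-open windows [1, 251) and
[251, 501) ms after cue onset; the half-open convention prevents boundary
spikes from being counted twice. Trial indices are 1-based in tables and
0-based in arrays, with the conversion confined to I/O.

The class label of a trial is the chosen image in What blocks and the
chosen direction in Where blocks; a label adapter can substitute the reward
outcome (1 = rewarded, 2 = unrewarded) so that every choice analysis runs
unchanged on reward-locked activity.

## Subspace identification

The informative direction of a block/phase/bin is w = μ₂ − μ₁, the
difference of class-mean population vectors; the noise covariance in the
discriminant w = Q⁻¹Δμ is approximated by the identity. The first four
trials of each phase are removed as learning trials before estimation. The
removal is counted per phase by default (`min_trial_in_phase=5`); a
per-block variant is exposed because the two readings differ only for the
reversal phase. Blocks need at least `min_trials=4` analyzed trials of each
choice in each phase (the smallest count that leaves a nondegenerate
leave-3-out fold); others are excluded everywhere.

Cross-validated directions leave out the tested trial and its neighbors.
Neighbors are defined in analyzed-trial order (after the first-4 removal)
rather than raw task order, which keeps fold sizes balanced; at phase edges
only the existing neighbors are dropped. Within-subspace information and
decoding are always computed from these leave-3-out folds — projecting
trials onto the pooled direction estimated from the same trials overfits
badly (on null data it roughly doubles the apparent information).

U collects class means (block-major, then phase, choice, bin: 192 columns
at full shape) and W their differences (96 columns). W's columns are built
from pooled analyzed trials; the pooled direction equals the average of the
leave-3-out directions up to edge effects. Zero columns are retained.

## Dimensionality

Spectra are eigenvalues of MMᵀ, i.e. squared singular values of M, padded
with zeros to the column count so cumulative fractions end at 1. No column
centering is applied by default (the decomposition acts on WWᵀ directly);
centering is exposed as an option and changes the thresholds. Note that
U's uncentered spectrum is dominated by the static grand-mean component
(baseline plus the mean of the choice-common component), which all columns
share; the discriminant matrix W cancels it, which is why subsequent
analyses are based on W. k-at-threshold uses the smallest k whose
cumulative fraction reaches the threshold. Block-accumulation curves use
100 seeded resamples by default, with a single exhaustive draw at the full
block count.

Cross-validated variance removes one analyzed trial per choice from a
randomly drawn block/phase, rebuilds the affected U columns, and measures
the squared-norm fraction of each held-out per-bin trial vector captured by
the leading eigendimensions, averaged over folds. The normalization
(projection energy over the held-out vector's total energy) and the
fold-averaging are package choices; they make the held-out curve directly
comparable to the within-sample cumulative curve, below which it must lie
on noisy data.

## Information, decoding, principal angles

Information along a stacked (two-bin) direction is I = (Δμ_z)²/σ_z², with
mean and pooled variance re-estimated after projection; it is invariant to
rescaling of the direction. Predicted error is the upper Gaussian tail at
√I/2. Measured decoding projects trials into the 2-column per-bin basis,
re-estimates class means with leave-one-out, and assigns each trial to the
nearest centroid under a Mahalanobis metric whose pooled 2×2 covariance is
estimated leave-one-block-out (class-centered within every block/phase of
the other blocks). Ill-conditioned covariances are blended toward a scaled
identity (γ = 0.05) with a logged warning. Ties break toward class 1.

For x-block and x-cond, the target is evaluated against each source
block's subspace separately and the resulting metrics averaged (the
alternative — pooling sources before evaluation — was rejected to keep the
per-source principal angles and the information average interpretable).
The principal angle between two subspaces is the arccosine of the largest
singular value of the orthonormalized cross-Gram matrix ("spectral"
convention, the first principal angle); a root-mean-square variant is
available behind a flag.

A caution on chance levels: with unbalanced classes, nearest-centroid
classification of pure noise drifts toward the majority base rate (the
overfit discriminant displaces the projected midpoint), so "chance" is 0.5
only for balanced sampling. The null fixture therefore samples choices
uniformly at random.

## Learning dynamics

Δinformation of a trial is M_other − M_chosen, the difference of
Mahalanobis distances from its projection to the two options' learned
distributions. Within-subspace curves estimate those distributions from
trials ≥ 5 of the same phase, excluding the scored trial (leave-one-out, to
avoid self-distance bias — the exclusion is a package choice). X-block
curves score the target's trials against the source block's own projected
distributions without re-estimating means after projection, which is why
their values sit much lower than the within curves. Curves default to
trials 1–25 of the acquisition phase (so trial 1 reflects initial learning,
not post-reversal carry-over); reversal-aligned curves score reversal-phase
trials in both the acquisition-phase and reversal-phase frames of the same
block. Trajectory plots use the block-phase subspace rotated into the
eigenbasis of the projected 2×2 covariance; ellipses, if drawn, are sample
1-sd ellipses.

## Behavior

The Rescorla–Wagner fit uses V₀ = 0.5 at each block start (new images),
box-constrained L-BFGS-B from a small grid of starts, with α, β shared
across the session's blocks (per-session fitting is a package choice; a
condition argument restricts the fit). The value regressor for the neuron
screen is the pre-update value of the chosen option. Accuracy curves
interpolate each phase to a common grid (30 + 45 points) before averaging
and smooth with a Gaussian kernel of sd 1 trial; the initially better
option is inferred from acquisition reward frequencies, as it would be for
real data. Trials-to-criterion applies a one-sided binomial test per trial
index with no multiple-comparison correction, matching the screen, which
likewise reports raw p < 0.05 fractions.

The single-neuron screen is a vectorized linear model: one design matrix
per condition (block, image nested in block, direction, reward, continuous
RW value), fit to all neurons and bins at once, with each factor tested by
the extra-sum-of-squares F between the full and the factor-dropped design.
Constant factors are dropped with a warning (e.g. the block factor in a
single-block session). On null data the expected significant fraction per
factor is the nominal 0.05.

## The synthetic generator

Rates are `baseline + c·g_k + d_k·s_k·w(block, phase, bin)` with Poisson
counts on rectified rates (a Gaussian option with controllable sd exists
for closed-form checks). Baselines are Gamma-distributed with mean 5
spikes/s. The choice-common component c has norm √var_common (default
variance 100 rate-units², i.e. sd 10 spikes/s along one fixed direction)
and a trial gain g_k ~ N(1, 1), giving U the high-variance common
structure that W cancels.

Informative directions are unit vectors composed of four mutually
orthonormal parts — global, condition-shared, block, phase-private — whose
squared weights set all pairwise cosines exactly: cross-condition 0.10,
cross-block 0.25 (What) / 0.80 (Where), cross-phase 0.55 (What) / 0.95
(Where). Where directions thus lie near a fixed shared subspace (two
dimensions, one per bin) while each What block/phase claims largely fresh
dimensions. The nonzero What overlap is deliberate: real cross-block
information is reduced, not abolished, and the ordering of information
across subspaces is only well-defined with some sharing.

The drive d_k = (1 − exp(−t/τ))·|ΔV_k| ties neural separation to the
agent's learned value difference (τ = 5 trials) and resets at the
reversal. Two asymmetries implement known differences between conditions:
Where blocks have a non-learned floor on direction coding
(`where_floor = 0.5` of the asymptotic value difference — saccade direction
is an overlearned motor feature, encoded from trial 1), and during the
reversal phase the acquisition pattern carries over with weight
`exp(−t/τ)·d_end`, so the first post-reversal trials still resemble the
acquisition distribution. Reward-locked sessions use a single direction
pair shared across all blocks and conditions with constant drive, so
outcome coding shows no What/Where dimensionality difference.

Remaining defaults were calibrated once so that within-block decoding of a
default session lands mid-way in the 0.7–0.95 fraction-correct range:
population size 200 units ("several hundred"), signal norm
`snr_signal = 35` spikes/s at unit drive, agent α = 0.3 and β = 3 (asymptotic
choice accuracy ≈ 0.77, enough exploration that blocks rarely fail the
usable rule).

What the generator does **not** emulate: noise correlations beyond the
single common component (Q is diagonal by construction, so identity-Q
decoding is near-optimal by design rather than by approximation), temporal
dynamics finer than the analysis bins, session-to-session drift,
non-Poisson spiking statistics, and eye-movement or stimulus confounds.
Passing tests therefore validate the estimators and the qualitative
What/Where contrasts under this generative model, not claims about any
real recording.

## Known limitations and numerical notes

- Information estimates are ratio statistics and heavy-tailed at small
  trial counts; comparisons across sessions use paired tests on replicate
  simulations rather than single-session values.
- Because the drive is coupled to |ΔV|, minority-choice trials occur at
  lower drive, slightly displacing the minority learned centroid toward
  the origin; trial-1 Δinformation in What blocks is therefore near zero
  but can dip slightly negative.
- The usable-block rule makes column counts of U/W data-dependent; the
  full 192/96 shape requires all 24 blocks to pass, which a typical
  default session misses by 1–3 blocks (the canned "paper-shape" fixture
  seed passes with all 24).
- Simulation sizes in the test suite (20 replicate sessions of 200 neurons;
  smaller configurations for unit tests) were chosen as the smallest runs
  at which the seeded statistical contrasts are stable.
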