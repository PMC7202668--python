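# popdim

Analysis pipeline for the dimensionality, information content and learning
dynamics of neural population activity in a two-armed bandit
reversal-learning task, together with a synthetic session generator that
produces populations with known ground truth.

## The scientific problem

In the task, a subject repeatedly chooses between two options in 80-trial
blocks. In *What* blocks the reward depends on which of two novel images is
chosen (p = 0.7 vs 0.3); in *Where* blocks it depends on the saccade
direction. The contingency reverses on a random trial between 30 and 50.
Because each What block introduces new images, value learning restarts every
block, and one can ask how learning reshapes the geometry of population
activity in prefrontal cortex: do newly learned values occupy fresh
dimensions of coding space (raising dimensionality across blocks), or do
they reuse a shared subspace, as repeated actions do?

The package implements the full analysis chain used to answer this on
trial-structured spike counts (`neurons × trials × bins` plus a trial
table):

- **Informative directions.** Per block, phase and 250 ms bin, the linear
  discriminant w = μ₂ − μ₁ (difference of choice-conditioned mean
  population vectors; the noise covariance Q is approximated by the
  identity). Estimated with leave-3-out cross-validation; the first four
  trials of each phase are treated as learning trials and removed; blocks
  with too few trials of either choice are excluded.
- **Dimensionality.** Eigen-decomposition of WWᵀ (equivalently squared
  singular values of the neuron × condition matrices U and W); k₈₀/k₉₀ are
  the smallest dimension counts reaching 80%/90% cumulative variance.
  Includes block-accumulation curves, first-PC removal, and cross-validated
  single-trial variance.
- **Information and decoding.** For a projection direction w_s,
  I = (w_sᵀΔμ)² / (w_sᵀQw_s), estimated after projection with the two bins
  stacked; predicted error is the upper Gaussian tail at √I/2. Measured
  decoding projects trials into a 2-D (per-bin) subspace, re-estimates
  class means there, and classifies by Mahalanobis nearest centroid with a
  leave-one-block-out pooled covariance. Subspaces are taken from the same
  block (within), the opposite phase (x-phase), other blocks of the same
  condition (x-block) or the other condition (x-cond); principal angles
  between subspaces quantify their overlap directly.
- **Learning dynamics.** Trial-wise Δinformation = M_other − M_chosen, the
  difference of Mahalanobis distances from a trial's projection to the two
  options' learned distributions, tracked over trials in phase and around
  reversals.
- **Behavior.** Rescorla–Wagner value estimation (V ← V + α(r − V), softmax
  choice) by maximum likelihood, interpolated/smoothed accuracy curves,
  binomial trials-to-criterion, and a per-neuron linear-model screen
  (factors: image nested in block, direction, RW value, block, reward).

No public recordings exist for this task, so the `synthetic` module is a
first-class component: it simulates agent behavior and Poisson (or
Gaussian) population activity whose informative directions have
configurable overlap structure — fresh near-orthogonal directions per What
block, a shared low-dimensional subspace across Where blocks — with the
learning ramp tied to the agent's value difference, and retains the ground
truth for recovery tests.

## Worked example

```python
from popdim import (GeneratorConfig, simulate_session, build_W, usable_blocks,
                    condition_split_spectra, pairing_report)

session, truth = simulate_session(GeneratorConfig(), seed=7)
blocks = usable_blocks(session)
w = build_W(session, blocks)
print(f"usable blocks: {len(blocks)} / 24; W has {w.matrix.shape[1]} columns")
for cond, res in condition_split_spectra(w).items():
    print(f"{cond}: k80 = {res.dims_at(0.8)}, k90 = {res.dims_at(0.9)}")
rep = pairing_report(session, w=w)
print(rep.groupby(["condition", "pairing"])[
    ["information", "fraction_correct", "principal_angle_deg"]].mean().round(2))
```

prints

```
usable blocks: 23 / 24; W has 92 columns
What: k80 = 25, k90 = 32
Where: k80 = 20, k90 = 29
                   information  fraction_correct  principal_angle_deg
condition pairing
What      within          7.75              0.88                 0.00
          x-block         1.25              0.68                79.58
          x-cond          0.34              0.58                82.49
          x-phase         4.32              0.83                72.43
Where     within         13.25              0.92                 0.00
          x-block        10.59              0.92                63.89
          x-cond          0.34              0.58                82.49
          x-phase        14.51              0.95                56.78
```

Reading the output: the What split of W needs more dimensions than the
Where split (25 vs 20 at 80% variance) because each What block's
discriminant occupies largely fresh dimensions. Information and decoding
fall off steeply from within to x-block for What (7.75 → 1.25; 0.88 → 0.68)
but barely for Where (13.25 → 10.59; decoding unchanged), and cross-block
principal angles are closer to orthogonal for What (80°) than Where (64°) —
the signature of value learning claiming new coding dimensions per image
pair while direction coding reuses a shared subspace.

The same chain runs end to end from the command line:

```bash
popdim run --out results/run0 --seed 0        # full pipeline + JSON summary
popdim simulate --out s.h5 --seed 1           # just a synthetic session
popdim dims s.h5                              # spectral dimensionality
popdim info s.h5 --out pairings.csv           # information/decoding table
```

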