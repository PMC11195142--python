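# Methods

`bleachcount` converts single-molecule GFP photobleaching traces into a
statistically corrected oligomer distribution. This note records the models,
the numerical choices, and what the synthetic benchmarks do and do not show.

## The counting problem

In a single-molecule pulldown (SiMPull) experiment, GFP-tagged membrane
protein complexes are captured in polymer nanodiscs, immobilized sparsely on
a slide and imaged by TIRF microscopy until every fluorophore bleaches. A
complex with *s* subunits should show *s* discrete intensity drops. Two
systematic effects break the naive count:

1. **Incomplete maturation.** Each GFP folds into a fluorescent state with
   probability *r* (≈ 0.7 for GFP); immature copies are invisible, so a
   dimer frequently shows one step.
2. **Detection truncation.** A complex whose GFPs all failed to mature emits
   nothing and is never selected for analysis, so the zero-step category is
   structurally missing rather than merely noisy.

## Maturation model

With independent maturation, the number *w* of mature GFPs in an *s*-mer is
binomial: π_{s→w} = C(s,w) r^w (1−r)^{s−w}. Conditioning on detection
(w ≥ 1) gives η_{s→w} = π_{s→w}/(1−π_{s→0}) and η_{s→0} = 0. Subunit counts
are modeled up to s = 3, with the "3" class meaning *trimer or larger* to
match the experimental binning of three-or-more steps; how true tetramers
map onto a 3-state model is an acknowledged approximation of the model
itself, not of this implementation. The η denominator is computed as
−expm1(s·log1p(−r)) to avoid cancellation at small r; matrices are
recomputed from *r* on access so no stale state can survive a parameter
change.

## Inference

The target is q = (q₁, q₂, q₃) on the 2-simplex: the fractions of complexes
that are monomer, dimer, trimer-or-larger. The generative model for each of
N analyzed traces is

    s_n | q ~ Categorical(q),   w_n | s_n ~ Categorical(η[s_n, ·]),

with a flat Dirichlet(1, 1, 1) prior on q. Because traces are exchangeable,
the data reduce to the tally (n₁, n₂, n₃).

**Sampler.** Posterior sampling uses a two-block Gibbs scheme chosen because
both conditionals are exact: (1) the latent tally of each step category is a
multinomial over s ≥ w with probabilities ∝ q_s η_{s→w}; (2) q is drawn
from the conjugate Dirichlet(α + latent tallies). There are no tuning
parameters. A counter-based Philox generator seeded by the user drives the
whole chain; identical inputs give bit-identical sample streams.

**Chain length.** Defaults are 20 000 iterations with 5 000 burn-in and no
thinning. Mixing is excellent at high *r* but the data augmentation slows
down at low maturation with dimer-heavy tallies (we have observed effective
sample sizes near 500 out of 15 000 retained draws at r = 0.5); the
per-component effective sample size is therefore reported with every run so
Monte-Carlo error (sd/√ESS) can be judged, and validation comparisons
against the quadrature oracle use 60 000 iterations to push MC error well
below the comparison scale.

**Oracle.** `exact_posterior_grid` integrates the unnormalized posterior
over a triangulation of the simplex into resolution² congruent cells,
evaluating at cell centroids (an equal-weight midpoint rule, O(1/resolution²)
error, no boundary evaluations). At the default resolution of 400 it
reproduces Dirichlet closed forms to ~10⁻⁵. It shares no code path with the
sampler and exists to validate it.

**Model consistency caveat.** η conditions each trace on detection, but the
prior s_n ~ Categorical(q) is *not* tilted by the s-dependent detection
probability 1−(1−r)^s. Under the physical generative process the
s-distribution among detected traces is q_s(1−(1−r)^s)/Σ_j q_j(1−(1−r)^j),
so the model's q estimates converge to that tilted distribution rather than
the population q (at q = (0.2, 0.3, 0.5), r = 0.7 the tilt is
(0.156, 0.303, 0.541), i.e. a worst-case systematic shift of ≈ 0.044). The
model is implemented exactly as stated; the simulator's two modes exist to
measure this bias, not to hide it.

## Step detection

The paper-side step caller is a penalized least-squares change-point fit:

- **Noise scale** σ is the median absolute first difference divided by
  √2·Φ⁻¹(0.75) — consistent for Gaussian noise and insensitive to the few
  frames that straddle steps.
- **Segmentation** minimizes within-segment squared error plus a penalty of
  `penalty`·σ²·log n per change-point (BIC-like), solved exactly by optimal
  partitioning with PELT pruning (O(n) candidates in practice). The default
  penalty constant 3.0 was set so that noise 20× below the step height
  produces no spurious calls while steps/noise = 5 is still resolved; 2.0
  admitted rare false splits adjacent to true steps.
- **Thresholding**: fitted jumps below `min_step_sigma`·σ (default 3σ) are
  iteratively merged, smallest first.
- **Rejection rules**: any remaining upward jump (blinking or aggregation)
  rejects the trace; no downward jump rejects it as zero-step (such traces
  are structurally unobservable in the model); more than `max_steps`
  (default 10) rejects it as anomalous; and the final segment must lie
  within 2σ of the lowest *fitted* level. The raw trace minimum is not used
  as the baseline reference because with Gaussian noise the minimum of a
  few hundred frames sits ≈ 3σ below the true baseline and would reject
  essentially every valid trace. Rejections are tallied by reason and
  reported, never silently dropped.

Accepted calls are binned n₁/n₂/n₃ with three-or-more steps collapsed into
n₃ ("higher-order"). The caller is deterministic and scale-equivariant
(penalty ∝ σ², thresholds ∝ σ).

## Synthetic data

The simulator provides ground truth for every other module.

- **Counts, model-faithful mode**: s ~ Categorical(q), w ~ Categorical(η[s,·])
  — exactly the likelihood the sampler inverts. Used for calibration and
  recovery tests.
- **Counts, physical mode**: s ~ Categorical(q), m ~ Binomial(s, r),
  complexes with m = 0 discarded (and reported), w = min(m, 3). Used to
  measure the detection-tilt bias above; the discard fraction matches
  Σ q_s(1−r)^s.
- **Traces**: each delivered complex's m visible GFPs get independent
  Exponential(bleach_rate) bleach times; intensity is background +
  unit_intensity × (survivors) + Gaussian noise. Bleach events that would
  share a frame are nudged onto distinct frames and the trace flagged
  `coincident`. Defaults: 100 ms frames, 600 frames (60 s), unit intensity
  100 over background 50, noise σ = 12.5 (step/noise 8), bleach rate
  0.1 s⁻¹. The 10 s mean bleach time is typical for GFP under continuous
  TIRF illumination and keeps both tails small: the chance a GFP survives
  the window is e⁻⁶ ≈ 0.25%, and same-frame double bleaches are rare
  (~2% per adjacent pair) rather than the ~14% a 2 s bleach time would
  produce.

What the simulator does **not** emulate: EMCCD gain and shot noise, blinking
(except through the explicit `inject_blink` helper), focus drift, spot
overlap, or any upstream spot-detection errors. Passing recovery tests
therefore demonstrate the correctness of the statistical chain, not
robustness to every camera artifact in real movies.

## Supporting quantifications

- **Co-capture.** With receptors spread uniformly at density ρ (molecules/µm²),
  nanodisc occupancy is Poisson with mean λ = ρπ(d/2)². Since only occupied
  discs are imaged, the reported co-capture probability is
  P(K≥2 | K≥1) = (1−e^{−λ}−λe^{−λ})/(1−e^{−λ}); the raw λ is emitted
  alongside for readers who interpret density × area directly. At
  ρ = 253 µm⁻² and d = 25 nm: λ ≈ 0.124, P ≈ 6.1%.
- **GPMV density.** Per-molecule brightness comes from a purified GFP
  standard (intensity / (concentration·N_A·volume)); the imaged membrane
  patch is modeled as a spherical zone of height equal to the optical slice
  thickness, area π·D·h (clamped to the full sphere πD² when the slice spans
  the vesicle). The zone model is this package's documented choice; the
  area formula for the confocal geometry is not uniquely determined by the
  named inputs.
- **Lipid quantitation.** pmol = C_IS × (lipid peak area / standard peak
  area) × extract volume (default 40 µL).

## Problem sizes used in validation

Recovery and end-to-end benchmarks run at N = 2000 traces (50 replicates
for coverage), the step-caller benchmark at 1000 traces of 600 frames, the
co-capture placement oracle at 10⁵ discs, and oracle-equivalence checks at
tallies of N ≤ 200 with a resolution-400 grid. These sizes give binomial /
Monte-Carlo errors comfortably below each check's tolerance.

## Known limitations

- s_max = 3 bins all higher-order species together; true tetramer content
  is not separable from trimers.
- r is a fixed input (literature value); it is not estimated from data, and
  errors in r propagate directly into q̂.
- The detection-tilt inconsistency described above means posterior means
  answer "what is the composition of *detected* complexes" under the
  physical process; at r = 0.7 the distinction is a few percent.
- The step caller assumes a flat baseline and equal per-GFP brightness;
  strongly varying single-fluorophore intensities would require a
  height-aware model.
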