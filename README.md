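# bleachcount

Single-molecule photobleaching step counting and maturation-corrected
oligomer distributions for SiMPull-style TIRF experiments.

## The problem

Counting photobleaching steps is the standard way to read the subunit
stoichiometry of GFP-tagged membrane protein complexes captured in
nanodiscs: an *s*-mer should bleach in *s* discrete steps. But GFP matures
into its fluorescent state with probability r ≈ 0.7, so a dimer often shows
one step — and a complex whose GFPs *all* failed to mature shows zero steps
and is never picked up at all, truncating the data. Raw step histograms
therefore systematically understate oligomerization.

`bleachcount` implements the full computational chain for experimentalists
running these assays:

- a deterministic change-point **step caller** for intensity traces, with
  explicit rejection rules (upward jumps, incomplete bleaching, too many
  steps) and an audit of every rejection;
- a Bayesian **correction** from step tallies (n₁, n₂, n₃₊) to the oligomer
  distribution q = (q₁, q₂, q₃) on the simplex. With
  π_{s→w} = C(s,w) r^w (1−r)^{s−w} and η_{s→w} = π_{s→w}/(1−π_{s→0}) for
  w ≥ 1 (η_{s→0} = 0), the model is
  s_n ~ Categorical(q), w_n | s_n ~ Categorical(η[s_n,·]),
  q ~ Dirichlet(1,1,1), sampled by a two-block Gibbs chain with an exact
  simplex-quadrature oracle for validation;
- a **simulator** producing traces and tallies with known ground truth, in
  both the model's own generative law and the physical
  maturation-then-detection process;
- **supporting quantifications**: Poisson co-capture probability for
  nanodiscs, receptor surface density from calibrated GPMV fluorescence,
  and internal-standard lipid quantitation.

## Worked example

Simulate 500 nanodisc captures from a population that is 80% dimer
(r = 0.7), call steps, and infer the corrected distribution:

```
$ bleachcount simulate --q 0.1,0.8,0.1 --r 0.7 --n 500 --seed 42 --outdir sim
INFO seed=42, delivered 500 traces, discarded 54 zero-mature complexes (fraction 0.0975)

$ bleachcount detect --traces sim/traces.csv --out steps.tsv
INFO tally n1=239 n2=243 n3=18; rejections: none

$ bleachcount infer --steps steps.tsv --r 0.7 --seed 1 --out posterior.json
INFO mean q = [0.0857 0.8061 0.1082], sd = [0.0391 0.0481 0.0246]
```

The raw tally looks like a near 50/50 monomer/dimer mixture (239 vs 243
traces) because immature GFPs make dimers masquerade as monomers; the
corrected posterior recovers the true ~10/80/10 composition, with posterior
standard deviations quantifying the remaining uncertainty. The same
pipeline is available from Python (`simulate_traces`, `detect_steps`,
`bin_steps`, `gibbs_sample`), and `bleachcount report` runs it end to end
and draws the raw-vs-corrected summary figure.

Checking the single-occupancy assumption at a measured membrane density:

```
$ bleachcount cocapture --density 253 --diameter 25
lambda=0.124191 p_cocapture=0.0608106
```

i.e. a 25 nm disc at 253 molecules/µm² holds 0.124 molecules on average,
and ~6% of occupied discs would hold a chance pair.

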