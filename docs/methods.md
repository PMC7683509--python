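# Methods

## Problem and model

Post-translational modifications (PTMs) — phosphorylation, ubiquitination,
acetylation and the like — are read and written by enzymes that recognise
short linear motifs around the modified residue. A missense mutation inside
such a motif can abolish or rewire the modification even when it does not
touch the modified residue itself. The package asks, protein by protein,
whether a cohort's missense mutations are enriched in these motif
neighbourhoods relative to the rest of the protein.

**Region construction.** For one protein and one PTM type, every site at
position p contributes the closed interval [p − w, p + w] clipped to
[1, n], with half-width w = 7 by default (an interior site therefore spans
15 residues: the centre plus seven on each side). Same-type intervals are
merged by union into the *modification region* (k positions); the remaining
n − k positions are the *background*. Different PTM types are never merged:
each (protein, PTM type) pair is an independent test unit, and a run covers
one PTM type. The half-width is configurable (`--window`); 7 follows the
motif-radius convention of earlier hotspot methods for PTM-proximal
mutation analysis.

**Counting.** Only missense substitutions are counted. Synonymous changes
do not alter the protein; stop-gain and stop-loss truncate or extend it,
which is a different mutational mechanism from motif disruption, so both
are excluded. Counts are cohort totals per residue position: a position
mutated in m samples contributes m, so recurrent hotspots accumulate
weight. Distinct amino-acid changes at one position all increment that
position.

**Inference.** Per-position counts are modelled as
Y_i ~ Poisson(λ₁) in the modification region and Y_i ~ Poisson(λ₂) in the
background, with independent Gamma priors on each rate. We use the
shape–rate parametrization Gamma(α, β) with mean α/β; a shape–scale prior
converts as rate = 1/scale. Conjugacy gives the posterior
Gamma(α + ΣY, β + #positions) for each region. The target of inference is
the relative rate R = λ₁/λ₂ with hypotheses H₀: R ≤ 1 against H₁: R > 1;
the reported p-value is the posterior probability of the null,

  P(λ₁ ≤ λ₂ | Y) = I_x(a₁, a₂),  x = b₁ / (b₁ + b₂),

where (a₁, b₁), (a₂, b₂) are the two posterior shape/rate pairs and I is
the regularized incomplete beta function. This follows from
B = λ₁b₁/(λ₁b₁ + λ₂b₂·(b₁/b₂)) reducing to a Beta(a₁, a₂) variable
evaluated at b₁/(b₁+b₂).

Because both posteriors are available in closed form, Monte Carlo inference
is implemented as *iid* sampling from the two Gamma posteriors rather than
a dependent chain: it is exact up to sampling noise and needs no burn-in.
The `iterations` and `burn_in` controls are still honoured (burn-in draws
are discarded) so that run configurations carry over unchanged from tools
that expose those knobs. The analytic incomplete-beta path is the default;
the sampler serves as a cross-check and supplies the posterior mean of R,
computed as the mean of draw-wise ratios λ₁/λ₂ (a posterior mean of the
ratio, deliberately not the ratio of posterior means; the choice of mean
over mode is ours and is labelled `R_mean` in outputs).

**Multiple testing.** All p-values of one run (one cohort × one PTM type)
form a single Benjamini–Hochberg family. Drivers are called by strict
q < threshold (default 0.05). Result ordering ties are broken by
(q, p, accession) so output files are deterministic.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 7 residues | motif half-width around each site |
| `prior_shape`, `prior_rate` | 0.001, 0.001 | Gamma hyperparameters, both regions |
| `iterations` | 10 000 draws | Monte Carlo sample size |
| `burn_in` | 1 000 draws | discarded draws (interface fidelity only) |
| `q_threshold` | 0.05 | BH driver-calling cutoff |
| `seed` | 0 | base seed; per-protein seeds derive from it |

The (0.001, 0.001) prior has mean 1 and variance 1000: weakly informative,
washed out by a handful of counts (with ≥ 100 total counts, p-values under
this prior and under Gamma(1, 1) agree within 0.01, which the tests check).
No hyperprior is fitted; the hierarchy is a fixed-hyperparameter two-level
Poisson–Gamma.

## Degenerate inputs and numerical notes

- Proteins whose motif regions swallow the whole sequence (k = n) or that
  have no catalogued sites of the requested PTM type are *excluded* and
  listed in `skipped_proteins.tsv` with a reason — they are not assigned
  p = 1, which would distort the BH family.
- When the background region has (near-)zero counts under the weak prior,
  the draw-wise ratio mean is heavy-tailed and `R_mean` can be very large
  or infinite; the p-value, which depends only on the incomplete beta, is
  unaffected.
- Mutations on accessions missing from the proteome, at positions beyond
  the protein length, or with unparsable annotations are dropped and
  tallied in the manifest; the identity
  input = retained + dropped-by-consequence + dropped-unmapped holds.
- Equidistant nearest-site ties in annotation resolve to the lower
  position. Duplicate catalog rows collapse; duplicate proteome accessions
  keep the first occurrence with a warning.
- A `--genome-assembly` flag is accepted for provenance and recorded in the
  manifest only; coordinate conversion happens upstream of this tool.

## Synthetic cohorts

`ptmburden.simulate` draws cohorts from the generative model itself:
protein lengths fixed (default 400) or uniform in a range, a few sites per
protein (default 3) placed uniformly, per-position counts Poisson(λ₂) in
background and Poisson(R·λ₂) in modification regions, with λ₂ = 0.1
expected cohort-summed mutations per position, R = 5 for a 10% driver
fraction, and a 100-sample cohort by default. Counts are expanded into
per-sample mutation rows with uniform sample attribution and uniform
random amino-acid letters (the inference ignores both, so these choices
only make the files realistic). Output is byte-identical for a fixed seed.

What this *does* show: correctness of the counting, inference and FDR
machinery under the model's own assumptions — null calibration (observed
type-I error ≈ 0.02–0.04 at nominal 0.05 across seeds; the posterior-
probability p-value is mildly conservative), power (≈ 1.0 at five-fold
enrichment with ~22 expected region mutations per driver) and realized FDR
(≤ 0.10).

What it does *not* show: robustness to features of real tumour cohorts the
model ignores — mutational signatures and trinucleotide context, per-sample
burden differences, gene-level covariates of background mutability, codon
structure, or errors in upstream genomic-to-protein mapping. Passing tests
here certify the engine, not those upstream effects.

Default problem sizes (500 proteins for calibration/power runs, 10⁵ draws
for estimator comparisons) keep the full suite and the acceptance script
in the seconds-to-a-minute range while leaving binomial standard errors
small enough for the stated bounds.

## Design choices

- **Exact vs sampled p-values.** The analytic path is the default because
  it is deterministic and exact; the sampler exists for interface fidelity
  and as an internal cross-check (the two must agree within Monte Carlo
  error, which both the unit tests and the acceptance script verify over
  randomized posterior grids).
- **Cohort-summed counts.** Counting m recurrent samples as m (not 1)
  matches a per-position count model and lets recurrent hotspots drive
  enrichment; binarizing would discard exactly the signal of interest.
- **One BH family per run.** Correction is applied within one cohort × one
  PTM type. Pooling across PTM types would mix test units of very
  different region sizes; users running several types should treat each
  run's q-values separately.
- **Predictor tally.** The 0–7 pathogenicity score counts deleterious
  verdicts among seven predictors (SIFT, LRT, MutationTaster,
  MutationAssessor, FATHMM, MetaSVM, MetaLR) supplied as a pre-computed
  table; missing calls count as non-deleterious, so absence of evidence
  never raises a score.

## Limitations

- The background model is a single uniform rate per protein; regional
  mutability covariates (replication timing, expression, chromatin) are
  not modelled and can inflate enrichment for proteins whose motif regions
  coincide with locally mutable sequence.
- Sites whose annotated residue disagrees with the supplied FASTA are kept
  (with a warning); the package does not re-curate catalogs or map
  isoforms.
- VCF support is a minimal pre-annotated dialect (pipe-delimited protein
  consequence per ALT in a configurable INFO key, default `PTM_ANN`); it
  does not parse general VEP/ANNOVAR annotation strings.
- The one-sided posterior probability is not a frequentist p-value; its
  null calibration is demonstrated empirically (conservative at the
  simulated settings) rather than guaranteed.
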