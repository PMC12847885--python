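# Methods

## Scope and model

`ribostress` quantifies *selectivity* under ribosomal stress: whether the
features most perturbed in a differential experiment (smallest p-values,
largest fold changes) differ systematically in transcript architecture or
amino-acid composition from the least perturbed ones.  It is a rank-based
association analysis, not a mechanistic model: all inference is carried
by two-sample and k-sample rank tests on feature distributions across
significance-defined groups.  The package presents this as a
model/results pair (`RibosomalStressModel.fit() -> StressResults`) so
that the configuration, the fitted comparisons and the serialised report
stay attached to each other.

## Inputs and joins

The DE table is tab-separated with mappable columns for feature id,
log2 fold change and p-value.  P-values outside [0, 1] are hard errors;
rows with unparsable numerics are dropped and counted in the load
summary.  Annotation is GTF or GFF3 (attribute dialect auto-detected per
line); coordinates are converted once, at the I/O boundary, from 1-based
inclusive to internal 0-based half-open intervals.  Transcript-level DE
ids join the annotation directly; if no id matches at transcript level,
the join falls back to gene level through a representative transcript
per gene — the one with the longest total CDS, ties broken
lexicographically — because DE tables in the wild are gene-level as
often as transcript-level.  Join failures are counted and reported,
never silently dropped mid-analysis.

## Architecture features

For each transcript: `exon_len` is the **sum** of exon widths (mature
transcript length; the mean exon width is carried as a secondary
column).  When explicit UTR features exist they are summed directly;
otherwise, with a CDS present, the 5′UTR is the exonic sequence strictly
upstream of the CDS start *in transcript orientation* (strand-aware) and
the 3′UTR strictly downstream of the CDS end, which yields the exact
integer identity `utr5 + cds + utr3 = exon_len`.  Transcripts without
CDS or UTR annotation have missing UTR lengths: they are excluded from
UTR comparisons (counted) but retained for exon length.

## Composition features

Residue counts and fractions are taken over the 20 standard one-letter
codes.  The strict alphabet policy (default) rejects anything else
(B, J, O, U, X, Z, `*`); the permissive policy drops such residues from
both counts and weight so the fraction denominator stays unambiguous.
Molecular weight uses Expasy **average** residue masses (4-decimal
constants in one table in `features.py`) plus one water, 18.01528 Da —
the intact-mass convention of label-free proteomics.  Selenocysteine and
pyrrolysine are unsupported.

## Partitioning and testing

* Ranking is by (p-value, feature id); the id tie-break makes every run
  reproducible, and p = 0 (common DE-software underflow) sorts first.
  Significance is strict: p = α goes to the non-significant stratum.
* k aliquots of a ranked set of size N have sizes
  `ceil` for the first `N mod k` groups and `floor` after, so the
  smallest-p groups take the remainder and sizes differ by at most one
  (9,045 → five groups of 905, five of 904).
* Quantile slices use round-half-away-from-zero of `frac × N` with a
  floor of one (478 × 0.25 = 119.5 → 120; 478 × 0.025 = 11.95 → 12).
  This rounding rule is the only one consistent with both printed sizes.
* Two-group comparisons default to the two-sided Mann–Whitney U test:
  exact null when `min(n) ≤ 8` with no ties, tie-corrected normal
  approximation otherwise; fully tied pooled samples short-circuit to
  p = 1, direction `none`.  Welch's t is a configuration option for a
  parametric reading.  Directions come from group medians.
* The 20 residue-fraction tests form one BH family; both raw and
  adjusted p-values are reported.  The headline Ile/Val slice calls are
  made on raw p-values (each is a single pre-specified contrast), with
  the BH column available to flag discrepancies.
* A decile **trend call** requires *both* the global Kruskal–Wallis test
  across all aliquots and the aliquot-1 vs aliquot-k contrast to fall
  below α.  A single 5 %-level contrast alone would fire too often on
  null features; requiring the global test as well brings the false-call
  rate to ~1–2 % while barely costing power at realistic effect sizes.

## Synthetic generator

The generator emulates the *statistical structure* the analysis
consumes, not real genomes: feature–significance associations with known
ground truth.

* Sizes: 9,045 significant + 9,045 non-significant transcripts
  (`n_transcripts` is the significant-stratum size; `frac_significant`
  sets its share) and 924 proteins split 478/446 — the group sizes the
  decile/slice arithmetic is designed around.
* Lengths are log-normal (positive, right-skewed, like real annotation):
  CDS median 1,750 nt (σ = 0.6), 5′UTR median 150 nt, 3′UTR median
  600 nt (σ = 0.8), giving a mature-length median near 2.5 kb.  The
  mature length is composed as `utr5 + cds + utr3` with the planted
  gradient applied to the CDS portion.  This composition is deliberate:
  drawing the total first and resampling UTRs to fit truncates UTR draws
  conditional on the rank-dependent total and leaks a spurious UTR–rank
  association, which would corrupt the generator's own null.  The
  consequence is that `exon_effect` (default 0.5 on the natural-log
  scale, i.e. the lowest-p transcript's CDS is ~65 % longer in
  expectation than the last significant one) applies exactly to the CDS
  and slightly diluted to the total.
* The exon effect is a rank-linear gradient, not a two-group shift, so
  the decile readout is a genuine recovery problem.  P-values are drawn
  directly (U(0, α) and U(α, 1)); upstream count modelling is out of
  scope because the pipeline consumes DE tables.
* Exon totals are realised as 1–12 exons via a uniform Dirichlet split
  (minimum width 1 nt, exact sum), introns 200–5,000 nt; the CDS is
  placed to leave exactly the drawn UTRs, strand-aware, so the geometry
  is valid by construction.
* Proteins: lengths log-normal (median 380 aa, σ = 0.55), significant
  proteins ×1.3 (the size effect); residues are sampled i.i.d. from a
  vertebrate-like background frequency vector; the top-25 %-|log2FC|
  significant subset samples from the background with the Ile
  probability reduced by `ile_effect` (default 0.010) and Val raised by
  `val_effect` (default 0.010), renormalised.  Real effect sizes are
  unknown (the source figures are distributions, not tables), so these
  defaults are documented as choices: they are small in absolute terms
  (one percentage point of composition) yet detectable at n = 120/group.
* Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives
  everything; identical config + seed gives byte-identical files.

What the generator does **not** emulate: splice-isoform sharing between
genes, codon/GC structure, homology between proteins, realistic p-value
shapes under dependence, or any mouse-genome mimicry.  Passing recovery
tests therefore show the *pipeline* is correct and calibrated, not that
any particular biological dataset will show these effects.

## Numerical and design choices

* Deterministic tie-breaks everywhere (feature id); no randomness in the
  analysis path at all — the seed is echoed into reports for provenance
  and drives only the generator.
* Not-computable comparisons (a group below two values) are marked in
  the report with a note instead of crashing the run.
* Reports are written to a temporary directory and atomically renamed,
  so a failed run leaves no partial report.
* Exit codes: 0 ok, 1 usage/config error, 2 input-validation error,
  3 internal error.
* Config precedence: command-line flags > YAML config file > defaults;
  unknown config keys are errors, because a silently ignored typo in
  `alpha` would invalidate a reproduction.

## Problem sizes used by the test suite

The acceptance-style checks run the generator at its default sizes
(18,090 transcripts, 924 proteins): 100 replicates for planted-effect
recovery and 100 for pipeline null calibration, plus 2,000 two-group
null replicates for test-level calibration.  The monotone-sensitivity
property uses a scaled-down problem (500 significant transcripts,
200 replicates per effect-grid point) — the package's choice of a
problem size at which the check is still a sharp test of monotonicity.
`scripts/acceptance.py` uses 50 replicates per rate for the same
reason.

## Known limitations

* The UTR analysis depends on CDS/UTR annotation quality; transcripts
  with CDS but biologically absent UTR annotation contribute zero-length
  UTRs only if the annotation says so.
* Gene-level joins collapse isoforms to one representative transcript;
  architecture conclusions at gene level inherit that choice.
* The exact Mann–Whitney path is disabled in the presence of ties (it
  falls back to the tie-corrected approximation), so tiny tied samples
  get approximate p-values.
* Amino-acid fractions are compositional; the per-fraction tests ignore
  the induced negative correlations between residues (as does the
  headline analysis this package implements).
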