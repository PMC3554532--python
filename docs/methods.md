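# Methods

## The question

MHC class I restricted T-cell epitopes are not found uniformly along their
source antigens: peptides from the two ends of viral proteins test positive
less often than peptides from the core. Two families of explanation exist.
Translation-defect mechanisms (premature termination, downstream
initiation) would skew the sampled regions of proteins directly; a
conservation-mediated mechanism would produce the same curve indirectly,
because protein termini are less evolutionarily conserved than cores and
conserved peptides are recognized more often. This package implements the
statistical machinery to measure the positional bias, to rule residue
composition in or out via predicted MHC binders, and to compute the bias
curve expected from conservation alone so the two explanations can be
compared — together with a synthetic-data module that generates inputs
with known ground truth for every one of those claims.

## Normalized position

A peptide placed at 1-based start `s` in a protein of length `L`, with
peptide length `k`, gets the normalized position

    x = (s - 1) / (L - k)

so `x = 0` exactly when the peptide contains the protein's first residue
and `x = 1` exactly when it contains the last. Uniformly placed peptides
give `x ~ U(0, 1)` regardless of protein length, which is what makes
positions poolable across proteins. `L = k` leaves `x` undefined
(denominator zero); such placements are excluded with an audit reason
rather than assigned an arbitrary midpoint. Because start positions live
on the integer lattice `{1, ..., L-k+1}`, the distribution of `x` is a
mixture of lattices with spacing `1/(L-k)`; the endpoints 0 and 1 are
always attainable, so arbitrarily fine equal-width binning shows an O(1/L)
edge excess. This is a property of the formula, not an artifact: flatness
checks therefore use the Kolmogorov–Smirnov statistic (insensitive to
O(1/L) lattice effects at the sample sizes used) and the 5-bin analyses,
where the effect is far below sampling noise.

## Peptide mapping

A peptide enters the analysis iff it occurs as an exact substring at
exactly one (antigen, start) site across the whole proteome. Zero hits,
two or more hits (ties carry placement uncertainty), degenerate lengths
and malformed records are excluded and counted in an audit whose
categories always sum to the input count. `X` residues never match.
Matching is case-insensitive (sequences are upper-cased on read).
Implementation: a hash index of every proteome window of each needed
length, giving O(total residues + peptides) mapping.

## The bias curve

Normalized positions of positive and negative peptides are binned into 5
equal intervals of [0, 1] (half-open, last bin closed; configurable), and
the per-bin ratio p(x|positive)/p(x|negative) is the bias statistic. A
flat curve at 1 means no positional bias; dividing by the negatives'
distribution absorbs study biases that affect where peptides get tested
at all. Uncertainty: positives and negatives are resampled independently
with replacement at the peptide level, 1000 times by default. Because the
ratio depends on the data only through bin counts, the resampling is
implemented as multinomial draws over the empirical bin masses —
distributionally identical and much faster. Summaries per bin: 25th/75th
percentile box and whiskers extending 1.0 interquartile range beyond the
box, clipped to the most extreme resample inside that range. Resamples
with zero negative mass in a bin make that resample's ratio non-finite;
they are excluded from the summaries and counted, rather than patched
with pseudocounts, keeping the statistic a plain ratio. Bins whose
full-data negative mass is zero are flagged undefined, never dropped.

When a *joint* claim "the curve is flat in all m bins" is asserted (in
tests and in the acceptance summary), per-bin intervals are taken as
ratio ± z·sd(bootstrap) with the level Bonferroni-divided across the m
simultaneous bins. Raw per-bin 25–75+IQR whisker checks have ~4% per-bin
false-alarm rate, so 60 simultaneous checks would reject a truly flat
family ~90% of the time; the family-wise adjustment makes "flat in all
bins" a meaningful statement with ~5% family error.

## Per-bin exact binomial tests

Each bin's positive count k out of n is tested against the table-wide
expected fraction (all positives / all tested; the published census gives
2394/12974 ≈ 0.1845). The two-sided p-value follows the min-likelihood
convention: the sum of probabilities of all outcomes whose point
probability does not exceed that of the observed count (with a 1e-12
relative cushion for floating-point ties). This convention is stated
explicitly because two-sided exact tests differ between implementations;
it matches `scipy.stats.binomtest` and is verified in the tests against an
exact-rational enumeration oracle. No multiple-testing correction is
applied to the reported per-bin p-values, matching the reference analysis.

Calibration note: when the expected fraction is *estimated from the same
table* (the practical procedure), the per-bin tests are conservative —
measured null rejection ≈ 2% at α = 0.05 — because each bin's count is
positively correlated with the pooled estimate. The type-I calibration
check therefore specifies the null fraction (the generator's true
positive rate), under which the measured rate is ≈ 4–5%.

## Predicted-binder bias

All 9-mer windows of the proteome are scored per allele by an external
prediction table; windows with IC50 < 500 nM are binders, > 500 nM
non-binders, and exactly 500 nM is assigned non-binder (the strict
inequalities leave the boundary unassigned; the conservative choice makes
fewer binders). Alleles are grouped into the 12 functional HLA supertypes
and each supertype's binder vs. non-binder ratio curve is computed with
the same machinery as the epitope curve, counting each window once per
(allele, window) prediction. A combined curve is a weighted arithmetic
mean of the supertype point ratios; restriction-frequency weights are a
user-supplied table and default to equal weights with a logged notice.
Supertypes with zero binders or zero non-binders are flagged, not emitted.

## Conservation

Per-residue conservation scores (higher = more conserved; rate-convention
inputs can be sign-flipped at ingestion) are z-scored within each protein
(sample sd; constant or single-residue profiles are excluded with an
audit reason), making every downstream quantity invariant to affine
rescaling of the raw scores. Residue i of a protein of length L sits at
normalized position (i-1)/(L-1) — the position formula with k = 1. Mean
conservation per position bin is bootstrapped over *proteins* (1000
resamples), since residues within a protein are not exchangeable; with a
single protein the bootstrap degenerates to the point estimate and is
flagged.

A peptide's conservation is the arithmetic mean of its footprint's
normalized scores (mean chosen over median/min for linear propagation;
the aggregation is configurable at the call site). The
conservation-to-recognition relationship is the ratio of positive to
negative probability masses over 5 quantile bins of the pooled scores
(~20% of data each; collapsed edges from duplicate-heavy data are merged
and flagged), with bin midpoints at the pooled within-bin medians and the
same two-sample bootstrap as the position curve.

The conservation-only estimate of the bias curve composes the two:
evaluate the ratio function at each position bin's mean conservation,
piecewise-linearly interpolated over the function's midpoints and clamped
to the terminal ratios outside its range (a step-function alternative was
considered and rejected: the composition is evaluated at exactly 5 points,
where interpolation error dominates). Its uncertainty is propagated by
evaluating the point ratio function on every protein-level bootstrap
replicate of the bin means; the ratio function's own sampling noise is
deliberately not mixed in, so the interval reflects the positional input
only. Agreement between observed and estimated curves is the Pearson
correlation of defined-bin point ratios (requiring ≥ 3 common defined
bins and non-constant curves), plus per-bin whisker-interval overlap.

Whether positives are more conserved than negatives is tested with
Welch's unequal-variance t-test, one-sided for mean(pos) > mean(neg),
with the Welch–Satterthwaite degrees of freedom; the degenerate
zero-variance/equal-means case returns p = 0.5, flagged. The same test on
the peptide-immunization slice of the records asks whether recognition is
*intrinsically* coupled to conservation or only through infection-context
exposure history.

## Synthetic data: what it emulates, and what it does not

The generator produces proteomes of uniform-random sequences over the 20
canonical residues (lengths uniform in a configurable range, default
200–800), assay-labelled peptides, conservation fields and toy binding
predictions. All draws come from per-operation streams spawned from one
scenario seed; every generator is a pure function of (inputs, seed).

* **Placement.** Negatives are placed uniformly over windows; positives
  follow a configurable density over x — uniform, central with truncated
  quadratic weight w(x) = 1 + s(1 − 4(x − ½)²), or linear N-/C-terminal
  weights — all with closed-form bin masses, so the expected ratio curve
  of any scenario is known analytically (`expected_ratio_curve`).
* **Conservation.** Raw scores are a parabolic positional trend
  (centre-minus-termini amplitude in noise-sd units) plus unit Gaussian
  noise per residue.
* **Coupling.** When the conservation-recognition coupling is on, peptide
  positions are drawn first and the positive-label probability is
  logistic in the peptide's mean raw conservation, with the intercept
  calibrated by root-finding so the marginal positive fraction is
  preserved. This label-side mechanism makes the density ratio
  p(score|pos)/p(score|neg) exactly exponential in the score, so the
  curve composition above is self-consistent: the conservation-derived
  curve and the observed curve estimate the same object, which is what
  the recovery check requires. (An additive mechanism — boosting the
  conservation field under positive footprints — was considered and
  rejected: it breaks that consistency, since uniform placement would
  leave the observed curve flat while the composed curve inherits the
  positional trend.) Coupling applies only to organism-immunogen
  (infection-context) records; the peptide-immunization fraction of
  records never couples.
* **Toy predictor.** Each pseudo-allele gets a fixed random
  position-specific scoring matrix over k-mer residues; scores are
  squashed through a logistic onto an IC50 scale in (1, 50000) nM with an
  offset placing ~4–5% of calls under 500 nM. Scores depend only on
  residue content, never on window position, so binder curves over these
  proteomes are flat by construction — a null instrument for the
  composition analysis.

Named scenarios fix the study conditions: `null` (uniform, no structure;
10,000 peptides, 20% positive), `central` (placement bias s = 1.5),
`recovery` (uniform placement, trend 1.0, coupling 2.0, 20,000 peptides,
20% peptide-immunization records), and `dissociation` (placement bias
s = 1.5 with a flat, uncoupled conservation field). The recovery scenario
uses a deliberately strong coupling so the recovered structure sits well
above bootstrap noise at a sample size that runs in seconds; calibration
claims use the null scenario. The dissociation control uses a flat
conservation field because a trending field with centrally placed
positives confounds the estimator by construction (positives sit in
conserved cores even without any coupling) — a limitation the
composition method inherently shares with the reference analysis, worth
remembering when reading real-data results.

What the generator does **not** emulate: real viral residue composition
and codon statistics, real HLA binding motifs, homology between curated
and reference antigens (mapping here is against a single reference
proteome, so the reference analysis's homology filter is subsumed and
recorded as n/a in the audit), and missing conservation profiles (real
pipelines assign scores to only ~60% of proteins; the pipeline audits and
tolerates missing profiles, but the generator produces complete fields).
Passing tests on synthetic data therefore validate the statistical
machinery and its calibration, not any claim about real epitope data.

## Numerical conventions and degenerate inputs

* Bins are half-open with the last closed at the right edge, everywhere.
* Bootstrap resample count defaults to 1000; bin count to 5; both
  configurable (10-bin curves behave similarly, as in the reference
  analysis).
* Ratios 0/0 or k/0 at the full-data level: bin flagged undefined, kept.
* Quantile bin edges that collapse under duplicate-heavy scores are
  merged and flagged; fewer than 2 surviving bins is an error.
* Empty inputs raise; record-level problems (empty peptide sequence,
  non-positive IC50) are audited, not raised.
* Curve combination re-normalizes weights over the defined subset per
  bin; combined bootstrap fields are weighted means of the inputs'
  summaries and are descriptive, not joint percentiles.
* All analysis outputs embed the full run configuration and a hash of it;
  equal hashes imply byte-identical numeric payloads given equal inputs.

## Problem sizes

Analyses and checks run at 10,000–50,000 peptides over 50-protein
proteomes (~23,000 windows; 24 pseudo-alleles → ~560,000 predictions),
200 replicate datasets for binomial calibration and 1000 for Welch
calibration — sizes at which every bootstrap quantity is stable to well
under its own CI width and the full pipeline completes in seconds on one
core.
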