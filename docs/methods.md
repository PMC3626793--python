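# Methods

## Problem setting

SILAC (stable isotope labeling by amino acids in cell culture) mixes a
"heavy"-labelled and a "light"-labelled cell population and reads out the
relative abundance of each protein as a heavy/light (H/L) intensity ratio.
Here the heavy channel carries trisomy-21 (T21) amniocytes and the light
channel euploid (CN) amniocytes, so a protein's H/L ratio estimates its
T21/CN fold change.  A euploid:euploid mixture (the CN:CN *control pair*)
measures how far ratios stray from 1 through biological and analytical
variability alone; several CN:T21 *experimental pairs* carry the signal.
Selected candidates are then verified on independent samples by selected
reaction monitoring (SRM), a targeted triple-quadrupole assay that
monitors specific precursor→fragment (Q1→Q3) transitions of proteotypic
peptides.

## Protein quantification

Protein-group H/L ratios are the median of razor-peptide log2 ratios,
exponentiated.  The median was chosen over the mean for bounded influence:
one corrupted peptide among five moves the protein ratio by less than the
corruption, which also makes the later peptide-consistency filter
meaningful.  A protein needs at least `min_ratio_count = 3` finite razor
ratios to be quantified at all; otherwise it carries an explicit NaN, never
a placeholder 0 or 1.

Ratios are normalized by a single multiplicative constant chosen so that
the median log ratio over quantified proteins is zero — the standard
correction for unequal channel mixing.  The operation is idempotent and
scale-equivariant; rank order is untouched.  Ratios are reported on the
natural H/L scale, while every internal statistic runs on log2.

## Outlier significance (Significance A and B)

Each log ratio `r` is scored against the asymmetric percentile spread of
the ratio distribution with percentiles `p15.87`, `p50`, `p84.13`:

    z = (r − p50) / (p84.13 − p50)     if r ≥ p50
    z = (p50 − r) / (p50 − p15.87)     otherwise
    p = erfc(z / √2) / 2

On a Gaussian distribution each half-width estimates one standard
deviation, so `p` is the one-sided tail probability of landing at least
that far out on the protein's side of the median.  Because the score is
one-sided and both tails contribute, a symmetric null yields a fraction
of about `2q` of proteins below any threshold `q` (e.g. ~10% at
`p ≤ 0.05`); the unit tests pin this calibration.  Significance B is the
same construction applied within consecutive bins of `bin_size = 300`
proteins ordered by total intensity (the final partial bin is absorbed
into its predecessor), because ratio variance in SILAC data shrinks with
intensity.  The bin size keeps ≥ 10 bins at a few-thousand-protein scale
while leaving percentile estimates stable; anything below 20 records per
bin is refused.

## Candidate cascade

The control-pair variability model is the mean and standard deviation
(ddof = 1) of the control pair's log2 *normalized* ratios — log scale so
that the interval is symmetric and matches the median-of-logs
normalization.  Two derived intervals drive everything:

* `μ ± 2σ` — covers 95.45% of a Gaussian null, so ~4.55% of null
  proteins fall outside; a ratio strictly outside it counts as
  "significant difference".  Boundary points (measure zero) are inliers.
* `μ ± 0.5σ` — "no clear differential expression"; strict inequality.

The cascade, each removal recorded per protein:

1. **Pooling** — union of the experimental pairs' outlier sets; the
   control-pair interval is applied verbatim to every experimental pair
   (not refitted per pair), as noted in the run metadata.
2. **Exclusions** — control-pair outliers ("variable proteins"), reverse
   hits, known contaminants, proteins that never reach significance A or
   B ≤ 0.05 in a pair where they were flagged (thresholds applied per
   pair, since each pair is its own ratio distribution), and
   unknown/predicted annotations.
3. **Razor-consistency** — removed iff two experimental pairs disagree in
   sign *and* the best per-pair ratio count is below `razor_min = 3`
   ("a few" razor peptides codified as the same 3 used for minimum
   quantification; configurable).
4. **High-probability rules** — (a) ≥ 2 razor peptides in every
   quantifying pair, all agreeing in sign with the protein ratio;
   (b) differential expression (2σ-outlier status) with the same sign in
   ≥ 2 experimental pairs; (c) any remaining pair either agrees in
   direction or sits strictly inside `μ ± 0.5σ`.  Direction
   (increased/decreased) comes from the consensus sign, and the reported
   ratio is the geometric mean of the per-pair normalized ratios.

Rule (b) deliberately requires *differential* expression in two pairs
rather than mere sign agreement: with three pairs, some sign always
recurs, so a sign-only rule would admit proteins flagged in a single
pair and destroy the binomial null bound (expected null survivors are
then bounded by the chance of independent ~4.55% flags coinciding in
≥ 2 of 3 pairs).

The published workflow's manual curation of the candidate list is
replaced by these deterministic rules; the run report says so, because
judgment calls cannot be reproduced by code.  No multiple-testing
correction is applied (raw thresholds are the design); a
Benjamini–Hochberg option would be a trivial extension but is off by
default to match the analysis being implemented.

## SRM assay design

Peptide selection per protein, in order: top 5 by +2 survey intensity;
length 7–20; +3/( +2 + +3 ) < 0.3 (a "significant" +3 share is not
defined anywhere, so it is operationalized as a configurable fraction —
0.3 marks a materially split precursor signal); no N-terminal Cys/Met;
externally supplied uniqueness verdict (a BLAST-style homology check is
out of scope — the flag is an input); finally the top 2 survivors.  The
four predicate rules are order-independent; the two rank rules respect
the stated order, and a brute-force oracle over small catalogs asserts
the whole cascade.

Transitions: from a survey of y-ion intensities (typically 8 ions) the 3
most intense are kept; ties prefer the longer fragment for specificity.
Monoisotopic masses come from pyteomics: Q1 = (M + z·H⁺)/z at charge 2,
Q3 = singly protonated y-ion.  SILAC label shifts are +8.0142 Da per
heavy lysine (¹³C₆,¹⁵N₂) and +6.0201 Da per heavy arginine (¹³C₆),
applied to precursor and to any fragment containing the residue.
Collision energy uses the common charge-2 linear rule
CE = 0.034·Q1 + 3.314 V (configurable; only "predicted CE" is specified
by the assay design it follows).  Instrument settings carried in
transition-list headers are comments with no computational content.

## SRM quantification

Within a sample, replicate 1/injection 1 is the reference; every other
(replicate, injection) is aligned by a single additive log2 constant — an
intercept-only linear model fitted with a Huber M-estimator (tuning
constant 1.345, 95% Gaussian efficiency) on reference-minus-replicate
differences over shared transitions (≥ 5 required).  Intercept-only
because the physical model is a multiplicative loading/injection offset;
the slope is fixed at 1.  With pure offsets the estimate equals ordinary
least squares; with gross outliers (failed peak integrations) the
bounded-influence loss keeps the constant within a few hundredths of a
log2 unit where least squares is dragged by ~0.1·shift.

Between samples, the median log2 area of a housekeeping control-peptide
panel is subtracted per sample (median over ten peptides tolerates an
aberrant control).  The packaged panel file is a synthetic stand-in: the
protein set (GAPDH, RPL27A, RPS3, TALDO1, TUBB, TUBB2C, UBB) is as
published, but the peptide sequences are plausible tryptic peptides
chosen here, since the published sequence list lives in a supplement that
is not redistributable.

Protein T21/CN ratios are unweighted means of per-peptide log2 area
differences (a geometric mean of peptide ratios); CVs are
percent-of-mean on the natural area scale (ddof = 1).  The differential
test is Welch's two-sample t-test on transition-centered log2 areas —
centering each transition by its grand mean removes fragment-response
differences so only the group effect and technical noise enter.  The
test's identity is an assumption of this implementation (the underlying
analysis names none); it is labelled as such in the API documentation.
Degenerate inputs (constant groups, < 3 measurements, single-measurement
CVs) yield NaN with a logged warning rather than a fabricated value.

## Synthetic data

The SILAC generator emulates: one CN:CN pair drawn from the null, N
CN:T21 pairs (default 3) in which a fraction (default 10%) of normal
proteins carries a consistent ±1 log2 effect (mean absolute effect
`effect_log2 = 1`, sign symmetric — the published candidate list splits
nearly evenly between directions); protein-level null spread
`bio_sigma = 0.35` log2 units; razor-peptide counts from a
zero-truncated Poisson with mean 6 (the simplest count law exercising
the minimum-3 rule); peptide-level Gaussian log2 noise (σ = 0.2);
contaminant (`CON__`) and reverse (`REV__`) entries at 1% each;
uncharacterized/predicted annotations at 2%; an optional global log2
bias to exercise normalization; and a completely-at-random dropout knob
(default 0 — the quantified fraction of a real experiment depends on a
dropout mechanism no desk analysis can identify, so it is a dial, not a
constant).  One RNG stream per pair is derived from the master seed by
fixed offsets, so adding pairs never changes earlier pairs.

The SRM generator emulates 2 peptides × 3 transitions per target, three
replicates × two injections per sample (each sample measured six times),
per-(replicate, injection) log2 offsets (σ = 0.3) with the reference
fixed at 0, per-sample loading offsets (σ = 0.3), technical noise
(σ = 0.1), and a fixed count of ≥ +4 log2 gross outliers.  Default true
ratios are the nine verification candidates at their discovery-phase
fold changes.

Not emulated, hence not demonstrated by passing tests: spectrum-level
structure (peaks, interference, chromatography), intensity-dependent
missingness, shared-peptide protein-group inference, and the
heterogeneity of primary amniocyte cultures.  Parameter-recovery results
on this generator show the machinery is correct under its stated
assumptions, not that real amniocyte data would yield any particular
candidate count.

## Numerical conventions

Strict inequalities at both interval boundaries; percentiles via numpy
linear interpolation; sample standard deviations with ddof = 1; p-values
clipped into (0, 1]; UTF-8 tables with "." decimals; evidence and
protein tables tab-delimited (MaxQuant-era headers by default,
configurable column maps), SRM and transition tables CSV.  All
randomness flows from one integer seed.

## Problem sizes

Simulation-based tests run at 400–5000 proteins and 5 seeds where
averaging matters; these sizes keep percentile and rate estimates within
the 3-standard-error bands the tests assert while the full suite stays
fast.  The acceptance script uses the same sizes.

## Known limitations

* The exact published candidate-list membership is not reproducible from
  summary data, and no attempt is made; the cascade reproduces the
  *rules*, with the manual-curation step replaced by deterministic ones.
* Uniqueness of proteotypic peptides is consumed, not computed.
* The one-sided significance score means a threshold `q` admits ~`2q` of
  a symmetric null — users comparing against two-sided conventions
  should halve their threshold.
* Protein groups are taken as given; razor assignment is an input flag.
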