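# Methods

This note documents the statistical procedures implemented in `pollenscreen`,
the study conditions encoded in the synthetic-data generator, and the
numerical and design choices made where the problem left them open.

## Experimental design and data model

The pipeline assumes a single-channel expression-array design over eight
tissues with three biological replicates each: five pollen stages (UNM, BCP,
TCP, MPG, GPG) and three sporophytic controls (callus, root, leaf).  Each
measurement carries an intensity (arbitrary fluorescence units, non-negative)
and a detection call P/A/M (present/absent/missing).  M counts as not-present
everywhere; its intensities are retained.  Arrays are made comparable by
global scaling: each column is multiplied so its two-sided 2 %-trimmed mean
equals a target (default 500).  The trimmed mean is linear under scaling, so
the operation preserves within-array ratios and is idempotent.  "Expressed in
a tissue" is operationalized as a P call in ≥ 2 of 3 replicates
(configurable); this rule is a package decision, since presence-counting
conventions vary between laboratories.

## Screens

All screens use per-tissue replicate **medians** (robust against a single
aberrant replicate).  For focal stage median X and reference medians
m₁…m_r (focal stage excluded):

* Z = (X − μ)/SD with μ the mean and SD the **sample** standard deviation
  (n−1) of the reference medians;
* ratio = X / max(m₁…m_r).

The stage screens use all seven other tissues as reference; the
pollen-preferential screen uses the three sporophytic tissues only.  Both of
these choices are configurable (`stage_reference="sporophytic"`,
`ratio_denominator="mean"`), because the reference-set convention is a
genuine ambiguity in this family of screens: a stage can be compared against
"everything else" or against somatic controls only.  The defaults are the
all-others reference for stage screens and max-of-others ratio, the most
stringent reading and the one under which the per-stage enriched sets are
pairwise disjoint (ratio ≥ 2 at one stage forces ratio ≤ ½ at every other).
The downregulated screen keeps the same max-of-others denominator for
symmetry; a min-of-others variant is arguably more natural for downregulation
and is available through the same switch.

Cutoff defaults are ratio ≥ 2.0 with Z ≥ 3.75 (stage-enriched), ratio ≤ 0.5
with Z ≤ −1.7245 (stage-downregulated; −1.7245 is close to the one-sided
t quantile at α = 0.05 on 20 df, though the screens treat it simply as a
configuration constant) and ratio ≥ 2.0 with Z ≥ 3.19 (pollen-preferential).
Screens operate on raw scaled intensities; a log2(x+1) option exists but the
large Z cutoffs are calibrated for the raw scale.  The SD and ratio
denominators are floored at ε = 10⁻⁸ × the global mean intensity; genes whose
reference SD hits the floor are flagged (`sd_floored`) rather than silently
producing unbounded Z.

Constitutive transcripts are those passing the presence rule in all eight
tissues — equivalently the intersection of the eight per-tissue expressed
sets.  Tissue–tissue similarity is summarized by the Pearson correlation of
per-tissue median profiles over all genes; zero-variance profiles yield
missing correlations rather than NaN-contaminated arithmetic.

## Pattern clustering and cluster-number selection

Per-gene 5-stage profiles (stage medians) are standardized row-wise to mean 0
and variance 1 (population convention, denominator n — only the shape is
retained); constant profiles cannot be standardized and are dropped with a
report.  Profiles are clustered by k-means with 20 restarts and a fixed seed.
A self-organizing-map clusterer occupies the same niche historically; k-means
with canonical labels is used here as the documented, deterministic
clusterer, and no SOM mode is provided.  Cluster labels are canonicalized by
the stage at which each centroid peaks (ties broken lexicographically on the
centroid vector), so "c0…c(k−1)" names are reproducible across seeds for
well-separated data.

The number of clusters is selected over k = 3…7 by the Pearson χ² association
(no continuity correction; df = (k−1)(C−1)) between cluster assignment and
functional category: the k with the smallest p wins, ties favouring the
smaller k.  Because strong associations drive p below double-precision
underflow, the selection ranks log-tail probabilities, switching to the
leading terms of the upper-incomplete-gamma asymptotic when `chi2.logsf`
itself underflows; at that magnitude only the ranking across k is
meaningful.  All-zero rows or columns of the contingency table are dropped
with a warning before testing.

## Functional summaries

Group distributions exclude "unknown" and "transposable-element" probes
before forming within-stage percentages; enriched percentages are signed
positive and downregulated negative, so a stage's row sums to ±100 over
classifiable genes.  Term over-representation is the hypergeometric upper
tail — P(X ≥ k) for k of n set genes carrying a term that K of N background
genes carry — with Benjamini–Hochberg adjustment across terms.  The gene →
term map is a plain two-column table; term hierarchy support is limited to
reporting a term's parent chain from a user-supplied child→parent table, and
gene counts are *not* propagated up the hierarchy by default (propagation
changes the null in ways a generic tool should not silently impose).

## qRT-PCR confirmation

Relative expression uses the classic ΔΔCt method with amplification
efficiency fixed at 2: replicate Ct values are averaged arithmetically,
ΔCt = Ct(target) − Ct(reference gene), ΔΔCt subtracts the calibrator sample,
and relative expression is 2^(−ΔΔCt).  Array and qPCR profiles over the same
ordered samples are compared by Pearson r against the exact critical value
r\* = t\*/√(t\*² + n − 2), with t\* the (1 − α/2) t quantile on n − 2 df.
Confirmation is one-sided in direction but uses the two-tailed critical
value — a profile is confirmed only for r > r\* — which is the convention
that yields r\* = 0.707 (α = 0.05) and 0.834 (α = 0.01) at n = 8.  The
profile length n is always an explicit argument, never a constant.

## Cross-species conservation

Homology is directional best-hit: 12-column BLAST tabular records are
filtered at E-value strictly below 10⁻⁵, and each query keeps the subject
with the highest bit-score (ties: lowest E-value, then lexicographic subject
id).  Reciprocal-best-hit filtering is deliberately out of scope.
Conservation summaries count (i) input genes with a surviving hit and
(ii) *distinct* subject genes, and report second-species expression
percentages over the distinct-subject denominator, since many-to-one mappings
otherwise inflate expression fractions.  Transcription-factor family
comparisons compute pollen percentages against the array-covered genome count
of each family (not the whole-genome count) rounded to integers, and classify
families as shared or species-specific by pollen expression.

## Promoter words

Promoters are the `length` (default 2000) bases 5′ of the start codon,
strand-resolved at extraction (reverse complement for − strand genes) and
truncated with a record at sequence edges; BED (0-based half-open) and GFF3
(1-based) coordinates are both supported.  Word counting is an overlapping
sliding window; N in a sequence matches nothing, while IUPAC ambiguity codes
in a query word match their letter sets.  Enrichment is tested at the gene
level: x of n target promoters contain the word, against the word's presence
probability in a background collection, by a binomial upper tail.  Gene-level
presence was chosen over occurrence-level counting because it is robust to
promoter-length truncation and to local repeats; background presence
probabilities optionally carry a +0.5 pseudo-count (default on) so unseen
words keep p₀ > 0.  BH correction is applied within each word length k, since
the number of testable words differs by orders of magnitude across k = 3…8.
Scanning is single-strand by default (promoters are already strand-resolved);
known-element annotation matches enriched words against a user-supplied
name/IUPAC-pattern catalogue.

## The synthetic-data generator

The generator emulates the statistical structure the screens assume, not
hybridization physics.  Defaults, chosen once as realistic microarray-like
conditions:

| parameter | default | rationale |
|---|---|---|
| genes | 5000 | large enough for stable rate estimates, seconds to run |
| baseline | log-normal, meanlog = ln 500, sdlog = 1 | right-skewed positive intensities around the array-scaling target |
| replicate noise | multiplicative log-normal, CV = 0.1 | typical biological-replicate spread on good arrays |
| enrichment / downregulation / preferential fold | 8 | a clear planted effect, ~4× the ratio cutoff |
| class proportions | 2 % per stage enriched, 1 % per stage downregulated, 20 % preferential, 15 % constitutive, 10 % absent, rest background | keeps every class populated at n = 5000 |
| absent class | log-normal meanlog = ln 20, sdlog = 0.5, capped below the call floor | a noise floor clearly separated from the baseline |
| detection calls | P iff intensity > 99th percentile of the absent class | a simple presence rule standing in for detection p-values |
| cluster–category association | 0.8 | strong planted signal for χ² selection |

Pollen-preferential genes carry one of five temporal templates (c0: rising to
GPG; c1: low early, peaking at MPG+GPG; c2: peaking at MPG then falling;
c3: peaking at BCP/TCP; c4: highest in UNM), encoded as fixed 5-vectors
scaled by the preferential fold.  Functional categories are drawn
cluster-conditionally — each template is paired with one of six core groups —
so cluster-number selection has planted signal.  Constitutive baselines are
clipped above 10× the call floor so the planted class actually satisfies the
constitutive rule under noise.

What the generator does **not** emulate: probe-level effects and
cross-hybridization, array spatial artifacts, correlated noise between
tissues, heavy-tailed outlier replicates, and detection-call uncertainty near
the floor.  Passing planted-recovery tests therefore demonstrates that the
statistics are implemented correctly and are sensitive under clean
multiplicative noise — not that real arrays would yield the same sensitivity.

Homolog simulation assigns each gene a conserved counterpart with a
configurable probability, gives conserved hits E-values below the 10⁻⁵ cutoff
(plus weaker decoy and secondary hits to exercise filtering and best-hit
selection), and flags subjects pollen-expressed at a second configurable
rate.  Promoter simulation plants a word at a configurable rate into target
sets over i.i.d. uniform ACGT backgrounds.  All generation is deterministic
given the seed.

## Problem sizes and calibration checks

Planted-recovery checks run at n = 5000 genes (screens, cluster selection)
and n = 10,000 (conservation rates, binomial 3-SD bounds); null calibrations
use 500 χ² replicates (Kolmogorov–Smirnov uniformity), 50,000–100,000
simulated null correlations at n = 8, and a 50-target/300-background word
scan at k = 4.  The word-enrichment calibration tolerance is
|fraction − α| < 0.05 absolute: binomial tests on discrete presence counts
are conservative, so exact attainment of α is not expected.

## Known limitations

* The clusterer is k-means on standardized profiles; elongated or
  non-spherical pattern families may split or merge differently than a SOM
  would.
* The screens' Z cutoffs assume raw-scale intensities; users applying the
  log2 option should recalibrate thresholds.
* Term enrichment treats annotations as flat labels; hierarchy-aware nulls
  are out of scope.
* Promoter extraction trusts the supplied coordinates; it does not validate
  that the interval actually starts at a start codon.
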