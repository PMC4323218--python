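# Methods

## Scope and data model

The pipeline starts from already-harmonized tables: foods paired with
their constituent compounds, bioassay measurements (compound, protein,
endpoint, value, optional pchembl), drugs with role-labeled protein
links, protein annotations (one category per record — drug target,
enzyme, transporter or carrier — plus disease classes at ontology level
3 and a biological system), PPI edges with confidence scores, ortholog
rows, normalized expression matrices and reference rank profiles.
Identifiers are opaque case-sensitive strings; nothing is validated
against live databases, so synthetic fixtures are first-class inputs.

All affinity-like values are normalized to nM on load (the 50 µM potency
cutoff becomes 50,000 nM) so every comparison happens on one scale.
Inhibition stays in percent. A protein that genuinely plays two roles
(e.g. a drug target that is also a metabolic enzyme for other drugs) is
represented as two records, one per category, mirroring how drug
databases keep target and enzyme lists separate; the role-context
argument of the strongest-binder annotation selects between them.

## Bioactivity classification

Positivity is endpoint-specific and strict at every boundary: pchembl
> 6 for K_i/K_d/IC50/EC50 (pchembl is derived as 9 − log10(value_nM)
when the column is absent; a row with neither field is negative),
inhibition > 30 %, potency < 50 µM. Replicates of one (compound,
protein) pair collapse to their positive frequency; the pair is kept iff
frequency > 0.5 (so a 1-of-2 split is discarded). The representative
affinity is the geometric mean of the positive affinity-endpoint values:
affinities span orders of magnitude, so means are taken on the log scale
throughout (category means likewise, macro-averaged over per-protein
geometric means so data-rich proteins do not dominate).

The drug activity range is built from the drugs' own measurements pushed
through the same filter/aggregation path (positive evidence only — an
assumption, since the alternative of using unfiltered drug measurements
is equally defensible). "Active" means representative affinity ≤ the
range maximum, i.e. at least as potent as the weakest drug. The
two-sided reading (also requiring ≥ the range minimum) would reject
phytochemicals that out-bind every drug — exactly the compounds of most
interest — so it is opt-in (`strict_two_sided_range`). Interactions
whose only evidence is inhibition-% or potency have no binding constant;
the range rule is undefined for them and the frequency rule alone
decides, with no representative affinity recorded.

## Chemical space

Fingerprints are 1024-bit Morgan circular fingerprints at radius 2 (the
conventional reading of a 1024-bit circular fingerprint; the radius is
configurable in code). The descriptor matrix is exactly 1029 columns:
1024 bits plus TPSA, SlogP, MW and the Lipinski rule-of-five H-bond
counts (N+O acceptors, NH+OH donors). Structures are recanonicalized
before descriptor computation so identical molecules give bit-identical
rows regardless of input atom order. PCA standardizes every column
(binary fingerprint columns included — the five physicochemical columns
would otherwise dominate) and drops constant columns with a warning.

Exact matching is canonical-structure-key equality computed from the
SMILES, not a lookup of supplied keys, because fixtures carry SMILES.
Similarity requires TC ≥ 0.85 **and** |ΔMW| < 50 g/mol (strict on the
weight window). PPI expansion adds first-degree neighbors with score
strictly above 400, only for targets reached through *exact* structure
matches, and only over human/rat/mouse edges; rodent ids are then
replaced by their human orthologs (one-to-many rows all retained,
unmapped ids dropped and counted).

## Networks

Food–food edge weight is the exact cardinality of the shared
interacting-protein set. Target–target edges (per disease class) require
≥ 3 shared (drug, food) pairs, where a pair counts once per protein no
matter how many phytochemicals mediate it. The "top 5 edges per node"
rule is a display-layer filter: per node the k heaviest edges are
ranked (weight descending, lexical edge tie-break) and an edge survives
when it is in the top k of **either** endpoint; it never feeds back into
any statistic and is idempotent. Node-size semantics are left to the
display: both the bioactive-compound count and the interacting-protein
count are exported per food node.

Overrepresentation of biological systems uses exp = (tpc / tdt) · tpa.
Two significance readouts are reported side by side: a t-test over
per-category observed/expected ratios, done leave-one-out (each
category's ratio against the one-sided t bound of the remaining
categories, so an outlier does not inflate its own threshold), and an
exact per-category binomial test of the observed count in tpa draws at
probability tpc/tdt. The t-flag mirrors the stated analysis of the
study design this reimplements; the binomial is the statistically
conventional alternative.

## Expression arm

Differential expression is a two-group moderated t-test: per-gene pooled
variances s²_g (d = n₁+n₂−2 df) are shrunk toward a scaled
inverse-chi-square prior (d₀, s₀²) fitted by the method of moments on
log s²_g, inverting the trigamma function by Newton iteration; the
moderated t has d₀ + d degrees of freedom (normal reference when d₀ is
infinite, i.e. when the spread of log-variances is at the sampling
floor). Equivalence with the reference empirical-Bayes implementation is
not claimed; calibration is instead verified by simulation (raw type-I
error ≈ 0.05 on null data, planted-signal recovery with controlled
FDR). Zero-variance/zero-difference genes get p = 1 and a warning.
Benjamini–Hochberg q < 0.05 defines significance; significant genes
split into up/down tag lists ordered by p-value, converted to the
reference profile's probe ids (unmapped tags dropped and counted). No
cap is imposed on tag-list length by default; one is available in the
config.

Connectivity scoring follows the two-sided KS enrichment convention of
expression connectivity mapping: per instance, an up-score a/b statistic
over the tag ranks; when up- and down-scores share a sign the instance
scores 0, else s = ks_up − ks_down. Instance scores are max-scaled to
[−1, 1] across all instances of the query (positives by the maximum,
negatives by |minimum|), and a reference set's enrichment score is the
mean of its scaled instances. The permutation p-value resamples tag sets
of the same sizes (default 10,000 draws, seeded) and is two-sided on the
**raw** (pre-scaling) set mean: under per-query max-scaling, any
permuted draw whose instances happen to dominate the query rescales to
±1, which destroys the test's power when a set's instances are few and
mutually correlated — the scaling is a cross-instance display
normalization, not part of the test statistic. Because the
sign-agreement rule gives the null score a point mass at 0, a null query
receives p = 1 with probability ≈ the mass of that atom; the p-value is
calibrated in its rejection region (P(p ≤ α) ≈ α), which is what the
thresholds consume. Non-null percentage = share of a set's instances
with nonzero score whose sign matches the set mean. A connection is
correlated/anticorrelated only when |ES| > 0.75, p < 0.01 and non-null
> 80 % — all strict.

The DE-vs-non-DE comparison restricts to compounds with at least one
target in each group and pools affinities into a two-sample Wilcoxon
rank-sum test (exact enumeration via the Mann–Whitney implementation for
small samples, normal approximation otherwise), alongside a per-compound
geometric-mean summary.

## Synthetic data

The chemistry generator emulates the shapes of the real inputs at desk
scale (defaults: 8 foods, 40 food compounds, 15 proteins, 12 drugs,
3 replicates per planted pair). Drug affinities are log-uniform on
1–300 nM — comfortably inside the pchembl > 6 window; planted in-range
food compounds sit below half the weakest drug affinity and planted
out-of-range compounds 2–3× above it (capped below 1000 nM so the
measurement filter, not the range rule, is never what removes them).
Replicate flips emit values on the failing side of the filter with the
stated probability, so retention follows the binomial closed form.
Structures are built programmatically as alkyl chains with aromatic
heads and polar tails; "twin" pairs are chain homologs, which makes
their radius-2 environments identical (TC = 1 ≥ 0.85, ΔMW = 14 g/mol)
by construction rather than by rejection sampling. Affinity noise is
log-normal, matching the geometric-mean summarization.

The expression generator plants a DE fraction (default 5 % of 1,000
genes) at ±3σ in the treatment group of a 5 vs 5 design and builds
reference rank instances per drug: correlated instances rank the planted
up-genes at the top and down-genes at the bottom (with a small random
pairwise-swap noise), anticorrelated instances invert the profile, null
instances are uniform permutations.

What passing on this synthetic world shows — and does not. The
generators exercise every rule and boundary of the pipeline, but real
bioassay data are messier in ways the plant does not emulate: assay
heterogeneity beyond a log-normal scatter, correlated measurement
errors, chemically diverse scaffolds (the fingerprint space here is
deliberately narrow), incomplete and biased food-composition records,
and expression studies mixing tissues, platforms and designs. Recovery
of the plant therefore validates the implementation of the rules, not
the biological error rate of the method on real databases. Problem
sizes in the test-suite simulations (hundreds to thousands of genes,
tens of compounds, ≤ 10,000 permutations) were chosen as the smallest
that leave comfortable Monte-Carlo margins for the calibration checks.

## Curated case-study fixture

`dfi.fixture` transcribes seven published case-study interactions
(phytochemical, protein, printed affinity, member foods, sharing drugs).
The drugs' own binding values are not printed in the source, so the
fixture assigns synthetic anchor affinities chosen so each case-study
phytochemical falls within the drug range, as the narrative describes.
Two rows sit exactly at or above the 1000 nM ↔ pchembl 6 boundary of
the positivity filter; for these the fixture supplies an explicit
assay-level `pchembl` column value (> 6) alongside the displayed nM
value, as happens in real bioassay records where the standardized
pchembl and the displayed value disagree by rounding. The filter itself
remains strictly `pchembl > 6`.

## Known limitations

- The frequency rule treats all assays as exchangeable; no
  assay-quality weighting or curve refitting.
- Duplicate structures under different compound ids are recorded but not
  merged; the registry keys on compound id.
- The connectivity permutation scheme is a documented local choice; the
  hosted service this mimics does not publish one.
- Disease-ontology mapping, probe-set conversion and expression
  normalization are upstream of the pipeline and enter only as tables.
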