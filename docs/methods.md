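# Methods

## Scope and data model

The package analyses panel-sequencing somatic variant tables from paired
tumor/normal samples. A variant record carries the gene, locus, alleles,
consequence class, paired ref/alt read counts in tumor and normal, and (for
single-base substitutions) the 3-mer reference context. Tumor metadata carry
the cohort group, the predisposing germline MMR variant (gene and whether it
is a point change or a large genomic deletion), immunohistochemistry results
per MMR protein, BAT25/BAT26 microsatellite stability, MLPA probe dosage
ratios and the MLH1 promoter methylation dosage ratio. Positions are 1-based
and fully closed; VCF input is converted on read. The trinucleotide context
is an input column (an upstream annotation) rather than recomputed from a
genome, which keeps the pipeline deterministic and download-free.

## Somatic significance test

For each variant the 2×2 table of ref/alt counts in tumor and normal is
tested for alt-allele enrichment in the tumor: with all margins fixed, the
one-tailed p-value is P(alt count in tumor ≥ observed) under the
hypergeometric null. The implementation is exact — integer binomial
coefficients over a shared denominator, converted to float once — so agreement
with an independent tail-sum oracle holds to machine precision over all tables
with ≤ 60 total reads (exhaustively verified). Variants pass at p < 0.01
(strict inequality) and a non-synonymous consequence (missense, nonsense,
frameshift, in-frame indel, splice site). A two-tailed variant of the test is
available by flag. No additional depth or strand-bias heuristics are applied:
the significance rule is the only filter.

Retained variants are stratified by allele frequency (low < 0.25, high
≥ 0.25, boundary inclusive on the high side) and by effect: truncating
(frameshift, nonsense) vs non-truncating (missense, in-frame indel).
Splice-site changes are non-synonymous but belong to neither effect class and
are reported as their own bucket rather than forced into the dichotomy.

## Burden and MMR classification

Burden is the count of retained non-synonymous mutations divided by the panel
footprint (default 4 Mb for the bundled 578-gene panel); a tumor is
hypermutated when strictly above 10 mutations/Mb, so exactly 10/Mb does not
qualify. MMR deficiency requires an absent MMR protein by IHC and/or
instability at ≥ 1 of BAT25/BAT26; the two-marker mononucleotide panel has no
MSI-low stratum, so any instability counts as MSI-high. When every assay is
missing the status is an error rather than a default.

## Second-hit attribution

For carriers of a germline point variant, LOH is assessed by the allele-ratio
statistic R = (Alt:Ref)_tumor / (Alt:Ref)_normal at informative heterozygous
sites (all four counts must be positive; counts are pooled over sites when
several are informative). The strict and putative bands come from external
interpretive conventions and are configuration with declared defaults: strict
at R ≥ 2.0 or R ≤ 0.5, putative at 1.5 ≤ R < 2.0 or 0.5 < R ≤ 2/3. For
carriers of a germline large deletion, LOH is called when the median MLPA
probe dosage over the deleted region is ≤ 0.75 — the midpoint between the
one-copy (0.5) and two-copy (1.0) expectations. MLH1 promoter
hypermethylation is called at a methylation dosage ratio ≥ 0.25 (boundary
inclusive) and is only evaluated for MLH1 carriers.

Mechanisms are attributed with precedence LOH > somatic point mutation of the
predisposing gene > methylation > none, so a tumor with both LOH and a
somatic point mutation is tallied once under LOH while both appear in the
evidence trail. "Not determined" (ND) is reserved for carriers whose LOH
assay is unavailable and in whom no positive mechanism was found; tallies over
any cohort therefore partition it exactly.

## Mutational signatures

Substitutions are histogrammed over the 96 pyrimidine-centric trinucleotide
channels (purine-reference calls are reverse-complemented; indels contribute
nothing). Exposures are estimated by refitting the normalized catalog t
against a reference matrix S of signatures: non-negative weights w, Σw ≤ 1,
minimizing ‖t − wᵀS‖². The fit is an iterative forward selection / coordinate
refinement: starting from zero, each step moves the single signature weight
that most reduces the squared error, stopping when the L2 reconstruction
error improves by less than `tol` (default 1e-3). Weights below the reporting
cutoff (default 0.06) are then zeroed and the surviving signatures re-fitted
exactly by sum-constrained non-negative least squares (a slack-variable NNLS).
The unexplained fraction 1 − Σw is reported as the residual. Selection runs
with per-weight bounds only — constraining the running sum during selection
creates coordinate-descent local minima in which mass cannot be traded
between signatures — and the simplex bound is enforced by the final NNLS.
No trinucleotide-abundance renormalization is applied by default (an optional
per-channel opportunity vector is accepted), matching refitting directly on
panel counts.

Group-level summaries take the unweighted mean of per-sample weights per
signature; the combined MMR-deficiency score sums the group means of
signatures 6, 20 and 26 (configurable), and signatures with group means below
0.05 are pooled into an "Other" display bucket. Per-sample refits of
panel-sized catalogs (tens of mutations) are dominated by multinomial noise
and the reporting cutoff, so two guard rails are provided: a minimum catalog
size filter for the per-sample averages (off by default; 50 mutations is the
conventional floor for per-sample refitting), and a collective route
(`group_pooled_exposures`) that refits the summed group catalog — far better
conditioned, at the price of weighting tumors by their mutation counts. The
end-to-end recovery checks score the collective route.

The bundled 30-signature reference is a deterministic **synthetic** stand-in
(Dirichlet profiles from a fixed generator) with the structure of the
canonical reference — 30 signatures, 96 channels, rows summing to 1 — not its
content; analyses of real data should supply the canonical matrix via
`read_signature_matrix`.

## Driver genes and statistics

A gene's recurrence is the fraction of tumors carrying ≥ 1 high-VAF (≥ 0.25)
non-synonymous mutation in it, each tumor counted once per gene. "Top mutant"
genes reach a cutoff proportion, default 0.27: the selection rule is quoted
both as "one-third" and as "a minimum of 27%" (3 of 11 tumors), and 0.27
honors the operational definition; the cutoff is configurable and surfaced in
output. Category enrichment uses the standard disjoint 2×2 table
[top∩category, top∖category; non-top∩category, non-top∖category] and the
two-sided Fisher exact test under the point-probability convention (sum over
tables no more likely than the observed one, ties resolved exactly with
integer arithmetic). The published p-values for the 18-gene top set (0.010
and 0.043) were computed from overlapping denominators ("5/18 vs 47/578"); on
the disjoint table this package obtains 0.0110 and 0.0438, reported as
consistency checks rather than forced matches. No multiple-testing correction
is applied, matching the source analysis.

The Mann-Whitney U test is exact by full enumeration of rank splits (midranks
for ties) when n₁ + n₂ ≤ 12 and otherwise uses the tie-corrected normal
approximation with a 0.5 continuity correction. On the per-case table, the
burden comparison between the deficient carrier group and the non-carriers
lands near the reported borderline value (p ≈ 0.05); the exact figure depends
on tie and exactness conventions of the original software.

## Synthetic cohorts

The simulator is the package's study-conditions generator, not a fixture.
Per tumor it draws: a non-synonymous rate, log-uniform between per-Mb bounds
(defaults 1–10/Mb non-hypermutated; 10–700/Mb hypermutated for deficient-like
groups, 10–120/Mb for proficient-like groups, spanning the observed 1–725/Mb
range on a 4 Mb panel); a 96-channel catalog, multinomial under the group's
planted signature mixture, with contexts generated directly from channel
labels (uniform strand presentation) so channel statistics are exact without
a genome; indels (10%) and extra synonymous substitutions (15%) around the
non-synonymous core; binomial tumor read counts at clonal (0.40 ± 0.05) or
subclonal (0.10 ± 0.05, mixing weight 0.25) true VAF at mean depth 100, with
clean normals (contamination 0, configurable). Second hits are planted per
group (defaults 55/36/9% LOH/somatic/none in the deficient-like group,
22/33/45% in the proficient-like group): LOH distorts the tumor allele
fraction to 0.75 at three informative germline heterozygous sites (emitted as
variant rows with normal alt reads, hence excluded by the somatic filter) or
halves MLPA dosage for deletion carriers; somatic point hits add a clonal
non-synonymous mutation in the predisposing gene; methylation draws a dosage
in 0.30–0.60 vs 0–0.08 otherwise. Passenger mutations avoid the predisposing
gene unless the planted mechanism is a somatic point mutation, keeping the
mechanism truth unambiguous. IHC/MSI labels follow the planted MMR state with
IHC sensitivity 1.0 and MSI sensitivity 0.55 — IHC is the more sensitive
assay, and roughly half of deficient tumors are MSI-high — with a configurable
discordance rate for proficient tumors. One pseudorandom stream per tumor is
derived from (seed, tumor index), so cohorts are byte-reproducible.

What the simulator does **not** emulate: FFPE artifacts, mapping and
strand-bias errors, copy-number structure beyond the planted allelic
imbalance, real gene footprints (genes are equal-weight except planted
drivers), germline contamination of normals, and real signature profiles.
Passing recovery checks therefore demonstrate correctness of the inference
chain under the stated generative model, not performance on raw sequencing
data.

## Problem sizes and numerical choices

The verification suite uses: an exhaustive oracle sweep of all paired-count
tables with ≤ 60 total reads; 200 refits of 500-mutation catalogs from random
2–4-signature mixtures (mean absolute exposure error ≤ 0.05; observed ≈
0.003); and a simulated 40-tumor, depth-100 cohort for end-to-end recovery
(MMR status ≥ 99%, second-hit mechanism ≥ 95%, collective group exposures
within ±0.05). Exact tests use integer arithmetic throughout; refit
tolerances are `tol = 1e-3` on the L2 error and cutoff 0.06, both
configurable. Degenerate inputs fail loudly: zero read depth, empty catalogs,
all-missing assays, non-carrier second-hit queries, inconsistent LOH band
configurations and malformed files all raise named errors.

## Known limitations

- Consequence annotation is consumed, not computed; transcript-set choices of
  the upstream caller are invisible here.
- The VarScan somatic caller applies depth/frequency heuristics beyond its
  p-value; only the published p < 0.01 rule is implemented.
- The strict/putative LOH bands reproduce external conventions as defaults
  and may need adjustment for other assays.
- The published top-gene p-values are approached but not exactly reproduced
  because their 2×2 construction was not printed.
- Mean mutation counts are reported as rate × footprint; printed per-sample
  rates are rounded, so grouped counts can differ by ±1 from published counts
  (e.g. 132 vs 131) while the per-Mb means match exactly.
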