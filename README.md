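# somaticmmr

Somatic mutational profiling of tumors from carriers of inherited DNA
mismatch-repair (MMR) defects — the analysis used to ask whether a tumor type
(here, breast carcinoma in Lynch syndrome families) carries the molecular
fingerprint of the predisposing MMR deficiency.

Starting from paired tumor/normal allele counts on a capture panel, the
package implements the full chain:

1. **Somatic filtering** — the one-tailed Fisher exact test on the 2×2
   ref/alt × tumor/normal read-count table; a variant is a somatic mutation
   when *p* < 0.01 and its consequence is non-synonymous. Retained variants
   are stratified by allele frequency (VAF < 0.25 vs ≥ 0.25) and effect
   (truncating vs non-truncating).
2. **Burden & MMR status** — non-synonymous mutations per megabase of panel
   footprint; hypermutated when > 10/Mb. A tumor is MMR-deficient (dMMR) when
   an MMR protein is absent by immunohistochemistry and/or ≥ 1 of the
   mononucleotide markers BAT25/BAT26 is unstable.
3. **Second-hit attribution** — loss of heterozygosity via the allele-ratio
   statistic R = (Alt:Ref)ₜ / (Alt:Ref)ₙ (strict at R ≥ 2 or ≤ 0.5, putative
   at 1.5 ≤ R < 2 or 0.5 < R ≤ 2/3) or MLPA probe dosage for deletion
   carriers; somatic point mutation of the predisposing gene; MLH1 promoter
   hypermethylation (dosage ratio ≥ 0.25); with precedence
   LOH > somatic point > methylation.
4. **Mutational signatures** — 96-channel trinucleotide catalogs refitted
   against a reference signature matrix by non-negative forward selection
   minimizing ‖t − Σᵢ wᵢ sᵢ‖² subject to wᵢ ≥ 0, Σwᵢ ≤ 1, with a 0.06
   reporting cutoff; the combined weight of signatures 6, 20 and 26
   summarizes MMR-deficiency exposure.
5. **Driver enrichment** — per-gene recurrence of high-VAF mutations, the
   "top mutant gene" rule (≥ ~1/3 of tumors), two-sided Fisher exact tests
   for functional-category enrichment, and exact Mann-Whitney U comparisons.
6. **Cohort summary** — the per-group report (means, hypermutated fractions,
   second-hit distributions, signature scores).
7. **Simulator** — a seeded generator of full synthetic cohorts (multinomial
   catalogs from planted exposure mixtures, binomial read counts, planted
   second hits and consistent IHC/MSI labels) with a truth table, so every
   stage is testable end to end.

## Worked example

The packaged per-case table of 30 breast carcinomas (11 dMMR Lynch-syndrome,
9 pMMR Lynch-syndrome, 10 non-carrier) reproduces the published group report:

```python
from somaticmmr import (table1_fixture, synthetic_panel, summarize,
                        second_hit_from_code)
from somaticmmr.burden import BurdenRecord

fx = table1_fixture()
panel = synthetic_panel()
burdens = {sid: BurdenRecord.from_rate(sid, r, panel.footprint_mb)
           for sid, r in fx.mutations_per_mb.items()}
second = {s.sample_id: second_hit_from_code(s.sample_id, fx.second_hit_code[s.sample_id])
          for s in fx.samples if s.is_carrier}
for summary in summarize(fx.samples, burdens, second):
    print(summary.display())
```

prints (abridged):

```
dMMR_LS_BC (n = 11)
  mean non-synonymous mutations: 697 (174/Mb)
  hypermutated (>10/Mb): 10/11 (91%)
  second hit LOH: 6/11 (55%)
  second hit somatic_point: 4/11 (36%)
  second hit none: 1/11 (9%)
pMMR_LS_BC (n = 9)
  mean non-synonymous mutations: 132 (33/Mb)
  hypermutated (>10/Mb): 4/9 (44%)
NC_BC (n = 10)
  mean non-synonymous mutations: 352 (88/Mb)
  hypermutated (>10/Mb): 3/10 (30%)
```

The deficient group averages 174 non-synonymous mutations/Mb — well above the
10/Mb hypermutation threshold in 10 of 11 tumors — with LOH as the dominant
second hit, while the proficient carrier group (33/Mb) resembles the
non-carrier group (88/Mb, inflated by three hypermutated outliers).

The same report can be produced from files via the CLI:

```
somaticmmr simulate --seed 7 --n-per-group 5 --out demo/
somaticmmr summarize --variants demo/variants.tsv --cohort demo/cohort.tsv
```

which runs filtering, burden, second-hit attribution and signature refitting
on the simulated cohort and prints the per-group report, e.g.

```
dMMR_LS_BC (n = 5)
  mean non-synonymous mutations: 429 (107/Mb)
  hypermutated (>10/Mb): 4/5 (80%)
  second hit LOH: 5/5 (100%)
  combined MMR-signature score: 0.571
```

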