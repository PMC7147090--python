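"""Top-mutant-gene selection and functional-category enrichment statistics.

A gene is "top mutant" in a cohort when at least the cutoff proportion of
tumors (default 0.27, i.e. roughly one-third) carry a high-allele-frequency
(VAF >= 0.25) non-synonymous somatic mutation in it — high-frequency mutations
being more likely clonal drivers than subclonal passengers. Enrichment of a
functional category among the top genes is tested with a two-sided Fisher
exact test on the disjoint 2x2 table
[top & category, top & not; non-top & category, non-top & not].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .filtering import HIGH_VAF_THRESHOLD
from .stats import MannWhitneyResult, fisher_exact_two_sided, mann_whitney_u  # noqa: F401
from .types import GeneCategory, GenePanel, SomaticVariant

#: Default top-gene cutoff proportion. The source convention is "about one
#: third"; operationally 3 of 11 tumors (0.27) already qualifies.
DEFAULT_TOP_CUTOFF = 0.27


@dataclass(frozen=True)
class GeneRecurrence:
    gene: str
    n_tumors_high_vaf: int
    proportion: float
    is_top: bool


@dataclass(frozen=True)
class EnrichmentResult:
    category: GeneCategory
    table: tuple[int, int, int, int]  # (a, b, c, d) row-major
    p: float


def gene_recurrence(
    variants: Iterable[SomaticVariant],
    cohort_size: int,
    panel: GenePanel,
    vaf_min: float = HIGH_VAF_THRESHOLD,
    cutoff: float = DEFAULT_TOP_CUTOFF,
) -> list[GeneRecurrence]:
    """Per-gene recurrence of high-VAF non-synonymous mutations across a cohort.

    Each tumor counts at most once per gene. One record is returned for every
    panel gene; variants in off-panel genes trigger a warning and are excluded.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    tumors_by_gene: dict[str, set[str]] = {g: set() for g in panel.genes}
    off_panel: set[str] = set()
    for v in variants:
        if not v.is_nonsynonymous or v.vaf < vaf_min:
            continue
        if v.gene not in tumors_by_gene:
            off_panel.add(v.gene)
            continue
        tumors_by_gene[v.gene].add(v.sample_id)
    if off_panel:
        warnings.warn(
            f"excluded variants in genes absent from panel: {sorted(off_panel)[:10]}",
            stacklevel=2,
        )
    records = []
    for gene in sorted(panel.genes):
        n = len(tumors_by_gene[gene])
        prop = n / cohort_size
        records.append(
            GeneRecurrence(gene=gene, n_tumors_high_vaf=n, proportion=prop, is_top=prop >= cutoff)
        )
    records.sort(key=lambda r: (-r.proportion, r.gene))
    return records


def top_genes(records: Sequence[GeneRecurrence]) -> list[str]:
    return [r.gene for r in records if r.is_top]


def category_enrichment(
    top: Iterable[str],
    panel: GenePanel,
    category: GeneCategory,
) -> EnrichmentResult:
    """Two-sided Fisher exact test for category enrichment among top genes."""
    top_set = set(top)
    if not top_set:
        raise ValueError("empty top-gene set")
    if not top_set <= panel.genes:
        raise ValueError(f"top genes absent from panel: {sorted(top_set - panel.genes)[:5]}")
    cat_genes = panel.genes_in_category(category)
    a = len(top_set & cat_genes)
    b = len(top_set - cat_genes)
    nontop = panel.genes - top_set
    c = len(nontop & cat_genes)
    d = len(nontop - cat_genes)
    p = fisher_exact_two_sided(a, b, c, d)
    return EnrichmentResult(category=GeneCategory(category), table=(a, b, c, d), p=p)
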