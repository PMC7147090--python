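"""Somatic significance testing on paired allele counts and variant stratification.

The significance test is the one-tailed Fisher exact test on the 2x2
ref/alt x tumor/normal read-count table, asking whether the alternate allele is
enriched in the tumor relative to the paired normal. Variants with p below the
significance level (default 0.01) and a non-synonymous consequence are the
"somatic mutations" every downstream stage consumes. Retained variants are
further stratified by allele frequency (low < 0.25 vs high >= 0.25) and effect
(truncating = frameshift/nonsense vs non-truncating = missense/in-frame indel;
splice-site changes are non-synonymous but form their own effect bucket).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .stats import hypergeom_sf_exact
from .types import (
    NON_TRUNCATING_CONSEQUENCES,
    TRUNCATING_CONSEQUENCES,
    Consequence,
    SomaticVariant,
)

#: Default significance level for the somatic test.
DEFAULT_ALPHA = 0.01
#: Allele-frequency boundary between the low and high strata.
HIGH_VAF_THRESHOLD = 0.25


class FrequencyClass(str, enum.Enum):
    low = "low"
    high = "high"


class EffectClass(str, enum.Enum):
    truncating = "truncating"
    non_truncating = "non_truncating"
    splice_site = "splice_site"


@dataclass(frozen=True)
class VariantStrata:
    is_nonsynonymous: bool
    frequency_class: FrequencyClass
    effect_class: Optional[EffectClass]  # None for synonymous/other
    passes_somatic: bool


def somatic_fisher_p(
    t_ref: int,
    t_alt: int,
    n_ref: int,
    n_alt: int,
    tail: str = "one",
) -> float:
    """Exact p-value for alt-allele enrichment in tumor vs paired normal.

    One-tailed (default): P(alt count in tumor >= observed) under the
    hypergeometric null with all four margins fixed. ``tail="two"`` gives the
    two-sided point-probability Fisher p instead.
    """
    for name, x in (("t_ref", t_ref), ("t_alt", t_alt), ("n_ref", n_ref), ("n_alt", n_alt)):
        if x < 0:
            raise ValueError(f"{name} must be non-negative")
    if t_ref + t_alt == 0 or n_ref + n_alt == 0:
        raise ValueError("insufficient depth: zero total reads in tumor or normal")
    N = t_ref + t_alt + n_ref + n_alt
    K = t_alt + n_alt
    n = t_ref + t_alt
    if tail == "one":
        return hypergeom_sf_exact(t_alt, N, K, n)
    if tail == "two":
        from .stats import fisher_exact_two_sided

        return fisher_exact_two_sided(t_alt, t_ref, n_alt, n_ref)
    raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")


def stratify(variant: SomaticVariant, alpha: float = DEFAULT_ALPHA) -> VariantStrata:
    """Assign frequency/effect strata and the somatic-significance flag."""
    p = variant.somatic_p
    if p is None:
        p = somatic_fisher_p(
            variant.tumor_ref_reads,
            variant.tumor_alt_reads,
            variant.normal_ref_reads,
            variant.normal_alt_reads,
        )
    if variant.consequence in TRUNCATING_CONSEQUENCES:
        effect = EffectClass.truncating
    elif variant.consequence in NON_TRUNCATING_CONSEQUENCES:
        effect = EffectClass.non_truncating
    elif variant.consequence == Consequence.splice_site:
        effect = EffectClass.splice_site
    else:
        effect = None
    freq = FrequencyClass.high if variant.vaf >= HIGH_VAF_THRESHOLD else FrequencyClass.low
    return VariantStrata(
        is_nonsynonymous=variant.is_nonsynonymous,
        frequency_class=freq,
        effect_class=effect,
        passes_somatic=p < alpha,
    )


def filter_somatic(
    variants: Iterable[SomaticVariant],
    alpha: float = DEFAULT_ALPHA,
    tail: str = "one",
) -> list[SomaticVariant]:
    """Retain non-synonymous variants with somatic p strictly below ``alpha``.

    Input order is preserved. Variants without a precomputed ``somatic_p`` get
    one; returned records always carry their p-value.
    """
    kept: list[SomaticVariant] = []
    for v in variants:
        p = v.somatic_p
        if p is None:
            p = somatic_fisher_p(
                v.tumor_ref_reads, v.tumor_alt_reads, v.normal_ref_reads, v.normal_alt_reads,
                tail=tail,
            )
            v = replace(v, somatic_p=p)
        if p < alpha and v.is_nonsynonymous:
            kept.append(v)
    return kept
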