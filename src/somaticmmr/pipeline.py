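"""End-to-end orchestration: raw paired-count variants to the per-group report.

``run_pipeline`` wires the stages together the way the study design intends:
somatic filtering on paired allele counts, per-tumor burden and MMR
classification, second-hit attribution for germline carriers (allele-ratio LOH
from germline heterozygous sites for point-variant carriers, MLPA dosage for
deletion carriers, promoter methylation, somatic point mutations), 96-channel
catalogs refitted against the reference signatures, and the group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .burden import BurdenRecord, MmrStatus, burden, classify_mmr
from .filtering import filter_somatic
from .second_hit import (
    DEFAULT_THRESHOLDS,
    LohCall,
    LohThresholds,
    SecondHitCall,
    attribute_second_hit,
    call_loh_mlpa,
    call_loh_point,
    call_methylation,
    loh_ratio,
)
from .signatures import (
    GroupSignatureSummary,
    build_catalog,
    group_pooled_exposures,
    group_signature_summary,
    refit_exposures,
)
from .summary import CohortSummary, summarize
from .types import (
    Consequence,
    ExposureVector,
    GenePanel,
    GermlineKind,
    MutationCatalog,
    SignatureMatrix,
    SomaticVariant,
    TumorSample,
)


@dataclass
class PipelineResult:
    filtered_variants: list[SomaticVariant]
    burdens: dict[str, BurdenRecord]
    mmr_status: dict[str, MmrStatus]
    second_hits: dict[str, SecondHitCall]
    catalogs: dict[str, MutationCatalog]
    exposures: dict[str, ExposureVector]
    group_signatures: dict[str, GroupSignatureSummary]
    #: collective per-group exposures from refitting the pooled group catalog
    group_pooled: dict[str, ExposureVector]
    summaries: list[CohortSummary]


def loh_call_for_sample(
    sample: TumorSample,
    raw_variants: Sequence[SomaticVariant],
    thresholds: LohThresholds = DEFAULT_THRESHOLDS,
    min_normal_vaf: float = 0.2,
) -> Optional[LohCall]:
    """LOH evidence for one carrier, routed by the germline variant type.

    Point-variant carriers: allele counts are pooled over the germline
    heterozygous sites of the predisposing gene (rows whose normal alt
    fraction is at least ``min_normal_vaf``) and the allele-ratio statistic is
    classified against the strict/putative bands. Deletion carriers: MLPA
    probe dosage. Returns ``None`` when the assay is unavailable.
    """
    if not sample.is_carrier:
        return None
    if sample.germline_variant_kind == GermlineKind.large_deletion:
        if sample.mlpa_dosage is None:
            return None
        return call_loh_mlpa(sample.mlpa_dosage, thresholds)
    het_sites = [
        v
        for v in raw_variants
        if v.sample_id == sample.sample_id
        and v.gene == sample.predisposing_gene.value
        and v.normal_alt_reads + v.normal_ref_reads > 0
        and v.normal_alt_reads / (v.normal_alt_reads + v.normal_ref_reads) >= min_normal_vaf
    ]
    if not het_sites:
        return None
    t_alt = sum(v.tumor_alt_reads for v in het_sites)
    t_ref = sum(v.tumor_ref_reads for v in het_sites)
    n_alt = sum(v.normal_alt_reads for v in het_sites)
    n_ref = sum(v.normal_ref_reads for v in het_sites)
    try:
        R = loh_ratio(t_alt, t_ref, n_alt, n_ref)
    except ValueError:
        return None
    return call_loh_point(R, thresholds)


def run_pipeline(
    samples: Sequence[TumorSample],
    raw_variants: Sequence[SomaticVariant],
    panel: GenePanel,
    reference: SignatureMatrix,
    alpha: float = 0.01,
    cutoff: float = 0.06,
    thresholds: LohThresholds = DEFAULT_THRESHOLDS,
) -> PipelineResult:
    filtered = filter_somatic(raw_variants, alpha=alpha)
    burdens = {s.sample_id: burden(filtered, panel, s.sample_id) for s in samples}
    mmr = {s.sample_id: classify_mmr(s) for s in samples}

    second_hits: dict[str, SecondHitCall] = {}
    for s in samples:
        if not s.is_carrier:
            continue
        loh = loh_call_for_sample(s, raw_variants, thresholds)
        methylation = (
            call_methylation(s.methylation_dosage) if s.methylation_dosage is not None else None
        )
        second_hits[s.sample_id] = attribute_second_hit(s, filtered, loh, methylation)

    catalogs = {s.sample_id: build_catalog(filtered, s.sample_id) for s in samples}
    exposures = {
        sid: refit_exposures(cat, reference, cutoff=cutoff)
        for sid, cat in catalogs.items()
        if cat.total > 0
    }
    groups = {s.sample_id: s.group.value for s in samples}
    group_sigs = {
        g.group: g
        for g in group_signature_summary(
            exposures, {k: groups[k] for k in exposures}
        )
    }
    pooled = group_pooled_exposures(
        {k: v for k, v in catalogs.items() if v.total > 0},
        groups,
        reference,
        cutoff=cutoff,
    )
    summaries = summarize(samples, burdens, second_hits, group_sigs)
    return PipelineResult(
        filtered_variants=filtered,
        burdens=burdens,
        mmr_status=mmr,
        second_hits=second_hits,
        catalogs=catalogs,
        exposures=exposures,
        group_signatures=group_sigs,
        group_pooled=pooled,
        summaries=summaries,
    )
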