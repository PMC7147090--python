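"""Seeded cohort simulator with the statistical structure the pipeline assumes.

Each simulated tumor draws a non-synonymous mutation rate (log-uniform within
hypermutated or non-hypermutated per-Mb bounds), a 96-channel substitution
catalog (multinomial under its group's planted signature-exposure mixture),
binomial tumor/normal read counts at clonal (~0.4) or subclonal (~0.1) true
allele fractions at a configurable mean depth, a planted second-hit mechanism
(allelic-imbalance LOH observed through germline heterozygous sites emitted as
variant rows, MLPA probe dosage for large-deletion carriers, a somatic point
mutation of the predisposing gene, promoter methylation for MLH1 carriers, or
none), and IHC/MSI labels consistent with the planted MMR state. A truth table
records everything planted so recovery can be scored.

Passenger mutations never land in the predisposing MMR gene unless the planted
mechanism is a somatic point mutation, keeping the mechanism truth unambiguous.
Trinucleotide contexts are generated directly from channel labels, so channel
statistics are exact without a reference genome. One pseudorandom stream per
tumor is derived from (seed, tumor index), making cohorts reproducible even if
tumors are generated in parallel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS, parse_channel, revcomp
from .datasets import (
    MMR_PROTEINS,
    Table1Fixture,
    synthetic_panel,
    synthetic_reference_signatures,
    table1_fixture,
)
from .second_hit import Mechanism
from .types import (
    Consequence,
    GenePanel,
    GermlineKind,
    Group,
    IhcResult,
    MmrGene,
    MsiResult,
    SignatureMatrix,
    SomaticVariant,
    TumorSample,
)

#: Marker gene value used in truth tables for non-carriers.
_CARRIER_GENES = (MmrGene.MLH1, MmrGene.MSH2, MmrGene.MSH6)


@dataclass
class GroupSpec:
    """Planted characteristics of one simulated cohort group."""

    name: str
    group: Group
    n_tumors: int
    exposures: dict[str, float]
    mmr_deficient: bool = False
    hypermutated_fraction: float = 0.0
    rate_bounds: tuple[float, float] = (0.5, 10.0)          # per Mb, log-uniform
    hyper_rate_bounds: tuple[float, float] = (10.0, 700.0)  # per Mb, log-uniform
    # germline carriers only; probabilities over planted mechanisms
    second_hit_probs: Optional[dict[str, float]] = None
    predisposing_genes: Optional[dict[str, float]] = None   # None -> non-carrier group
    germline_kind_probs: dict[str, float] = field(
        default_factory=lambda: {"point": 0.5, "large_deletion": 0.5}
    )
    msi_sensitivity: float = 0.55   # P(MSI-high | dMMR): IHC is the more sensitive assay
    ihc_sensitivity: float = 1.0    # P(IHC loss | dMMR)
    label_discordance: float = 0.0  # P(spurious abnormal label | pMMR)

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        for name, dist in (
            ("exposures", self.exposures),
            ("second_hit_probs", self.second_hit_probs),
            ("predisposing_genes", self.predisposing_genes),
            ("germline_kind_probs", self.germline_kind_probs),
        ):
            if dist is None:
                continue
            total = sum(dist.values())
            if any(v < 0 for v in dist.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1, got {dist}")
        if not self.exposures or all(v == 0 for v in self.exposures.values()):
            raise ValueError("zero-probability signature mixture")


@dataclass
class SimulationConfig:
    seed: int
    groups: Sequence[GroupSpec]
    signatures: SignatureMatrix = field(default_factory=synthetic_reference_signatures)
    panel: GenePanel = field(default_factory=synthetic_panel)
    depth: float = 100.0
    clonal_vaf: float = 0.4
    subclonal_vaf: float = 0.1
    subclonal_weight: float = 0.25
    vaf_sd: float = 0.05
    indel_fraction: float = 0.10        # frameshift/in-frame indels among non-synonymous
    synonymous_fraction: float = 0.15   # extra synonymous SNVs relative to non-synonymous
    splice_fraction: float = 0.05       # splice-site share among non-synonymous SNVs
    nonsense_fraction: float = 0.12
    driver_genes: tuple[str, ...] = ("TP53", "PIK3CA", "PTEN", "ERBB2", "KMT2C", "KMT2D")
    driver_weight: float = 25.0
    n_loh_sites: int = 3                # informative germline het sites per carrier
    loh_alt_fraction: float = 0.75      # tumor alt fraction under planted LOH
    mlpa_loh_mean: float = 0.5
    mlpa_normal_mean: float = 1.0
    mlpa_sd: float = 0.04


@dataclass
class TruthRecord:
    sample_id: str
    group: str
    exposures: dict[str, float]
    rate_per_mb: float
    n_nonsyn: int
    n_snv: int
    mechanism: str            # planted second hit, "N/A" for non-carriers
    mmr_deficient: bool
    predisposing_gene: str


@dataclass
class SimulatedCohort:
    samples: list[TumorSample]
    variants: list[SomaticVariant]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": t.sample_id,
                    "group": t.group,
                    "rate_per_mb": t.rate_per_mb,
                    "n_nonsyn": t.n_nonsyn,
                    "n_snv": t.n_snv,
                    "mechanism": t.mechanism,
                    "mmr_deficient": t.mmr_deficient,
                    "predisposing_gene": t.predisposing_gene,
                    "exposures": ";".join(f"{k}={v!r}" for k, v in sorted(t.exposures.items())),
                }
                for t in self.truth
            ]
        )

    def write(self, outdir: str) -> None:
        from .io import write_cohort, write_variants

        os.makedirs(outdir, exist_ok=True)
        write_variants(self.variants, os.path.join(outdir, "variants.tsv"))
        write_cohort(self.samples, os.path.join(outdir, "cohort.tsv"))
        self.truth_frame().to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)


def _draw(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _emit_snv(
    rng: np.random.Generator,
    config: SimulationConfig,
    sample_id: str,
    gene: str,
    pos: int,
    channel: str,
    consequence: Consequence,
) -> tuple[SomaticVariant, float]:
    ref, alt, ctx = parse_channel(channel)
    # present half of the substitutions on the purine strand, as real calls are
    if rng.random() < 0.5:
        ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
    subclonal = rng.random() < config.subclonal_weight
    mean_vaf = config.subclonal_vaf if subclonal else config.clonal_vaf
    vaf = float(np.clip(rng.normal(mean_vaf, config.vaf_sd), 0.02, 0.98))
    t_depth = max(8, int(rng.poisson(config.depth)))
    n_depth = max(8, int(rng.poisson(config.depth)))
    t_alt = int(rng.binomial(t_depth, vaf))
    v = SomaticVariant(
        sample_id=sample_id,
        gene=gene,
        chrom="chr1",
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        consequence=consequence,
        tumor_ref_reads=t_depth - t_alt,
        tumor_alt_reads=t_alt,
        normal_ref_reads=n_depth,
        normal_alt_reads=0,
        context3=ctx,
    )
    return v, vaf


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort: variant table, metadata, and truth records."""
    S = config.signatures
    panel_genes = sorted(config.panel.genes)
    gene_weights = np.array(
        [config.driver_weight if g in config.driver_genes else 1.0 for g in panel_genes]
    )
    samples: list[TumorSample] = []
    variants: list[SomaticVariant] = []
    truth: list[TruthRecord] = []
    tumor_index = 0
    for spec in config.groups:
        channel_probs = S.mixture_profile(spec.exposures)
        for k in range(spec.n_tumors):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, tumor_index]))
            sample_id = f"{spec.name}_{k:03d}"
            hyper = rng.random() < spec.hypermutated_fraction
            lo, hi = spec.hyper_rate_bounds if hyper else spec.rate_bounds
            rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            n_nonsyn = max(1, round(rate * config.panel.footprint_mb))

            carrier = spec.predisposing_genes is not None
            gene_sym = MmrGene.none
            kind = GermlineKind.none
            mechanism = "N/A"
            if carrier:
                gene_sym = MmrGene(_draw(rng, spec.predisposing_genes))
                kind = GermlineKind(_draw(rng, spec.germline_kind_probs))
                mechanism = _draw(rng, spec.second_hit_probs or {"none": 1.0})
                if mechanism == "methylation":
                    gene_sym = MmrGene.MLH1  # promoter methylation is only assayed for MLH1

            # gene pool for passengers: avoid the predisposing gene so the
            # planted mechanism stays the only somatic hit to it
            weights = gene_weights.copy()
            if carrier:
                weights[panel_genes.index(gene_sym.value)] = 0.0
            gene_p = weights / weights.sum()

            n_indel = int(rng.binomial(n_nonsyn, config.indel_fraction))
            n_snv = n_nonsyn - n_indel
            n_syn = int(rng.binomial(n_nonsyn, config.synonymous_fraction))
            channel_counts = rng.multinomial(n_snv + n_syn, channel_probs)
            # decide which of the drawn substitutions are the synonymous extras
            snv_channels = np.repeat(np.arange(96), channel_counts)
            rng.shuffle(snv_channels)

            pos = 1
            for i, ch_idx in enumerate(snv_channels):
                if i < n_snv:
                    r = rng.random()
                    if r < config.splice_fraction:
                        cons = Consequence.splice_site
                    elif r < config.splice_fraction + config.nonsense_fraction:
                        cons = Consequence.nonsense
                    else:
                        cons = Consequence.missense
                else:
                    cons = Consequence.synonymous
                gene = panel_genes[rng.choice(len(panel_genes), p=gene_p)]
                v, _ = _emit_snv(rng, config, sample_id, gene, pos, CHANNELS[ch_idx], cons)
                variants.append(v)
                pos += 1000
            for _ in range(n_indel):
                gene = panel_genes[rng.choice(len(panel_genes), p=gene_p)]
                ref = "ACGT"[rng.integers(4)]
                frameshift = rng.random() < 0.8
                alt = ref + "ACGT"[rng.integers(4)]
                cons = Consequence.frameshift if frameshift else Consequence.inframe_indel
                subclonal = rng.random() < config.subclonal_weight
                vaf = float(
                    np.clip(
                        rng.normal(
                            config.subclonal_vaf if subclonal else config.clonal_vaf,
                            config.vaf_sd,
                        ),
                        0.02,
                        0.98,
                    )
                )
                t_depth = max(8, int(rng.poisson(config.depth)))
                n_depth = max(8, int(rng.poisson(config.depth)))
                t_alt = int(rng.binomial(t_depth, vaf))
                variants.append(
                    SomaticVariant(
                        sample_id=sample_id, gene=gene, chrom="chr1", pos=pos,
                        ref_allele=ref, alt_allele=alt if frameshift else ref + "AGT",
                        consequence=cons,
                        tumor_ref_reads=t_depth - t_alt, tumor_alt_reads=t_alt,
                        normal_ref_reads=n_depth, normal_alt_reads=0,
                    )
                )
                pos += 1000

            mlpa = None
            methylation = None
            if carrier:
                if mechanism == "somatic_point":
                    v, _ = _emit_snv(
                        rng, config, sample_id, gene_sym.value, pos,
                        CHANNELS[int(rng.integers(96))], Consequence.missense,
                    )
                    # force a clearly clonal hit
                    t_depth = max(8, int(rng.poisson(config.depth)))
                    t_alt = int(rng.binomial(t_depth, config.clonal_vaf))
                    v.tumor_ref_reads, v.tumor_alt_reads = t_depth - t_alt, t_alt
                    variants.append(v)
                    pos += 1000
                if kind == GermlineKind.point:
                    # informative germline heterozygous sites near the predisposing gene
                    p_t = config.loh_alt_fraction if mechanism == "LOH" else 0.5
                    for _ in range(config.n_loh_sites):
                        t_depth = max(8, int(rng.poisson(config.depth)))
                        n_depth = max(8, int(rng.poisson(config.depth)))
                        t_alt = int(rng.binomial(t_depth, p_t))
                        n_alt = int(rng.binomial(n_depth, 0.5))
                        variants.append(
                            SomaticVariant(
                                sample_id=sample_id, gene=gene_sym.value, chrom="chr1",
                                pos=pos, ref_allele="A", alt_allele="G",
                                consequence=Consequence.other,
                                tumor_ref_reads=t_depth - t_alt, tumor_alt_reads=t_alt,
                                normal_ref_reads=n_depth - n_alt, normal_alt_reads=n_alt,
                                context3="AAC",
                            )
                        )
                        pos += 1000
                else:
                    mean = config.mlpa_loh_mean if mechanism == "LOH" else config.mlpa_normal_mean
                    mlpa = {
                        f"probe{j+1}": float(max(0.05, rng.normal(mean, config.mlpa_sd)))
                        for j in range(3)
                    }
                if gene_sym == MmrGene.MLH1:
                    methylation = (
                        float(rng.uniform(0.30, 0.60))
                        if mechanism == "methylation"
                        else float(rng.uniform(0.0, 0.08))
                    )

            # assay labels consistent with the planted MMR state
            if spec.mmr_deficient:
                ihc_lost = rng.random() < spec.ihc_sensitivity
                msi_high = rng.random() < spec.msi_sensitivity
                if not ihc_lost and not msi_high:
                    msi_high = True  # a dMMR tumor is dMMR by at least one assay
                lost = gene_sym.value if carrier else "MLH1"
                ihc = {
                    p: (IhcResult.absent if (ihc_lost and p == lost) else IhcResult.present)
                    for p in MMR_PROTEINS
                }
                msi = {
                    "BAT25": MsiResult.unstable if (msi_high and rng.random() < 0.7) else MsiResult.stable,
                    "BAT26": MsiResult.unstable if msi_high else MsiResult.stable,
                }
                if msi_high and msi["BAT25"] == MsiResult.stable:
                    msi["BAT26"] = MsiResult.unstable
            else:
                discordant = rng.random() < spec.label_discordance
                ihc = {p: IhcResult.present for p in MMR_PROTEINS}
                msi = {m: MsiResult.stable for m in ("BAT25", "BAT26")}
                if discordant:
                    ihc["MLH1"] = IhcResult.absent

            samples.append(
                TumorSample(
                    sample_id=sample_id,
                    group=spec.group,
                    predisposing_gene=gene_sym,
                    germline_variant_kind=kind,
                    ihc=ihc,
                    msi_markers=msi,
                    mlpa_dosage=mlpa,
                    methylation_dosage=methylation,
                    age_at_diagnosis=float(np.round(rng.normal(57, 9), 1)),
                )
            )
            truth.append(
                TruthRecord(
                    sample_id=sample_id,
                    group=spec.group.value,
                    exposures=dict(spec.exposures),
                    rate_per_mb=rate,
                    n_nonsyn=n_nonsyn,
                    n_snv=n_snv,
                    mechanism=mechanism,
                    mmr_deficient=spec.mmr_deficient,
                    predisposing_gene=gene_sym.value,
                )
            )
            tumor_index += 1
    return SimulatedCohort(samples=samples, variants=variants, truth=truth)


def default_study_config(seed: int, n_per_group: int = 20) -> SimulationConfig:
    """Two-group study emulating the dMMR / pMMR Lynch-syndrome breast cohorts.

    Hypermutated fractions (0.9 vs 0.44), per-Mb rate ranges (up to ~700/Mb on
    the 4 Mb panel), second-hit mechanism mixes (~55/36/9 in the deficient
    group) and the predominance of MLH1 carriers follow the observed cohorts.
    """
    dmmr = GroupSpec(
        name="dMMR",
        group=Group.dMMR_LS_BC,
        n_tumors=n_per_group,
        exposures={"6": 0.40, "20": 0.15, "26": 0.10, "1": 0.35},
        mmr_deficient=True,
        hypermutated_fraction=0.9,
        rate_bounds=(1.0, 10.0),
        hyper_rate_bounds=(10.0, 700.0),
        second_hit_probs={"LOH": 0.55, "somatic_point": 0.36, "methylation": 0.0, "none": 0.09},
        predisposing_genes={"MLH1": 0.64, "MSH2": 0.18, "MSH6": 0.18},
    )
    pmmr = GroupSpec(
        name="pMMR",
        group=Group.pMMR_LS_BC,
        n_tumors=n_per_group,
        exposures={"6": 0.10, "20": 0.15, "1": 0.50, "3": 0.25},
        mmr_deficient=False,
        hypermutated_fraction=0.44,
        rate_bounds=(0.5, 10.0),
        hyper_rate_bounds=(10.0, 120.0),
        second_hit_probs={"LOH": 0.22, "somatic_point": 0.33, "methylation": 0.0, "none": 0.45},
        predisposing_genes={"MLH1": 0.44, "MSH2": 0.22, "MSH6": 0.34},
    )
    return SimulationConfig(seed=seed, groups=[dmmr, pmmr])


def simulate_table1_fixture() -> Table1Fixture:
    """Deterministic transcription of the published 30-tumor table (golden input)."""
    return table1_fixture()
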