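"""Domain types for the somatic profiling pipeline.

The central records are :class:`SomaticVariant` (one paired tumor/normal call),
:class:`TumorSample` (per-tumor assay metadata), :class:`GenePanel` (the capture
design that normalizes mutational burden), and :class:`SignatureMatrix`
(reference signatures over the 96 trinucleotide channels).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .channels import CHANNELS, CHANNEL_INDEX


class Consequence(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    splice_site = "splice_site"
    synonymous = "synonymous"
    other = "other"


#: Consequence classes counted as non-synonymous throughout the pipeline.
NONSYNONYMOUS_CONSEQUENCES = frozenset(
    {
        Consequence.missense,
        Consequence.nonsense,
        Consequence.frameshift,
        Consequence.inframe_indel,
        Consequence.splice_site,
    }
)
TRUNCATING_CONSEQUENCES = frozenset({Consequence.frameshift, Consequence.nonsense})
NON_TRUNCATING_CONSEQUENCES = frozenset({Consequence.missense, Consequence.inframe_indel})


class Group(str, enum.Enum):
    dMMR_LS_BC = "dMMR_LS_BC"
    pMMR_LS_BC = "pMMR_LS_BC"
    NC_BC = "NC_BC"
    LS_OC = "LS_OC"
    LS_CRC = "LS_CRC"
    custom = "custom"


class MmrGene(str, enum.Enum):
    MLH1 = "MLH1"
    MSH2 = "MSH2"
    MSH6 = "MSH6"
    none = "none"


class GermlineKind(str, enum.Enum):
    point = "point"
    large_deletion = "large_deletion"
    none = "none"


class IhcResult(str, enum.Enum):
    present = "present"
    absent = "absent"
    not_done = "not_done"


class MsiResult(str, enum.Enum):
    stable = "stable"
    unstable = "unstable"
    not_done = "not_done"


MSI_MARKERS = ("BAT25", "BAT26")


class GeneCategory(str, enum.Enum):
    epigenetic_regulation = "epigenetic_regulation"
    dna_repair = "dna_repair"
    other = "other"


@dataclass
class SomaticVariant:
    """One somatic call on a paired tumor/normal sample.

    ``vaf`` is derived from the tumor read counts; ``somatic_p`` is filled in by
    the paired-count significance test when not supplied by the caller.
    ``context3`` is the 3-mer reference context, required downstream for
    single-nucleotide substitutions only.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    consequence: Consequence
    tumor_ref_reads: int
    tumor_alt_reads: int
    normal_ref_reads: int
    normal_alt_reads: int
    context3: Optional[str] = None
    somatic_p: Optional[float] = None

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("tumor_ref_reads", "tumor_alt_reads", "normal_ref_reads", "normal_alt_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.somatic_p is not None and not 0.0 <= self.somatic_p <= 1.0:
            raise ValueError(f"somatic_p must lie in [0, 1], got {self.somatic_p}")
        if self.context3 is not None:
            self.context3 = self.context3.upper()
            if self.is_snv and (len(self.context3) != 3 or self.context3[1] != self.ref_allele.upper()):
                raise ValueError(
                    f"context3 {self.context3!r} not centered on ref allele {self.ref_allele!r}"
                )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != self.alt_allele
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
        )

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence in NONSYNONYMOUS_CONSEQUENCES

    @property
    def vaf(self) -> float:
        depth = self.tumor_ref_reads + self.tumor_alt_reads
        if depth == 0:
            raise ValueError("vaf undefined: zero tumor depth")
        return self.tumor_alt_reads / depth


@dataclass
class TumorSample:
    """Per-tumor metadata: cohort group, germline predisposition, and assay results."""

    sample_id: str
    group: Group
    predisposing_gene: MmrGene = MmrGene.none
    germline_variant_kind: GermlineKind = GermlineKind.none
    ihc: Mapping[str, IhcResult] = field(default_factory=dict)
    msi_markers: Mapping[str, MsiResult] = field(
        default_factory=lambda: {m: MsiResult.not_done for m in MSI_MARKERS}
    )
    mlpa_dosage: Optional[Mapping[str, float]] = None
    methylation_dosage: Optional[float] = None
    pole_pold1_screened: Optional[bool] = None
    age_at_diagnosis: Optional[float] = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.predisposing_gene = MmrGene(self.predisposing_gene)
        self.germline_variant_kind = GermlineKind(self.germline_variant_kind)
        self.ihc = {k: IhcResult(v) for k, v in self.ihc.items()}
        self.msi_markers = {k: MsiResult(v) for k, v in self.msi_markers.items()}
        if self.group == Group.NC_BC and self.predisposing_gene != MmrGene.none:
            raise ValueError(
                f"{self.sample_id}: non-carrier sample cannot carry predisposing gene "
                f"{self.predisposing_gene.value}"
            )
        if set(self.msi_markers) != set(MSI_MARKERS):
            raise ValueError(
                f"{self.sample_id}: msi_markers must be exactly {MSI_MARKERS}, "
                f"got {sorted(self.msi_markers)}"
            )
        if self.mlpa_dosage is not None:
            for probe, ratio in self.mlpa_dosage.items():
                if ratio < 0:
                    raise ValueError(f"{self.sample_id}: MLPA ratio for {probe} must be >= 0")
        if self.methylation_dosage is not None and self.methylation_dosage < 0:
            raise ValueError(f"{self.sample_id}: methylation dosage must be >= 0")

    @property
    def is_carrier(self) -> bool:
        return self.predisposing_gene != MmrGene.none


@dataclass
class GenePanel:
    """A capture panel: gene set, footprint in megabases, functional categories."""

    genes: frozenset[str]
    footprint_mb: float
    category: Mapping[str, frozenset[GeneCategory]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError("panel must contain at least one gene")
        if self.footprint_mb <= 0:
            raise ValueError(f"footprint_mb must be positive, got {self.footprint_mb}")
        self.category = {
            g: frozenset(GeneCategory(c) for c in cats) for g, cats in self.category.items()
        }
        extra = set(self.category) - self.genes
        if extra:
            raise ValueError(f"categorized genes absent from panel: {sorted(extra)[:5]}")

    def genes_in_category(self, category: GeneCategory) -> frozenset[str]:
        category = GeneCategory(category)
        return frozenset(g for g, cats in self.category.items() if category in cats)


@dataclass
class SignatureMatrix:
    """Reference mutational signatures: rows are signatures, columns the 96 channels."""

    signature_ids: tuple[str, ...]
    probs: np.ndarray  # shape (n_signatures, 96), rows sum to 1

    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.signature_ids = tuple(str(s) for s in self.signature_ids)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(set(self.signature_ids)) != len(self.signature_ids):
            raise ValueError("duplicate signature ids")
        if self.probs.shape != (len(self.signature_ids), 96):
            raise ValueError(
                f"probs must have shape ({len(self.signature_ids)}, 96), got {self.probs.shape}"
            )
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            offenders = [self.signature_ids[i] for i in np.nonzero(bad)[0][:5]]
            raise ValueError(f"signature rows must sum to 1 within 1e-6; offenders: {offenders}")

    def profile(self, signature_id: str) -> np.ndarray:
        return self.probs[self.signature_ids.index(str(signature_id))]

    def mixture_profile(self, weights: Mapping[str, float]) -> np.ndarray:
        """Channel probabilities of a weighted mixture of signatures (renormalized)."""
        vec = np.zeros(96)
        for sig, w in weights.items():
            vec += w * self.profile(sig)
        total = vec.sum()
        if total <= 0:
            raise ValueError("mixture has zero total probability")
        return vec / total


@dataclass
class MutationCatalog:
    """96-channel substitution count vector for one tumor. Indels contribute nothing."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError(f"counts must have shape (96,), got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty catalog")
        return self.counts / self.total

    def __getitem__(self, channel: str) -> int:
        return int(self.counts[CHANNEL_INDEX[channel]])


@dataclass
class ExposureVector:
    """Per-signature refitted weights; ``residual`` is the unexplained fraction."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for sig, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for signature {sig}")
        if sum(self.weights.values()) > 1 + 1e-9:
            raise ValueError("exposure weights must sum to at most 1")

    @property
    def residual(self) -> float:
        return max(0.0, 1.0 - sum(self.weights.values()))

    def get(self, signature_id: str) -> float:
        return self.weights.get(str(signature_id), 0.0)
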