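"""Tumor mutational burden and mismatch-repair status classification.

Burden is the count of retained non-synonymous somatic mutations normalized by
the panel footprint in megabases; a tumor is hypermutated when it carries
strictly more than 10 such mutations per Mb. A tumor is MMR-deficient (dMMR)
when any MMR protein is absent by immunohistochemistry and/or at least one of
the mononucleotide-repeat markers BAT25/BAT26 is unstable; otherwise it is
MMR-proficient (pMMR).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import GenePanel, IhcResult, MsiResult, SomaticVariant, TumorSample

#: Hypermutation rule: strictly more than this many non-synonymous mutations/Mb.
HYPERMUTATION_THRESHOLD_PER_MB = 10.0


@dataclass(frozen=True)
class BurdenRecord:
    sample_id: str
    n_nonsyn: int
    rate_per_mb: float
    hypermutated: bool

    @classmethod
    def from_rate(cls, sample_id: str, rate_per_mb: float, footprint_mb: float) -> "BurdenRecord":
        """Build a record from an already-normalized per-Mb rate (e.g. a published table)."""
        if footprint_mb <= 0:
            raise ValueError("footprint_mb must be positive")
        return cls(
            sample_id=sample_id,
            n_nonsyn=round(rate_per_mb * footprint_mb),
            rate_per_mb=rate_per_mb,
            hypermutated=rate_per_mb > HYPERMUTATION_THRESHOLD_PER_MB,
        )


class MmrState(str, enum.Enum):
    dMMR = "dMMR"
    pMMR = "pMMR"


@dataclass(frozen=True)
class MmrStatus:
    status: MmrState
    msi_high: bool
    ihc_abnormal: bool


def burden(variants: Iterable[SomaticVariant], panel: GenePanel, sample_id: str) -> BurdenRecord:
    """Burden record for one tumor from its somatic-filtered non-synonymous variants."""
    if panel.footprint_mb <= 0:
        raise ValueError("panel footprint must be positive")
    n = sum(1 for v in variants if v.sample_id == sample_id and v.is_nonsynonymous)
    rate = n / panel.footprint_mb
    return BurdenRecord(
        sample_id=sample_id,
        n_nonsyn=n,
        rate_per_mb=rate,
        hypermutated=rate > HYPERMUTATION_THRESHOLD_PER_MB,
    )


def classify_mmr(sample: TumorSample) -> MmrStatus:
    """dMMR iff any MMR protein absent by IHC and/or any of BAT25/BAT26 unstable."""
    ihc_done = any(r != IhcResult.not_done for r in sample.ihc.values())
    msi_done = any(r != MsiResult.not_done for r in sample.msi_markers.values())
    if not ihc_done and not msi_done:
        raise ValueError(f"MMR status indeterminable for {sample.sample_id}: all assays not done")
    ihc_abnormal = any(r == IhcResult.absent for r in sample.ihc.values())
    msi_high = any(r == MsiResult.unstable for r in sample.msi_markers.values())
    status = MmrState.dMMR if (ihc_abnormal or msi_high) else MmrState.pMMR
    return MmrStatus(status=status, msi_high=msi_high, ihc_abnormal=ihc_abnormal)


def msi_high_count(samples: Sequence[TumorSample]) -> int:
    """Number of samples in the subset that are MSI-high."""
    return sum(
        1
        for s in samples
        if any(r == MsiResult.unstable for r in s.msi_markers.values())
    )
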