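"""Attribution of the somatic "second hit" inactivating the wild-type MMR allele.

For carriers of a germline point variant, loss of heterozygosity (LOH) is
assessed through the allele-ratio statistic R = (alt:ref)_tumor / (alt:ref)_normal
at informative heterozygous sites; for carriers of a germline large deletion,
through MLPA probe dosage over the deleted region. Promoter hypermethylation
(MLH1 carriers only) and somatic point mutation of the predisposing gene are the
other mechanisms considered. When both LOH and a somatic point mutation are
present the call is tallied as LOH, with both recorded in the evidence trail.

The strict/putative LOH bands and the MLPA deletion threshold follow external
interpretive conventions and are therefore configurable; the defaults are
strict at R >= 2 or R <= 0.5, putative at 1.5 <= R < 2 or 0.5 < R <= 2/3, and
an MLPA median dosage <= 0.75 (midpoint of the one- and two-copy expectations).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .types import MmrGene, SomaticVariant, TumorSample

#: Hypermethylation rule: methylation dosage ratio of 0.25 or higher.
METHYLATION_CUTOFF = 0.25


class LohLevel(str, enum.Enum):
    strict = "strict"
    putative = "putative"
    none = "none"


class Mechanism(str, enum.Enum):
    LOH = "LOH"
    somatic_point = "somatic_point"
    methylation = "methylation"
    none = "none"
    ND = "ND"


@dataclass(frozen=True)
class LohCall:
    ratio: Optional[float]
    call: LohLevel


@dataclass(frozen=True)
class SecondHitCall:
    sample_id: str
    mechanism: Mechanism
    evidence: str


@dataclass(frozen=True)
class LohThresholds:
    """Allele-ratio bands for point-variant carriers plus the MLPA dosage cutoff."""

    strict_high: float = 2.0
    strict_low: float = 0.5
    putative_high: float = 1.5
    putative_low: float = 2.0 / 3.0
    mlpa_deletion: float = 0.75

    def __post_init__(self) -> None:
        ok = (
            0
            < self.strict_low
            < self.putative_low
            <= 1.0
            <= self.putative_high
            < self.strict_high
        )
        if not ok:
            raise ValueError(
                "inconsistent LOH threshold config: require "
                "0 < strict_low < putative_low <= 1 <= putative_high < strict_high"
            )


DEFAULT_THRESHOLDS = LohThresholds()


def loh_ratio(t_alt: int, t_ref: int, n_alt: int, n_ref: int) -> float:
    """R = (t_alt/t_ref) / (n_alt/n_ref). All four counts must be positive."""
    if min(t_alt, t_ref, n_alt, n_ref) <= 0:
        raise ValueError("uninformative site: all four allele counts must be > 0")
    return (t_alt / t_ref) / (n_alt / n_ref)


def call_loh_point(R: float, thresholds: LohThresholds = DEFAULT_THRESHOLDS) -> LohCall:
    """Classify an allele-ratio statistic into strict / putative / no LOH."""
    if R <= 0:
        raise ValueError("LOH ratio must be positive")
    if R >= thresholds.strict_high or R <= thresholds.strict_low:
        level = LohLevel.strict
    elif thresholds.putative_high <= R or R <= thresholds.putative_low:
        level = LohLevel.putative
    else:
        level = LohLevel.none
    return LohCall(ratio=R, call=level)


def call_loh_mlpa(
    dosage_ratios: Mapping[str, float],
    thresholds: LohThresholds = DEFAULT_THRESHOLDS,
) -> Optional[LohCall]:
    """LOH from MLPA probe dosage over the germline-deleted region.

    The median probe ratio is compared to the deletion threshold. Returns
    ``None`` (not determinable) when no probes cover the region.
    """
    ratios = sorted(dosage_ratios.values())
    if not ratios:
        return None
    mid = len(ratios) // 2
    median = ratios[mid] if len(ratios) % 2 else (ratios[mid - 1] + ratios[mid]) / 2
    level = LohLevel.strict if median <= thresholds.mlpa_deletion else LohLevel.none
    return LohCall(ratio=median, call=level)


def call_methylation(dosage: float) -> bool:
    """Promoter hypermethylation iff the methylation dosage ratio is >= 0.25."""
    if dosage < 0:
        raise ValueError("methylation dosage must be >= 0")
    return dosage >= METHYLATION_CUTOFF


def attribute_second_hit(
    sample: TumorSample,
    filtered_variants: Iterable[SomaticVariant],
    loh: Optional[LohCall],
    methylation: Optional[bool] = None,
) -> SecondHitCall:
    """Attribute the second hit for one germline carrier.

    Precedence: LOH > somatic point mutation of the predisposing gene >
    promoter methylation > none; ND when the LOH assay is unavailable and no
    positive mechanism was found. Coexisting mechanisms are all listed in the
    evidence string (LOH together with a somatic point mutation is common).
    """
    if not sample.is_carrier:
        raise ValueError(f"second hit undefined for non-carrier sample {sample.sample_id}")
    gene = sample.predisposing_gene.value
    evidence: list[str] = []
    has_loh = loh is not None and loh.call in (LohLevel.strict, LohLevel.putative)
    if loh is not None and loh.ratio is not None:
        evidence.append(f"LOH {loh.call.value} (R={loh.ratio:.3g})")
    somatic_hits = [
        v
        for v in filtered_variants
        if v.sample_id == sample.sample_id and v.gene == gene and v.is_nonsynonymous
    ]
    if somatic_hits:
        locs = ",".join(f"{v.chrom}:{v.pos}" for v in somatic_hits[:3])
        evidence.append(f"somatic point mutation in {gene} ({locs})")
    if methylation is not None:
        evidence.append(f"promoter methylation {'+' if methylation else '-'}")

    if has_loh:
        mech = Mechanism.LOH
    elif somatic_hits:
        mech = Mechanism.somatic_point
    elif methylation:
        mech = Mechanism.methylation
    elif loh is None:
        mech = Mechanism.ND
        evidence.append("LOH assay unavailable")
    else:
        mech = Mechanism.none
    return SecondHitCall(sample_id=sample.sample_id, mechanism=mech, evidence="; ".join(evidence))


def second_hit_from_code(sample_id: str, code: str) -> SecondHitCall:
    """Parse a tabulated second-hit code ('L', 's', 'L, s', 'm', 'None', 'ND').

    Codes are tallied once under the highest-precedence mechanism present;
    'N/A' codes (non-carriers) are rejected.
    """
    raw = code.strip()
    if raw.upper().startswith("N/A"):
        raise ValueError(f"second hit undefined for non-carrier sample {sample_id}")
    tokens = {t.strip() for t in raw.split(",")}
    if raw == "ND":
        mech = Mechanism.ND
    elif raw == "None":
        mech = Mechanism.none
    elif "L" in tokens:
        mech = Mechanism.LOH
    elif "s" in tokens:
        mech = Mechanism.somatic_point
    elif "m" in tokens:
        mech = Mechanism.methylation
    else:
        raise ValueError(f"unrecognized second-hit code {code!r} for {sample_id}")
    return SecondHitCall(sample_id=sample_id, mechanism=mech, evidence=f"code={raw}")


def tally(calls: Sequence[SecondHitCall]) -> dict[Mechanism, int]:
    """Mechanism counts over a cohort; every mechanism appears (zero when absent)."""
    counts = Counter(c.mechanism for c in calls)
    return {m: counts.get(m, 0) for m in Mechanism}
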