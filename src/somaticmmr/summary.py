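"""Per-group cohort report assembled from the per-sample pipeline outputs.

For each cohort group this produces the mean age at diagnosis, the mean
non-synonymous mutation count and per-Mb rate, the hypermutated proportion, the
distribution of predisposing genes, the second-hit mechanism distribution
(including "not determined" as its own bucket) and the group signature summary.
Raw values are always retained; rounding (per-Mb means to integers, proportions
to whole percent) is applied only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .burden import BurdenRecord
from .second_hit import Mechanism, SecondHitCall
from .signatures import GroupSignatureSummary
from .stats import MannWhitneyResult, fisher_exact_two_sided, mann_whitney_u
from .types import Group, MmrGene, TumorSample


@dataclass(frozen=True)
class Proportion:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator if self.denominator else 0.0

    @property
    def percent(self) -> int:
        return round(100 * self.value)

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent}%)"


@dataclass
class CohortSummary:
    group: Group
    n: int
    mean_age: Optional[float]
    mean_n_nonsyn: float
    mean_rate_per_mb: float
    prop_hypermutated: Proportion
    gene_distribution: dict[MmrGene, Proportion]
    second_hit_distribution: Optional[dict[Mechanism, Proportion]]
    signature_summary: Optional[GroupSignatureSummary] = None

    def display(self) -> str:
        lines = [
            f"{self.group.value} (n = {self.n})",
            f"  mean age at diagnosis: "
            + (f"{self.mean_age:.0f}" if self.mean_age is not None else "n/a"),
            f"  mean non-synonymous mutations: {self.mean_n_nonsyn:.0f} "
            f"({self.mean_rate_per_mb:.0f}/Mb)",
            f"  hypermutated (>10/Mb): {self.prop_hypermutated}",
        ]
        for gene, prop in self.gene_distribution.items():
            lines.append(f"  predisposing {gene.value}: {prop}")
        if self.second_hit_distribution is not None:
            for mech, prop in self.second_hit_distribution.items():
                lines.append(f"  second hit {mech.value}: {prop}")
        if self.signature_summary is not None:
            lines.append(f"  combined MMR-signature score: {self.signature_summary.combined_mmr:.3f}")
        return "\n".join(lines)


def summarize(
    samples: Sequence[TumorSample],
    burdens: Mapping[str, BurdenRecord],
    second_hits: Optional[Mapping[str, SecondHitCall]] = None,
    signature_summaries: Optional[Mapping[str, GroupSignatureSummary]] = None,
) -> list[CohortSummary]:
    """One :class:`CohortSummary` per group present among ``samples``.

    ``second_hits`` must cover every germline carrier; every sample needs a
    burden record. A missing stage output raises an error naming the sample.
    """
    second_hits = second_hits or {}
    by_group: dict[Group, list[TumorSample]] = {}
    for s in samples:
        by_group.setdefault(s.group, []).append(s)

    out: list[CohortSummary] = []
    for group, members in by_group.items():
        n = len(members)
        for s in members:
            if s.sample_id not in burdens:
                raise ValueError(f"sample {s.sample_id} missing stage output: burden")
            if s.is_carrier and s.sample_id not in second_hits:
                raise ValueError(f"sample {s.sample_id} missing stage output: second_hit")
        ages = [s.age_at_diagnosis for s in members if s.age_at_diagnosis is not None]
        recs = [burdens[s.sample_id] for s in members]
        n_hyper = sum(r.hypermutated for r in recs)
        carriers = [s for s in members if s.is_carrier]
        gene_dist = {}
        if carriers:
            for gene in (MmrGene.MLH1, MmrGene.MSH2, MmrGene.MSH6):
                k = sum(1 for s in carriers if s.predisposing_gene == gene)
                gene_dist[gene] = Proportion(k, len(carriers))
        sh_dist = None
        if carriers:
            calls = [second_hits[s.sample_id] for s in carriers]
            sh_dist = {
                mech: Proportion(sum(1 for c in calls if c.mechanism == mech), len(carriers))
                for mech in Mechanism
            }
        sig = signature_summaries.get(group.value) if signature_summaries else None
        out.append(
            CohortSummary(
                group=group,
                n=n,
                mean_age=sum(ages) / len(ages) if ages else None,
                mean_n_nonsyn=sum(r.n_nonsyn for r in recs) / n,
                mean_rate_per_mb=sum(r.rate_per_mb for r in recs) / n,
                prop_hypermutated=Proportion(n_hyper, n),
                gene_distribution=gene_dist,
                second_hit_distribution=sh_dist,
                signature_summary=sig,
            )
        )
    return out


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    kind: str = "continuous",
) -> MannWhitneyResult | float:
    """Group comparison: Mann-Whitney for continuous metrics, Fisher for proportions.

    For ``kind="proportion"`` the inputs are binary indicators per sample and
    the returned value is the two-sided Fisher exact p.
    """
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "continuous":
        return mann_whitney_u(values_a, values_b)
    if kind == "proportion":
        k_a = sum(1 for v in values_a if v)
        k_b = sum(1 for v in values_b if v)
        return fisher_exact_two_sided(k_a, len(values_a) - k_a, k_b, len(values_b) - k_b)
    raise ValueError(f"kind must be 'continuous' or 'proportion', got {kind!r}")
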