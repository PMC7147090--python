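"""LOH ratio, threshold bands, methylation cutoff, and second-hit attribution."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaticmmr import (
    Group,
    LohThresholds,
    Mechanism,
    TumorSample,
    attribute_second_hit,
    call_loh_mlpa,
    call_loh_point,
    call_methylation,
    loh_ratio,
    second_hit_from_code,
    tally,
)
from somaticmmr.second_hit import LohCall, LohLevel

from conftest import make_snv


class TestLohRatio:
    def test_balanced_alleles_give_unity(self):
        assert loh_ratio(10, 10, 10, 10) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert loh_ratio(30, 10, 15, 15) == pytest.approx(3.0)

    @given(
        t_alt=st.integers(1, 200), t_ref=st.integers(1, 200),
        n_alt=st.integers(1, 200), n_ref=st.integers(1, 200),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reciprocity_of_swapped_samples(self, t_alt, t_ref, n_alt, n_ref):
        r = loh_ratio(t_alt, t_ref, n_alt, n_ref)
        r_inv = loh_ratio(n_alt, n_ref, t_alt, t_ref)
        assert r * r_inv == pytest.approx(1.0)

    def test_uninformative_site_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            loh_ratio(10, 0, 10, 10)


class TestLohBands:
    @pytest.mark.parametrize(
        "R,level",
        [
            (1.0, LohLevel.none),
            (3.0, LohLevel.strict),
            (1.7, LohLevel.putative),
            (2.0, LohLevel.strict),
            (0.5, LohLevel.strict),
            (0.6, LohLevel.putative),
            (0.8, LohLevel.none),
        ],
    )
    def test_default_bands(self, R, level):
        assert call_loh_point(R).call == level

    def test_overlapping_band_config_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            LohThresholds(strict_high=1.4, putative_high=1.5)

    def test_mlpa_balanced_probes(self):
        call = call_loh_mlpa({"p1": 1.0, "p2": 1.0, "p3": 1.02})
        assert call.call == LohLevel.none

    def test_mlpa_half_dosage_is_loh(self):
        call = call_loh_mlpa({"p1": 0.5, "p2": 0.5})
        assert call.call == LohLevel.strict

    def test_mlpa_no_probes_not_determinable(self):
        assert call_loh_mlpa({}) is None


class TestMethylation:
    @pytest.mark.parametrize("dosage,expected", [(0.25, True), (0.24, False), (0.0, False)])
    def test_cutoff_inclusive(self, dosage, expected):
        assert call_methylation(dosage) is expected

    @given(lo=st.floats(0, 1), hi=st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_dosage(self, lo, hi):
        lo, hi = sorted((lo, hi))
        assert call_methylation(lo) <= call_methylation(hi)


def _carrier(sample_id="LS1", gene="MLH1", methylation=None):
    return TumorSample(
        sample_id=sample_id,
        group=Group.dMMR_LS_BC,
        predisposing_gene=gene,
        germline_variant_kind="point",
        ihc={"MLH1": "absent"},
        msi_markers={"BAT25": "stable", "BAT26": "unstable"},
        methylation_dosage=methylation,
    )


class TestAttribution:
    def test_loh_takes_precedence_over_somatic_point(self):
        hit = make_snv(sample_id="LS1", gene="MLH1", somatic_p=1e-6)
        call = attribute_second_hit(
            _carrier(), [hit], LohCall(ratio=3.0, call=LohLevel.strict)
        )
        assert call.mechanism == Mechanism.LOH
        assert "somatic point" in call.evidence  # both recorded

    def test_somatic_point_without_loh(self):
        hit = make_snv(sample_id="LS1", gene="MLH1", somatic_p=1e-6)
        call = attribute_second_hit(_carrier(), [hit], LohCall(ratio=1.0, call=LohLevel.none))
        assert call.mechanism == Mechanism.somatic_point

    def test_methylation_when_nothing_else(self):
        call = attribute_second_hit(
            _carrier(methylation=0.4), [], LohCall(ratio=1.0, call=LohLevel.none), True
        )
        assert call.mechanism == Mechanism.methylation

    def test_no_assays_is_nd(self):
        call = attribute_second_hit(_carrier(), [], None, None)
        assert call.mechanism == Mechanism.ND

    def test_informative_assays_without_hit_is_none(self):
        call = attribute_second_hit(_carrier(), [], LohCall(ratio=1.0, call=LohLevel.none), False)
        assert call.mechanism == Mechanism.none

    def test_non_carrier_rejected(self):
        nc = TumorSample(sample_id="NC1", group=Group.NC_BC)
        with pytest.raises(ValueError, match="non-carrier"):
            attribute_second_hit(nc, [], None)


class TestPublishedTallies:
    def test_dmmr_split(self, table1):
        calls = [
            second_hit_from_code(s.sample_id, table1.second_hit_code[s.sample_id])
            for s in table1.samples
            if s.group == Group.dMMR_LS_BC
        ]
        counts = tally(calls)
        assert counts[Mechanism.LOH] == 6
        assert counts[Mechanism.somatic_point] == 4
        assert counts[Mechanism.none] == 1
        assert counts[Mechanism.ND] == 0

    def test_pmmr_split(self, table1):
        calls = [
            second_hit_from_code(s.sample_id, table1.second_hit_code[s.sample_id])
            for s in table1.samples
            if s.group == Group.pMMR_LS_BC
        ]
        counts = tally(calls)
        assert counts[Mechanism.LOH] == 2
        assert counts[Mechanism.somatic_point] == 3
        assert counts[Mechanism.none] == 3
        assert counts[Mechanism.ND] == 1

    def test_tally_partitions_cohort(self, table1):
        carriers = [s for s in table1.samples if s.is_carrier]
        calls = [
            second_hit_from_code(s.sample_id, table1.second_hit_code[s.sample_id])
            for s in carriers
        ]
        assert sum(tally(calls).values()) == len(carriers) == 20

    def test_non_carrier_codes_rejected(self, table1):
        with pytest.raises(ValueError, match="non-carrier"):
            second_hit_from_code("BC24_31711T", "N/A")
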