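"""Catalog construction, exposure refitting, and group signature summaries."""

import numpy as np
import pytest

from somaticmmr import (
    Consequence,
    ExposureVector,
    MutationCatalog,
    SignatureMatrix,
    SignatureRefit,
    build_catalog,
    group_signature_summary,
    refit_exposures,
)

from conftest import expected_catalog, make_snv


class TestBuildCatalog:
    def test_no_snvs_gives_zero_catalog(self):
        indel = make_snv(ref="C", alt="CT", consequence=Consequence.frameshift, context3=None)
        cat = build_catalog([indel], "S1")
        assert cat.total == 0

    def test_identical_snvs_accumulate_one_channel(self):
        vs = [make_snv(pos=p) for p in (1, 2, 3)]
        cat = build_catalog(vs, "S1")
        assert cat["A[C>T]A"] == 3 and cat.total == 3

    def test_snv_without_context_is_named_in_error(self):
        v = make_snv(context3=None)
        with pytest.raises(ValueError, match="chr1:100"):
            build_catalog([v], "S1")

    def test_other_samples_ignored(self):
        vs = [make_snv(sample_id="A"), make_snv(sample_id="B")]
        assert build_catalog(vs, "A").total == 1


class TestRefit:
    def test_pure_signature_recovered(self, reference):
        cat = expected_catalog(reference, {"6": 1.0}, 1000)
        exp = refit_exposures(cat, reference)
        assert exp.get("6") >= 0.95
        assert all(w < 0.06 for s, w in exp.weights.items() if s != "6")

    def test_two_signature_mixture_matches_grid_search_oracle(self, reference):
        """Exhaustive search over the 2-signature simplex at step 0.001 is the
        independent optimum; the refit agrees within +/-0.02."""
        cat = expected_catalog(reference, {"4": 0.6, "17": 0.4}, 100_000)
        t = cat.fractions()
        s4, s17 = reference.profile("4"), reference.profile("17")
        grid = np.arange(0, 1.0005, 0.001)
        a, b = np.meshgrid(grid, grid, indexing="ij")
        # quadratic expansion of ||t - a*s4 - b*s17||^2 over the full grid
        err = (
            t @ t
            - 2 * a * (t @ s4)
            - 2 * b * (t @ s17)
            + a**2 * (s4 @ s4)
            + 2 * a * b * (s4 @ s17)
            + b**2 * (s17 @ s17)
        )
        err[a + b > 1.0] = np.inf
        i, j = np.unravel_index(np.argmin(err), err.shape)
        best = (grid[i], grid[j])
        exp = refit_exposures(cat, reference)
        assert exp.get("4") == pytest.approx(best[0], abs=0.02)
        assert exp.get("17") == pytest.approx(best[1], abs=0.02)

    def test_single_signature_reference_explains_itself(self, reference):
        single = SignatureMatrix(signature_ids=("only",), probs=reference.probs[:1])
        cat = MutationCatalog("s", np.round(single.probs[0] * 50000).astype(int))
        exp = refit_exposures(cat, single)
        assert exp.get("only") == pytest.approx(1.0, abs=1e-3)
        assert exp.residual == pytest.approx(0.0, abs=1e-3)

    def test_empty_catalog_rejected(self, reference):
        with pytest.raises(ValueError, match="empty catalog"):
            SignatureRefit(MutationCatalog("s", np.zeros(96, dtype=int)), reference)

    def test_scale_invariance(self, reference):
        cat = expected_catalog(reference, {"2": 0.5, "9": 0.5}, 2000)
        exp1 = refit_exposures(cat, reference)
        exp2 = refit_exposures(MutationCatalog("s", cat.counts * 7), reference)
        for sig in set(exp1.weights) | set(exp2.weights):
            assert exp1.get(sig) == pytest.approx(exp2.get(sig), abs=1e-6)

    def test_results_summary_reports_fit(self, reference):
        cat = expected_catalog(reference, {"6": 1.0}, 500)
        res = SignatureRefit(cat, reference).fit()
        text = res.summary()
        assert str(cat.total) in text and "6" in text

    def test_reconstruction_error_decreases_with_refinement(self, reference):
        """A coarser stopping tolerance never yields a better fit."""
        rng = np.random.default_rng(5)
        counts = rng.multinomial(300, reference.mixture_profile({"3": 0.5, "11": 0.5}))
        cat = MutationCatalog("s", counts)
        sse_loose = SignatureRefit(cat, reference).fit(tol=1e-1).sse
        sse_tight = SignatureRefit(cat, reference).fit(tol=1e-6).sse
        assert sse_tight <= sse_loose + 1e-12


class TestGroupSummary:
    def test_published_group_averages_combine_to_printed_scores(self):
        """The tabulated per-signature group means for the MMR signatures sum
        to the printed combined scores 0.115 (deficient) and 0.226 (proficient)."""
        exposures = {
            "dmmr": ExposureVector(weights={"6": 0.072, "20": 0.007, "26": 0.036}),
            "pmmr": ExposureVector(weights={"6": 0.088, "20": 0.138, "26": 0.0}),
        }
        groups = {"dmmr": "dMMR_LS_BC", "pmmr": "pMMR_LS_BC"}
        summaries = {g.group: g for g in group_signature_summary(exposures, groups)}
        assert round(summaries["dMMR_LS_BC"].combined_mmr, 3) == 0.115
        assert round(summaries["pMMR_LS_BC"].combined_mmr, 3) == 0.226

    def test_single_sample_group_means_equal_weights(self):
        exp = ExposureVector(weights={"1": 0.3, "6": 0.2})
        [summary] = group_signature_summary({"s": exp}, {"s": "G"})
        assert summary.mean_weight == {"1": 0.3, "6": 0.2}
        assert summary.combined_mmr == pytest.approx(0.2)

    def test_other_bucket_pools_small_means(self):
        exp = ExposureVector(weights={"1": 0.9, "2": 0.04, "3": 0.03})
        [summary] = group_signature_summary({"s": exp}, {"s": "G"})
        assert summary.other_bucket == pytest.approx(0.07)

    def test_min_catalog_filter_excludes_sparse_samples(self):
        exposures = {
            "big": ExposureVector(weights={"1": 1.0}),
            "tiny": ExposureVector(weights={"2": 1.0}),
        }
        groups = {"big": "G", "tiny": "G"}
        [summary] = group_signature_summary(
            exposures, groups, min_catalog_total=50, catalog_totals={"big": 500, "tiny": 5}
        )
        assert summary.mean_weight == {"1": 1.0}
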