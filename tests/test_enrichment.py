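"""Top-gene recurrence, category enrichment, and the Mann-Whitney U test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu

from somaticmmr import (
    GeneCategory,
    category_enrichment,
    fisher_exact_two_sided,
    gene_recurrence,
    mann_whitney_u,
    top_genes,
)

from conftest import make_snv


def enumeration_two_sided_p(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins and
    sum the probabilities of those no more likely than the observed table."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(K, n)
    pmf = {k: hypergeom.pmf(k, N, K, n) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs * (1 + 1e-9)))


class TestGeneRecurrence:
    def test_three_of_eleven_tumors_reaches_default_cutoff(self, panel):
        vs = [make_snv(sample_id=f"T{i}", gene="TP53") for i in range(3)]
        recs = {r.gene: r for r in gene_recurrence(vs, 11, panel)}
        assert recs["TP53"].n_tumors_high_vaf == 3
        assert recs["TP53"].proportion == pytest.approx(3 / 11)
        assert recs["TP53"].is_top  # 0.273 >= 0.27

    def test_low_vaf_mutations_do_not_count(self, panel):
        vs = [make_snv(sample_id="T1", gene="TP53", t_ref=90, t_alt=10)]
        recs = {r.gene: r for r in gene_recurrence(vs, 10, panel)}
        assert recs["TP53"].n_tumors_high_vaf == 0

    def test_tumor_counts_once_per_gene(self, panel):
        vs = [make_snv(sample_id="T1", gene="TP53", pos=p) for p in (1, 2)]
        recs = {r.gene: r for r in gene_recurrence(vs, 10, panel)}
        assert recs["TP53"].n_tumors_high_vaf == 1

    def test_duplicating_every_record_leaves_proportions_unchanged(self, panel):
        vs = [make_snv(sample_id=f"T{i}", gene="PTEN") for i in range(4)]
        r1 = {r.gene: r.proportion for r in gene_recurrence(vs, 10, panel)}
        r2 = {r.gene: r.proportion for r in gene_recurrence(vs * 2, 10, panel)}
        assert r1 == r2

    def test_off_panel_gene_warned_and_excluded(self, panel):
        vs = [make_snv(sample_id="T1", gene="NOT_A_GENE")]
        with pytest.warns(UserWarning, match="NOT_A_GENE"):
            recs = gene_recurrence(vs, 10, panel)
        assert all(r.n_tumors_high_vaf == 0 for r in recs)


class TestCategoryEnrichment:
    def test_identical_proportions_give_p_one(self, panel):
        # choose a top set with the same category fraction as the panel: all genes
        res = category_enrichment(sorted(panel.genes), panel, GeneCategory.dna_repair)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(5, 13, 42, 518), (4, 14, 41, 519)])
    def test_matches_enumeration_oracle(self, table):
        p = fisher_exact_two_sided(*table)
        assert p == pytest.approx(enumeration_two_sided_p(*table), abs=1e-12)
        # scipy uses the same two-sided convention
        a, b, c, d = table
        assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], abs=1e-9)

    def test_invariant_to_simultaneous_row_and_column_swap(self):
        assert fisher_exact_two_sided(5, 13, 42, 518) == pytest.approx(
            fisher_exact_two_sided(518, 42, 13, 5), abs=1e-12
        )

    def test_empty_top_set_rejected(self, panel):
        with pytest.raises(ValueError, match="empty top"):
            category_enrichment([], panel, GeneCategory.dna_repair)

    def test_table_construction_from_panel(self, panel):
        cat_genes = sorted(panel.genes_in_category(GeneCategory.epigenetic_regulation))
        top = cat_genes[:5] + sorted(panel.genes - set(cat_genes))[:13]
        res = category_enrichment(top, panel, GeneCategory.epigenetic_regulation)
        a, b, c, d = res.table
        assert (a, b) == (5, 13)
        assert a + b + c + d == len(panel.genes)


class TestMannWhitney:
    def test_complete_separation_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)  # 2 of the C(6,3)=20 rank splits
        assert res.method == "exact"

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([2, 2, 5], [5, 2, 2])
        assert res.p == pytest.approx(1.0)

    @given(
        data=st.lists(st.integers(0, 6), min_size=4, max_size=10),
        split=st.integers(2, 8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_path_matches_brute_enumeration(self, data, split):
        split = min(split, len(data) - 2)
        a, b = data[:split], data[split:]
        res = mann_whitney_u(a, b)
        # independent brute force: deviation of U over all assignments
        from scipy.stats import rankdata

        pooled = np.asarray(a + b, dtype=float)
        if np.ptp(pooled) == 0:
            assert res.p == 1.0
            return
        ranks = rankdata(pooled)
        n_a = len(a)
        mu = n_a * len(b) / 2
        u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n_a):
            u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
            total += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.permutation(np.arange(10, dtype=float))
            a, b = vals[:5], vals[5:]
            ours = mann_whitney_u(a, b).p
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_permutation_oracle(self):
        """n=15 vs 15 normal samples: the tie-corrected normal approximation
        stays within 0.02 of a 20k permutation estimate."""
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.7, 1, 15)
        res = mann_whitney_u(a, b)
        assert res.method == "normal"
        from scipy.stats import rankdata

        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        mu = 15 * 15 / 2
        u_obs = ranks[:15].sum() - 15 * 16 / 2
        count = 0
        reps = 20_000
        for _ in range(reps):
            perm = rng.permutation(30)
            u = ranks[perm[:15]].sum() - 15 * 16 / 2
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
        assert res.p == pytest.approx(count / reps, abs=0.02)
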