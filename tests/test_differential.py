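"""BH adjustment, NB Wald DE, TE-change test and hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from translatome.differential import (
    bh_adjust,
    de_results_from_table,
    de_test,
    hypergeom_enrich,
    te_change_test,
)


def bh_step_up_oracle(p):
    """Brute-force BH: fdr_i = min over j with p_(j) >= p_(i) of p_(j)*n/rank(j)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        out[idx] = running_min
    return out


class TestBH:
    def test_equal_spacing_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_singleton_and_all_ones(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up_oracle(p), rtol=1e-12)


def _frames(rng, n_genes, mu_a, mu_b, disp=0.01, reps=2):
    def draw(mu):
        n = 1.0 / disp
        return rng.negative_binomial(n, n / (n + mu), size=(n_genes, reps))

    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    return (
        pd.DataFrame(draw(np.broadcast_to(mu_a, (reps, n_genes)).T), index=idx),
        pd.DataFrame(draw(np.broadcast_to(mu_b, (reps, n_genes)).T), index=idx),
    )


class TestDETest:
    def test_identical_counts_are_unchanged(self):
        idx = pd.Index(["g1", "g2"], name="gene_id")
        a = pd.DataFrame({"r1": [100, 300], "r2": [110, 280]}, index=idx)
        res = de_test(a, a.copy())
        assert (res["log2fc"] == 0).all()
        assert (res["status"] == "unchanged").all()

    def test_swap_symmetry(self, rng):
        a, b = _frames(rng, 100, 200.0, 500.0)
        r1 = de_test(a, b)
        r2 = de_test(b, a)
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(r1["pvalue"], r2["pvalue"], atol=1e-12)

    def test_power_on_planted_four_fold_change(self, rng):
        # 500 genes with a 4-fold increase planted in a null background
        # (most genes unchanged, as median-of-ratios normalization assumes)
        mu_a = np.full(2000, 500.0)
        mu_b = mu_a.copy()
        mu_b[:500] *= 4
        a, b = _frames(rng, 2000, mu_a, mu_b)
        res = de_test(a, b)
        assert (res["status"].iloc[:500] == "up").mean() >= 0.95

    def test_null_calibration(self, default_pipeline):
        m = default_pipeline.metrics
        assert m["de_tx_empirical_fdr"] <= 0.10
        assert m["de_tl_empirical_fdr"] <= 0.10

    def test_mismatched_gene_sets_error(self, rng):
        a, b = _frames(rng, 10, 100.0, 100.0)
        with pytest.raises(ValueError, match="gene sets"):
            de_test(a, b.iloc[:-1])

    def test_external_table_thresholding(self):
        tab = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [2.0, -0.5, -3.0],
                "pvalue": [1e-6, 1e-6, 0.5],
            }
        )
        res = de_results_from_table(tab)
        assert list(res["status"]) == ["up", "unchanged", "unchanged"]


class TestTEChange:
    def _one_gene(self, ribo_ck, ribo_s, rna_ck, rna_s):
        idx = pd.Index(["g"], name="gene_id")
        mk = lambda v: pd.DataFrame({"r1": [v]}, index=idx)
        return te_change_test(
            mk(rna_ck), mk(rna_s), mk(ribo_ck), mk(ribo_s),
            sf_rna=np.ones(2), sf_ribo=np.ones(2),
        )

    def test_proportional_table_is_null(self):
        res = self._one_gene(100, 50, 200, 100)
        assert res["delta_log2_te"].iloc[0] == pytest.approx(0.0)
        assert not res["significant"].iloc[0]

    def test_interaction_ratio_arithmetic(self):
        res = self._one_gene(100, 400, 100, 100)
        assert res["delta_log2_te"].iloc[0] == pytest.approx(2.0)

    def test_chi_square_matches_hand_computation(self):
        a, b, c, d = 100.0, 400.0, 100.0, 100.0  # ribo ck/s, rna ck/s
        res = self._one_gene(a, b, c, d)
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res["chi2"].iloc[0] == pytest.approx(hand)

    def test_zero_margin_excluded(self):
        res = self._one_gene(0, 0, 100, 100)
        assert bool(res["excluded"].iloc[0])

    def test_planted_te_effects_recovered(self, default_pipeline):
        m = default_pipeline.metrics
        assert m["te_change_recall"] >= 0.9
        assert m["te_change_empirical_fdr"] <= 0.10


class TestEnrichment:
    def test_exact_extreme_overlap(self):
        term_map = {f"g{i}": ["T"] for i in range(5)}
        bg = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich([f"g{i}" for i in range(5)], term_map, bg)
        assert res["pvalue"].iloc[0] == pytest.approx(1 / 252, rel=1e-9)

    def test_proportional_selection_not_enriched(self):
        term_map = {f"g{i}": ["T"] for i in range(5)}
        bg = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich(["g0", "g9"], term_map, bg)  # 1 of 2 in term
        assert res["pvalue"].iloc[0] >= 0.5

    def test_empty_selection_gives_empty_result(self):
        res = hypergeom_enrich([], {"g0": ["T"]}, ["g0", "g1"])
        assert res.empty

    def test_selection_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["x"], {}, ["g0"])
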