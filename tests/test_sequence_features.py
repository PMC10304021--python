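"""GC content, folding engines and feature-association statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from translatome.sequence_features import (
    NussinovEngine,
    accordance_feature_test,
    enumerate_structures_mfe,
    features_by_te_group,
    gc_content,
    nmfe,
    significance_letters,
)

_REVCOMP = str.maketrans("ACGT", "TGCA")


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5)])
    def test_basic(self, seq, expected):
        assert gc_content(seq) == expected

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            gc_content("ACXA")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_invariant_under_reverse_complement(self, seq):
        rc = seq.translate(_REVCOMP)[::-1]
        assert gc_content(seq) == pytest.approx(gc_content(rc))


class TestFolding:
    def test_unpairable_sequence_has_zero_mfe(self):
        assert nmfe("AAAAAAA") == 0.0

    def test_four_gc_pairs_hairpin(self):
        # GGGG....CCCC closes four G:C pairs around a loop of 4
        assert NussinovEngine().mfe("GGGGAAAACCCC") == -4.0
        assert nmfe("GGGGAAAACCCC") == pytest.approx(-4 / 12)

    def test_nmfe_is_never_positive(self, rng):
        eng = NussinovEngine()
        for _ in range(20):
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, size=30))
            assert nmfe(seq, eng) <= 0.0

    def test_matches_exhaustive_enumeration_short_sequences(self, rng):
        eng = NussinovEngine()
        mismatches = 0
        for _ in range(150):
            n = int(rng.integers(5, 15))
            seq = "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))
            if eng.mfe(seq) != enumerate_structures_mfe(seq):
                mismatches += 1
        assert mismatches == 0

    def test_min_loop_of_three_enforced(self):
        # hairpin with only 2 unpaired bases cannot close
        assert NussinovEngine().mfe("GAAC") == 0.0
        assert NussinovEngine().mfe("GAAAC") == -1.0


class TestTEGroupAssociation:
    def _features(self, values, gene_prefix):
        return pd.DataFrame(
            {
                "gene_id": [f"{gene_prefix}{i}" for i in range(len(values))],
                "region": "CDS",
                "length": 300,
                "gc": values,
                "nmfe": -0.1,
            }
        )

    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(0.5, 0.05, size=40)
        feats = pd.concat([self._features(vals, "a"), self._features(vals, "b")])
        groups = {f"a{i}": "G1" for i in range(40)} | {f"b{i}": "G4" for i in range(40)}
        _, tests = features_by_te_group(feats, groups)
        gc_row = tests[(tests["feature"] == "gc")].iloc[0]
        assert gc_row["pvalue"] > 0.99

    def test_separated_groups_highly_significant(self, rng):
        a = rng.normal(0, 1, size=50)
        b = rng.normal(5, 1, size=50)
        feats = pd.concat([self._features(a, "a"), self._features(b, "b")])
        groups = {f"a{i}": "G1" for i in range(50)} | {f"b{i}": "G4" for i in range(50)}
        _, tests = features_by_te_group(feats, groups)
        assert tests[tests["feature"] == "gc"]["pvalue"].iloc[0] < 1e-10

    def test_planted_gc_te_association_recovered(self, rng):
        # low-TE genes built GC-rich: the test must recover the direction
        low = rng.normal(0.65, 0.03, size=60)
        high = rng.normal(0.45, 0.03, size=60)
        feats = pd.concat([self._features(low, "lo"), self._features(high, "hi")])
        groups = {f"lo{i}": "G1" for i in range(60)} | {f"hi{i}": "G4" for i in range(60)}
        summary, tests = features_by_te_group(feats, groups)
        row = tests[tests["feature"] == "gc"].iloc[0]
        assert row["significant"] and row["t"] > 0  # G1 mean > G4 mean

    def test_tiny_group_excluded_from_tests(self):
        feats = self._features([0.5, 0.6, 0.7], "a")
        groups = {"a0": "G1", "a1": "G1", "a2": "G4"}  # G4 has a single member
        _, tests = features_by_te_group(feats, groups)
        assert tests.empty

    def test_letters_share_when_indistinct(self):
        letters = significance_letters(
            ["G1", "G2", "G3"],
            {("G1", "G2"): 0.8, ("G1", "G3"): 0.01, ("G2", "G3"): 0.03},
        )
        assert letters["G1"] == letters["G2"]
        assert set(letters["G3"]) != set(letters["G1"])


class TestAccordance:
    def _frame(self, values):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(values))],
                "region": "CDS",
                "length": 300,
                "gc": 0.5,
                "nmfe": values,
            }
        )

    def test_identical_samples_null(self):
        vals = list(np.linspace(-0.5, -0.1, 30))
        res = accordance_feature_test(self._frame(vals), self._frame(vals))
        row = res[res["feature"] == "nmfe"].iloc[0]
        assert row["D"] == 0.0 and row["pvalue"] == 1.0

    def test_fully_separated_samples(self):
        res = accordance_feature_test(
            self._frame(list(np.linspace(-1, -0.6, 20))),
            self._frame(list(np.linspace(-0.5, -0.1, 20))),
        )
        assert res[res["feature"] == "nmfe"]["D"].iloc[0] == 1.0

    def test_shifted_uniform_statistic(self, rng):
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(0.3, 1.3, 100)
        res = accordance_feature_test(self._frame(a), self._frame(b))
        assert res[res["feature"] == "nmfe"]["D"].iloc[0] == pytest.approx(0.3, abs=0.15)

    def test_p_consistent_with_permutation_oracle(self, rng):
        # a shift mild enough that 5000 shuffles resolve the p-value
        a = rng.uniform(0, 1, 100)
        b = rng.uniform(0.15, 1.15, 100)
        res = accordance_feature_test(self._frame(a), self._frame(b))
        row = res[res["feature"] == "nmfe"].iloc[0]
        pooled = np.concatenate([a, b])
        hits = 0
        n_perm = 5000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if stats.ks_2samp(pooled[:100], pooled[100:]).statistic >= row["D"]:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert 0.5 <= row["pvalue"] / p_perm <= 2.0

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            accordance_feature_test(self._frame([1.0]), self._frame([]))
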