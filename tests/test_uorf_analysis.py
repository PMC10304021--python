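"""uORF scanning, translated calling, Kozak matrices and feature tests."""

import numpy as np
import pytest
from scipy import stats

from translatome.uorf_analysis import (
    UORFRecord,
    call_translated,
    eligible_5utrs,
    kozak_matrix,
    morf_kozak_contexts,
    scan_uorfs,
    te_by_uorf_class,
    uorf_feature_tests,
    uorf_summary,
    validate_uorf,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_uorfs(seq: str) -> set[tuple[int, int]]:
    """Independent oracle: every (AUG index, end of first in-frame stop)."""
    s = seq.upper().replace("U", "T")
    out = set()
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(s):
            if s[j : j + 3] in STOPS:
                out.add((i, j + 3))
                break
            j += 3
    return out


class TestScan:
    def test_single_uorf_with_codons(self):
        found, _ = scan_uorfs("CCAUGAAAUGACC")
        assert [(u.start, u.end, u.length) for u in found] == [(2, 11, 9)]

    def test_no_aug_negative_control(self):
        found, overlapping = scan_uorfs("C" * 120)
        assert found == [] and overlapping == []

    def test_nested_uorfs_share_stop(self):
        found, _ = scan_uorfs("AUGAUGUAA")
        assert {(u.start, u.end) for u in found} == {(0, 9), (3, 9)}
        assert sorted(u.length for u in found) == [6, 9]

    def test_aug_without_stop_reported_as_overlapping(self):
        found, overlapping = scan_uorfs("CCATGAAACC")
        assert found == [] and overlapping == [2]

    def test_matches_brute_force_on_random_utrs(self, rng):
        mismatches = 0
        for _ in range(2000):
            n = int(rng.integers(60, 461))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            found, _ = scan_uorfs(seq)
            if {(u.start, u.end) for u in found} != brute_force_uorfs(seq):
                mismatches += 1
            for u in found:
                validate_uorf(u, seq)
        assert mismatches == 0


class TestEligibility:
    def test_boundary_lengths_inclusive(self, small_genome):
        _, models, genome, _ = small_genome
        # synthetic UTRs are all in range; spoof models at the borders
        import copy

        lengths = []
        for L in (59, 60, 460, 461):
            m = copy.deepcopy(models[0])
            m.utr5_span = (0, L)
            m.cds_span = (L, m.cds_span[1])
            lengths.append(m)
        kept = [m.utr5_length for m, _ in eligible_5utrs(lengths, genome)]
        assert kept == [60, 460]

    def test_transcript_without_utr_excluded(self, small_genome):
        _, models, genome, _ = small_genome
        import copy

        m = copy.deepcopy(models[0])
        m.utr5_span = (0, 0)
        m.cds_span = (0, m.cds_span[1])
        assert eligible_5utrs([m], genome) == []


class TestTranslatedCalls:
    def _uorf(self, start=0, end=30):
        return UORFRecord("g", "t", 100, start, end)

    def test_inclusive_fpkm_threshold(self):
        # 3 reads, length 30, total 1e8 -> fpkm exactly 1.0 -> translated
        (rec,) = call_translated([self._uorf()], {"t": [0, 10, 29]}, 10**8)
        assert rec.fpkm == pytest.approx(1.0) and rec.translated

    def test_just_below_threshold_untranslated(self):
        (rec,) = call_translated([self._uorf()], {"t": [0, 10, 29]}, 101_010_102)
        assert rec.fpkm < 1.0 and not rec.translated

    def test_reads_outside_span_ignored(self):
        (rec,) = call_translated([self._uorf(10, 40)], {"t": [0, 5, 40, 50]}, 1000)
        assert rec.fpkm == 0.0

    def test_planted_occupancy_recovered_exactly(self, default_pipeline):
        m = default_pipeline.metrics
        assert m["uorf_translated_recall"] == 1.0
        assert m["uorf_translated_false_positives"] == 0


class TestSummary:
    def test_published_scale_mean_per_gene(self):
        # 28,490 uORFs over 6,463 genes -> 4.4 per gene
        uorfs = [
            UORFRecord(f"g{i % 6463}", f"t{i % 6463}", 100, 0, 30)
            for i in range(28490)
        ]
        s = uorf_summary(uorfs)
        assert round(s["mean_per_gene"], 1) == 4.4
        assert s["mean_per_gene"] * s["n_genes"] == s["n_uorfs"]

    def test_single_uorf(self):
        s = uorf_summary([UORFRecord("g", "t", 100, 0, 9)])
        assert (s["n_uorfs"], s["n_genes"], s["mean_per_gene"], s["median_length"]) == (1, 1, 1.0, 9)

    def test_median_length(self):
        lengths = [9, 12, 300]
        uorfs = [UORFRecord("g", "t", 400, 0, L) for L in lengths]
        assert uorf_summary(uorfs)["median_length"] == 12


class TestKozak:
    def test_fixed_minus_three(self):
        pfm = kozak_matrix(["AAAAAAAUGG", "ACGAAAAUGG", "AGCAAAAUGG"], up=6, down=4)
        assert pfm.freqs.loc["A", -3] == 1.0
        np.testing.assert_allclose(pfm.freqs[-3].sum(), 1.0)

    def test_uniform_contexts_near_quarter(self, rng):
        ctxs = ["".join("ACGU"[i] for i in rng.integers(0, 4, size=10)) for _ in range(4000)]
        pfm = kozak_matrix(ctxs)
        assert np.all(np.abs(pfm.freqs.to_numpy() - 0.25) < 0.02)

    def test_short_contexts_skipped(self):
        pfm = kozak_matrix(["AAAAAAAUGG", None, "AUG"])
        assert pfm.n_sequences == 1

    def test_planted_morf_bias_recovered(self, small_genome):
        _, models, genome, _ = small_genome
        pfm = kozak_matrix(morf_kozak_contexts(models, genome))
        ag_minus3 = pfm.freqs.loc["A", -3] + pfm.freqs.loc["G", -3]
        assert ag_minus3 > 0.7  # generator plants A/G at -3
        assert pfm.freqs.loc["G", 4] > 0.5  # and G at +4
        # positions -2/-1 are AUG-free background, so A is depleted before
        # T..G-completing contexts but no single base dominates
        assert pfm.freqs.loc["G", -6] < 0.5


class TestTEByClass:
    def test_null_calibration(self, rng):
        rejections = 0
        for _ in range(200):
            te = {f"g{i}": float(x) for i, x in enumerate(rng.normal(size=120))}
            uorfs = []
            for i in range(120):
                k = i % 3  # 0, 1, 2 translated uORFs
                for j in range(max(k, 1)):
                    uorfs.append(
                        UORFRecord(f"g{i}", f"t{i}", 100, j * 12, j * 12 + 9,
                                   )
                    )
                    uorfs[-1].translated = j < k
            _, tests = te_by_uorf_class(te, uorfs)
            if (tests["pvalue"].dropna() < 0.05).any():
                rejections += 1
        # three tests per replicate at alpha 0.05: family-wise ~14% expected
        assert 0.02 <= rejections / 200 <= 0.30

    def test_planted_te_shift_detected(self, rng):
        te = {}
        uorfs = []
        for i in range(600):
            gid = f"g{i}"
            multi = i % 3 == 2
            shift = -0.5 if multi else 0.0
            te[gid] = float(rng.normal(shift, 0.5))
            k = i % 3
            for j in range(max(k, 1)):
                u = UORFRecord(gid, f"t{i}", 100, j * 12, j * 12 + 9)
                u.translated = j < k
                uorfs.append(u)
        _, tests = te_by_uorf_class(te, uorfs)
        row = tests[(tests["group1"] == "none") & (tests["group2"] == "multiple")].iloc[0]
        assert row["pvalue"] < 0.01

    def test_degenerate_group_skipped(self):
        te = {"g0": 1.0, "g1": 0.5}
        u0 = UORFRecord("g0", "t0", 100, 0, 9)
        u0.translated = False
        u1 = UORFRecord("g1", "t1", 100, 0, 9)
        u1.translated = True
        _, tests = te_by_uorf_class(te, [u0, u1])
        assert tests["skipped"].all()


class TestFeatureTests:
    def _records(self, lengths, translated):
        out = []
        for i, L in enumerate(lengths):
            u = UORFRecord("g%d" % i, "t%d" % i, 300, 0, int(L) // 3 * 3 or 6)
            u.translated = translated
            u.nmfe = -0.2
            out.append(u)
        return out

    def test_identical_sets_null(self, rng):
        lengths = rng.integers(30, 90, size=40) * 3 // 3 * 3
        res = uorf_feature_tests(self._records(lengths, True), self._records(lengths, False))
        row = res[res["feature"] == "uorf_length"].iloc[0]
        assert row["pvalue"] > 0.99

    def test_large_length_difference_extreme_p(self, rng):
        a = rng.normal(120, 20, size=500)
        b = rng.normal(80, 20, size=500)
        res = uorf_feature_tests(self._records(a, True), self._records(b, False))
        assert res[res["feature"] == "uorf_length"]["pvalue"].iloc[0] < 1e-60

    def test_null_nmfe_calibrated(self, rng):
        rejections = 0
        for _ in range(200):
            a = self._records(rng.integers(30, 90, size=30) * 1.0, True)
            b = self._records(rng.integers(30, 90, size=30) * 1.0, False)
            for u in a + b:
                u.nmfe = float(rng.normal(-0.3, 0.05))
            res = uorf_feature_tests(a, b)
            if res[res["feature"] == "nmfe"]["pvalue"].iloc[0] < 0.05:
                rejections += 1
        assert 0.005 <= rejections / 200 <= 0.12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            uorf_feature_tests([], self._records([60], False))
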