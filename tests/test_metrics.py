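"""Segmentation scores, classification metrics and the bootstrap test."""

import numpy as np
import pytest

from rna3dseg import (ConfusionCounts, DomainDecomposition, ScoreConfig,
                      accuracy, best_match_iou, bootstrap_mcc_difference,
                      classify_decomposition, confusion_from_pairs, csd, dbd,
                      iou, mcc, ndo)

from conftest import decomposition
from oracles import csd_brute, dbd_brute, iou_brute, ndo_brute, random_label_array


def dd(labels):
    return DomainDecomposition.from_label_array(labels)


def lab(*spec):
    """Label array from (value, length) pairs; value None = linker."""
    out = []
    for value, length in spec:
        out.extend([value] * length)
    return out


class TestNDO:
    def test_identity_is_one(self):
        d = dd(lab(("A", 50), (None, 20), ("B", 60)))
        assert ndo(d, d) == pytest.approx(1.0)

    def test_undersegmentation_worked_example(self):
        truth = decomposition(100, [("D1", [(1, 50)]), ("D2", [(51, 100)])])
        merged = decomposition(100, [("D1", [(1, 100)])])
        assert ndo(merged, truth) == pytest.approx(0.5)

    def test_can_be_negative(self):
        # a computed domain lying mostly on the true linker loses more
        # overlap than it gains, driving the score below zero
        truth = dd(lab(("A", 30), (None, 70)))
        computed = dd(lab((None, 20), ("A", 80)))
        assert ndo(computed, truth) < 0

    def test_not_symmetric(self):
        a = dd(lab(("A", 30), (None, 40), ("B", 30)))
        b = dd(lab(("A", 70), ("B", 30)))
        assert ndo(a, b) != pytest.approx(ndo(b, a))

    def test_rejects_zero_domain_truth(self):
        with pytest.raises(ValueError):
            ndo(dd(lab(("A", 50))), dd(lab((None, 50))))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            ndo(dd(lab(("A", 50))), dd(lab(("A", 60))))


class TestDBD:
    def test_identity_two_domains(self):
        d = dd(lab(("A", 50), ("B", 50)))
        assert dbd(d, d) == pytest.approx(1.0)

    def test_linker_boundary_worked_example(self):
        # the true boundary is the whole linker 61-70; a computed point
        # boundary at 75 is 5 away: S = 20 - 5, DBD = 15/20
        truth = dd(lab(("A", 60), (None, 10), ("B", 130)))
        computed = dd(lab(("A", 75), ("B", 125)))
        assert dbd(computed, truth) == pytest.approx(0.75)

    def test_single_vs_multi_is_zero(self):
        truth = dd(lab(("A", 50), ("B", 50)))
        single = dd(lab(("A", 100)))
        assert dbd(single, truth) == 0.0

    def test_both_single_is_one(self):
        a = dd(lab(("A", 100)))
        b = dd(lab(("B", 90), (None, 10)))
        assert dbd(a, b) == 1.0

    def test_boundary_inside_linker_scores_full(self):
        truth = dd(lab(("A", 60), (None, 10), ("B", 130)))
        computed = dd(lab(("A", 65), ("B", 135)))
        assert dbd(computed, truth) == pytest.approx(1.0)

    def test_terminal_linker_is_not_a_boundary(self):
        a = dd(lab(("A", 80), (None, 20)))
        b = dd(lab(("A", 100)))
        assert dbd(a, b) == 1.0  # no boundaries on either side


class TestCSD:
    def test_identity_single_domain(self):
        d = dd(lab(("A", 100)))
        assert csd(d, d) == pytest.approx(1.0)

    def test_shrunken_domain_worked_example(self):
        # d5=10, d3=5 -> S = (40-15)/2 = 12.5 -> 12.5/20
        truth = decomposition(100, [("D1", [(1, 100)])])
        computed = decomposition(100, [("D1", [(11, 95)])],
                                 linkers=[(1, 10), (96, 100)])
        assert csd(computed, truth) == pytest.approx(0.625)

    def test_oversegmentation_scores_zero(self):
        truth = decomposition(100, [("D1", [(1, 100)])])
        split = decomposition(100, [("D1", [(1, 40)]), ("D2", [(41, 100)])])
        assert csd(split, truth) == pytest.approx(0.0)

    def test_interior_linker_extension_lowers_distance(self):
        # computed domain ends at 60; the true domain continues to 100 but
        # its 3' flank in the computed decomposition is an interior linker
        # 61-100, so the computed end may extend across it
        truth = dd(lab(("A", 100), ("B", 100)))
        computed = dd(lab(("A", 60), (None, 40), ("B", 100)))
        # without extension d3 = 40 for domain A; with extension d3 = 0
        assert csd(computed, truth) == pytest.approx(1.0)

    def test_rejects_zero_domains(self):
        with pytest.raises(ValueError):
            csd(dd(lab((None, 50))), dd(lab(("A", 50))))


class TestIoU:
    def test_identical(self):
        assert iou(range(1, 51), range(1, 51)) == 1.0

    def test_disjoint(self):
        assert iou(range(1, 11), range(11, 21)) == 0.0

    def test_partial_overlap(self):
        assert iou(range(1, 81), range(21, 101)) == pytest.approx(0.6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iou([], range(3))

    def test_best_match_picks_largest_intersection(self):
        d = dd(lab(("A", 50), ("B", 50)))
        # query hits B with 40 residues, A with 10
        assert best_match_iou(range(41, 91), d) == pytest.approx(40 / 60)


class TestClassification:
    def test_single_with_terminal_linker(self):
        assert classify_decomposition(dd(lab(("A", 80), (None, 20)))) == "single"

    def test_multi(self):
        assert classify_decomposition(dd(lab(("A", 50), ("B", 50)))) == "multi"

    def test_zero_domains_single(self):
        assert classify_decomposition(dd(lab((None, 50)))) == "single"

    # Acc values recomputable from printed benchmark counts
    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(tp=20, tn=60, fp=22, fn=30), 60.61),   # 80 of 132
        (ConfusionCounts(tp=10, tn=12, fp=4, fn=0), 84.62),     # 22 of 26
    ])
    def test_accuracy_examples(self, counts, expected):
        assert accuracy(counts) == pytest.approx(expected, abs=0.005)

    def test_accuracy_zero_correct(self):
        assert accuracy(ConfusionCounts(0, 0, 3, 4)) == 0.0

    def test_accuracy_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_benchmark_confusion_matrix(self):
        assert mcc(ConfusionCounts(tp=10, tn=12, fp=4, fn=0)) \
            == pytest.approx(0.732, abs=5e-4)

    def test_mcc_perfect(self):
        assert mcc(ConfusionCounts(10, 10, 0, 0)) == pytest.approx(1.0)

    def test_mcc_symmetric_counts_zero(self):
        assert mcc(ConfusionCounts(5, 5, 5, 5)) == pytest.approx(0.0)

    def test_mcc_degenerate_marginal_zero(self):
        assert mcc(ConfusionCounts(0, 10, 0, 5)) == 0.0

    def test_confusion_from_pairs(self):
        pairs = [("multi", "multi"), ("multi", "single"),
                 ("single", "single"), ("single", "multi")]
        c = confusion_from_pairs(pairs)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)


class TestBootstrap:
    def test_identical_sets_no_difference(self):
        pairs = [("multi", "multi")] * 12 + [("single", "single")] * 10 \
            + [("multi", "single")] * 4 + [("single", "multi")] * 3
        observed, p = bootstrap_mcc_difference(pairs, list(pairs),
                                               n_boot=4000, seed=7)
        assert observed == 0.0
        assert 0.35 < p < 0.65

    def test_deterministic_given_seed(self):
        a = [("multi", "multi")] * 10 + [("single", "single")] * 8 \
            + [("single", "multi")] * 4
        b = [("multi", "single")] * 6 + [("single", "single")] * 12 \
            + [("multi", "multi")] * 5
        r1 = bootstrap_mcc_difference(a, b, n_boot=1000, seed=3)
        r2 = bootstrap_mcc_difference(a, b, n_boot=1000, seed=3)
        assert r1 == r2

    def test_p_counts_exceedances_of_observed(self):
        # perfect vs noisy: every replicate difference scatters around the
        # large observed gap, so the exceedance fraction stays moderate
        rng = np.random.default_rng(0)
        perfect = [("multi", "multi")] * 15 + [("single", "single")] * 15
        noisy = [("multi" if rng.random() < 0.5 else "single",
                  "multi" if rng.random() < 0.5 else "single")
                 for _ in range(30)]
        observed, p = bootstrap_mcc_difference(perfect, noisy,
                                               n_boot=2000, seed=1)
        assert observed > 0.5
        assert 0.0 <= p <= 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mcc_difference([], [("multi", "multi")])


class TestOracleEquivalence:
    """Implementation vs independent brute-force formulas on random
    decompositions of short chains."""

    def _random_pair(self, rng):
        while True:
            length = int(rng.integers(20, 61))
            a = random_label_array(rng, length)
            b = random_label_array(rng, length)
            if any(v is not None for v in a) and any(v is not None for v in b):
                return a, b

    def test_ndo_dbd_csd_iou_match_brute_force(self, rng):
        for _ in range(250):
            a, b = self._random_pair(rng)
            da, db_ = dd(a), dd(b)
            assert ndo(da, db_) == pytest.approx(ndo_brute(a, b), abs=1e-9)
            assert dbd(da, db_) == pytest.approx(dbd_brute(a, b), abs=1e-9)
            assert csd(da, db_) == pytest.approx(csd_brute(a, b), abs=1e-9)
            ra = da.domains[0].residues()
            rb = db_.domains[0].residues()
            assert iou(ra, rb) == pytest.approx(iou_brute(ra, rb), abs=1e-9)

    def test_ranges(self, rng):
        for _ in range(100):
            a, b = self._random_pair(rng)
            da, db_ = dd(a), dd(b)
            assert ndo(da, db_) <= 1.0 + 1e-12
            assert 0.0 <= dbd(da, db_) <= 1.0
            assert 0.0 <= csd(da, db_) <= 1.0

    def test_label_invariance(self, rng):
        for _ in range(50):
            a, b = self._random_pair(rng)
            da, db_ = dd(a), dd(b)
            renamed = da.relabeled({d.label: f"X{i}"
                                    for i, d in enumerate(da.domains)})
            assert ndo(renamed, db_) == pytest.approx(ndo(da, db_))
            assert dbd(renamed, db_) == pytest.approx(dbd(da, db_))
            assert csd(renamed, db_) == pytest.approx(csd(da, db_))

    def test_csd_symmetry_on_spaced_decompositions(self, rng):
        # symmetry needs domains spaced farther apart than the score budget
        # 2T (min run 45 > 40) so every domain has at most one scoring
        # partner; at equal counts CSD sums the computed side by convention
        for _ in range(60):
            length = int(rng.integers(150, 400))
            a = random_label_array(rng, length, min_seg=45)
            b = random_label_array(rng, length, min_seg=45)
            if not (any(v is not None for v in a) and any(v is not None for v in b)):
                continue
            da, db_ = dd(a), dd(b)
            assert csd(da, db_) == pytest.approx(csd(db_, da), abs=1e-12)

    def test_dbd_symmetry_on_point_boundaries(self, rng):
        # with only point boundaries spaced beyond 2T, closest partners are
        # mutual, so the score is direction-independent; wide linker
        # intervals can legitimately break this (both their ends may
        # approach different true boundaries)
        for _ in range(60):
            def domains_only(n_dom):
                out = []
                for i in range(n_dom):
                    out.extend(["ABCDE"[i]] * int(rng.integers(45, 90)))
                return out
            a = domains_only(int(rng.integers(1, 5)))
            b = domains_only(int(rng.integers(1, 5)))
            L = max(len(a), len(b))
            a += [None] * (L - len(a))   # terminal linker padding only
            b += [None] * (L - len(b))
            da, db_ = dd(a), dd(b)
            assert dbd(da, db_) == pytest.approx(dbd(db_, da), abs=1e-12)
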