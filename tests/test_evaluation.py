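"""Evaluation protocols: matching, categorisation, anchors, Hi-C, thinning."""

import numpy as np
import pytest

from loopforest.core import GenomicInterval, LoopRecord
from loopforest.evaluation import (
    SupportCategory,
    categorize_predictions,
    evaluate_anchors,
    hic_support_test,
    match_loops,
    scan_genome,
    thin_pet_counts,
)
from loopforest.io import ContactMatrix


def _loop(s1, s2, pet=None, fdr=None, prob=None, chrom="chr1"):
    return LoopRecord(
        GenomicInterval(chrom, max(0, s1 - 500), s1 + 500),
        GenomicInterval(chrom, s2 - 500, s2 + 500),
        pet_count=pet,
        fdr=fdr,
        probability=prob,
        summit1=s1,
        summit2=s2,
    )


class TestMatchLoops:
    def test_identical_and_shifted(self):
        q = _loop(100_000, 300_000)
        assert match_loops(q, [_loop(100_000, 300_000, pet=2)]) is not None
        assert match_loops(q, [_loop(150_000, 350_000, pet=2)]) is None

    def test_best_match_by_pet(self):
        q = _loop(100_000, 300_000)
        refs = [_loop(100_100, 300_100, pet=1), _loop(99_900, 299_900, pet=4)]
        assert match_loops(q, refs).pet_count == 4


class TestCategorize:
    def test_category_rules(self):
        calls = [
            _loop(100_000, 300_000, pet=3, fdr=0.01),
            _loop(500_000, 700_000, pet=1, fdr=0.8),
        ]
        preds = [_loop(100_000, 300_000), _loop(500_000, 700_000), _loop(2_000_000, 2_300_000)]
        cats, fractions = categorize_predictions(preds, calls)
        assert cats == [
            SupportCategory.SIGNIFICANT,
            SupportCategory.WITH_EVIDENCE,
            SupportCategory.NO_SUPPORT,
        ]
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_partition_sums_to_total(self, small_fixture):
        preds = [
            _loop(int(lp.summit1), int(lp.summit2), chrom=lp.chrom)
            for lp in small_fixture.loop_calls[::3]
        ]
        cats, _ = categorize_predictions(preds, small_fixture.loop_calls)
        assert len(cats) == len(preds)


class TestAnchors:
    def test_toy_curve_matches_hand_enumeration(self):
        # 3 positive loops + 2 negatives over 6 distinct anchor regions
        pos = [_loop(100_000, 300_000), _loop(500_000, 700_000)]
        neg = [_loop(900_000, 1_100_000)]
        preds = [
            _loop(100_000, 300_000, prob=0.9),
            _loop(900_000, 1_100_000, prob=0.6),
        ]
        summary, curve = evaluate_anchors(preds, pos, neg)
        # anchor scores: pos anchors {0.9, 0.9, 0, 0}; neg anchors {0.6, 0.6}
        # threshold 0.9: predict 2 anchors, both positive -> P=1, R=2/4
        row = curve[curve["threshold"] == 0.9].iloc[0]
        assert row["precision"] == 1.0 and row["recall"] == 0.5
        # threshold 0.6: predict 4 anchors, 2 positive -> P=0.5, R=0.5
        row = curve[curve["threshold"] == 0.6].iloc[0]
        assert row["precision"] == 0.5 and row["recall"] == 0.5

    def test_all_predicted_gives_full_recall(self):
        pos = [_loop(100_000, 300_000)]
        neg = [_loop(900_000, 1_100_000)]
        preds = [_loop(100_000, 300_000, prob=0.7), _loop(900_000, 1_100_000, prob=0.7)]
        _, curve = evaluate_anchors(preds, pos, neg)
        assert curve.iloc[0]["recall"] == 1.0


class TestScanGenome:
    def test_candidate_combinatorics_and_cutoff_monotonicity(self, default_model, default_training):
        # take a cluster of sites within 1 Mb of one another on one chromosome
        sites = [s for s in default_training["sites"] if s.chrom == "chr1"][:12]
        span = sites[-1].summit - sites[0].summit
        n_feasible = sum(
            1
            for i in range(len(sites))
            for j in range(i + 1, len(sites))
            if 10_000 <= sites[j].summit - sites[i].summit <= 1_000_000
        )
        preds_all = scan_genome(
            default_model, sites, default_training["bundle"], p_cutoff=0.0
        )
        assert len(preds_all) == n_feasible
        counts = [
            len(
                scan_genome(
                    default_model, sites, default_training["bundle"], p_cutoff=c
                )
            )
            for c in (0.0, 0.3, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestHiC:
    @staticmethod
    def _null_matrix(n_bins=400, res=10_000, seed=0):
        rng = np.random.default_rng(seed)
        entries = {}
        for off in range(0, 101):
            lam = 40.0 / (1.0 + off)
            counts = rng.poisson(lam, size=n_bins - off)
            for i in np.flatnonzero(counts):
                entries[(int(i), int(i) + off)] = float(counts[i])
        kr = rng.lognormal(0, 0.05, size=n_bins)
        return ContactMatrix(res, entries, kr)

    def test_control_lengths_match_exactly(self):
        mat = self._null_matrix()
        loops = [_loop(100_000 + 37_000 * k, 100_000 + 37_000 * k + 20_000 + 10_000 * (k % 5)) for k in range(20)]
        out = hic_support_test(
            loops, {"chr1": mat}, {"chr1": 4_000_000}, seed=1, return_controls=True
        )
        _, _, _, controls = out
        assert sorted(c.length for c in controls) == sorted(l.length for l in loops)

    def test_planted_enrichment_detected(self):
        mat = self._null_matrix(seed=3)
        rng = np.random.default_rng(4)
        loops = []
        for k in range(30):
            s1 = int(rng.integers(50_000, 2_500_000))
            s2 = s1 + int(rng.integers(20_000, 900_000))
            loops.append(_loop(s1, s2))
            i, j = s1 // 10_000, s2 // 10_000
            off = j - i
            mat.entries[(i, j)] = float(rng.poisson(5 * 40.0 / (1.0 + off)) + 1)
        _, _, p = hic_support_test(loops, {"chr1": mat}, {"chr1": 4_000_000}, seed=5)
        assert p < 0.01

    def test_seed_reproducible(self):
        mat = self._null_matrix(seed=6)
        loops = [_loop(100_000 + 40_000 * k, 200_000 + 45_000 * k) for k in range(15)]
        r1 = hic_support_test(loops, {"chr1": mat}, {"chr1": 4_000_000}, seed=9)
        r2 = hic_support_test(loops, {"chr1": mat}, {"chr1": 4_000_000}, seed=9)
        assert np.array_equal(r1[1], r2[1]) and r1[2] == r2[2]


class TestThinning:
    def test_identity_at_fraction_one(self):
        calls = [_loop(100_000, 300_000, pet=7, fdr=0.01)]
        assert thin_pet_counts(calls, 1.0, seed=0)[0].pet_count == 7

    def test_zero_count_loops_dropped(self):
        calls = [_loop(100_000, 300_000, pet=1, fdr=0.01) for _ in range(200)]
        thinned = thin_pet_counts(calls, 0.15, seed=0)
        assert 0 < len(thinned) < len(calls)
        assert all(lp.pet_count >= 1 for lp in thinned)

    def test_feeds_categorisation(self, small_fixture):
        thinned = thin_pet_counts(small_fixture.loop_calls, 0.15, seed=2)
        preds = [
            _loop(int(lp.summit1), int(lp.summit2), chrom=lp.chrom)
            for lp in small_fixture.truth[:20]
        ]
        cats, fractions = categorize_predictions(preds, thinned)
        assert len(cats) == 20
        assert sum(fractions.values()) == pytest.approx(1.0)
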