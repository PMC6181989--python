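"""Feature schema: closed forms, orientation codes, column contracts."""

import numpy as np
import pandas as pd
import pytest

from loopforest.core import GenomicInterval, LoopRecord
from loopforest.features import (
    DataBundle,
    FeatureConfig,
    LoopFeaturizer,
    expression_feature,
    featurize,
    flanking_features,
    in_between_feature,
    local_features,
    motif_orientation_code,
)
from loopforest.io import ExpressionRecord, ReadSet, SignalTrack
from loopforest.sites import BindingSite, MotifOccurrence


def _site(chrom, summit, strand=None, score=10.0, intensity=1.0):
    motif = (
        MotifOccurrence(GenomicInterval(chrom, summit - 9, summit + 10, strand), score)
        if strand
        else None
    )
    return BindingSite(
        chrom, summit, GenomicInterval(chrom, max(0, summit - 500), summit + 500), intensity, motif
    )


def _loop(s1, s2, chrom="chr1"):
    return LoopRecord(
        GenomicInterval(chrom, s1 - 500, s1 + 500),
        GenomicInterval(chrom, s2 - 500, s2 + 500),
        summit1=s1,
        summit2=s2,
    )


def _track(intervals, lib=1_000_000, name="t"):
    return SignalTrack(name, ReadSet([GenomicInterval(*iv) for iv in intervals], lib), [])


ORIENTATION_CASES = [
    (None, None, 0),
    ("+", None, 1),
    ("-", None, 1),
    (None, "+", 1),
    (None, "-", 1),
    ("+", "-", 4),  # convergent
    ("-", "+", 2),  # divergent
    ("+", "+", 3),  # tandem
    ("-", "-", 3),  # tandem
]


@pytest.mark.parametrize("left,right,code", ORIENTATION_CASES)
def test_motif_orientation_all_combinations(left, right, code):
    a1 = _site("chr1", 10_000, left)
    a2 = _site("chr1", 60_000, right)
    assert motif_orientation_code(a1, a2) == code


class TestClosedForms:
    def test_local_avg_std(self):
        # anchor windows are summit +- 2 kb (4 kb): RPKM = n/4 at 1 M library
        reads = [("chr1", 10_000 + i, 10_050 + i) for i in range(8)]  # anchor1: 8 -> 2.0
        reads += [("chr1", 110_000 + i, 110_050 + i) for i in range(24)]  # anchor2: 24 -> 6.0
        track = _track(reads)
        loop = _loop(10_000, 110_000)
        avg, std = local_features(loop, track)
        assert (avg, std) == (pytest.approx(4.0), pytest.approx(2.0))
        # anchor swap leaves the pair statistics unchanged
        swapped = _loop(110_000, 10_000)
        assert local_features(swapped, track) == (avg, std)

    def test_in_between(self):
        # 30 reads over a 100 kb inter-summit span, 1 M library -> 0.3
        track = _track([("chr1", 20_000 + 3_000 * i, 20_100 + 3_000 * i) for i in range(30)])
        assert in_between_feature(_loop(15_000, 115_000), track) == pytest.approx(0.3)
        assert in_between_feature(_loop(500_000, 600_000), track) == 0.0

    def test_flanking(self):
        # nearest outside site 10 kb upstream with 5 reads in between -> 0.5
        sites = [_site("chr1", 40_000), _site("chr1", 50_000), _site("chr1", 150_000), _site("chr1", 180_000)]
        track = _track([("chr1", 42_000 + 1_000 * i, 42_050 + 1_000 * i) for i in range(5)])
        loop = _loop(50_000, 150_000)
        left, right = flanking_features(loop, track, sites)
        assert left == pytest.approx(5 / (10 * 1))
        assert right == 0.0  # no reads in [150k, 180k)

    def test_flanking_fallback_at_chromosome_edge(self):
        sites = [_site("chr1", 50_000), _site("chr1", 150_000)]  # anchors are the only sites
        track = _track([("chr1", 45_000, 45_100)])
        left, right = flanking_features(_loop(50_000, 150_000), track, sites, fallback=10_000)
        assert left == pytest.approx(1 / (10 * 1))
        assert right >= 0.0

    def test_expression(self):
        genes = [
            ExpressionRecord("g1", GenomicInterval("chr1", 30_000, 30_001, "+"), 2.0),
            ExpressionRecord("g2", GenomicInterval("chr1", 60_000, 60_001, "-"), 4.0),
            ExpressionRecord("out", GenomicInterval("chr1", 200_000, 200_001, "+"), 50.0),
        ]
        assert expression_feature(_loop(10_000, 110_000), genes) == pytest.approx(3.0)
        assert expression_feature(_loop(400_000, 500_000), genes) == 0.0

    def test_promoter_straddling_anchor_excluded(self):
        # promoter = TSS +- 2 kb; TSS at summit1 + 1 kb straddles the summit
        genes = [ExpressionRecord("g", GenomicInterval("chr1", 11_000, 11_001, "+"), 9.0)]
        assert expression_feature(_loop(10_000, 110_000), genes) == 0.0


class TestFeaturizer:
    @staticmethod
    def _bundle(tracks=("CTCF", "RAD21", "DNase")):
        sites = [_site("chr1", 50_000, "+"), _site("chr1", 150_000, "-")]
        return DataBundle(
            tracks={n: _track([("chr1", 49_000, 49_100)], name=n) for n in tracks},
            ctcf_sites=sites,
            conservation=None,
            expression=[],
        )

    def test_canonical_config_has_77_columns(self, default_training):
        assert default_training["X"].shape[1] == 77
        assert list(default_training["X"].columns) == FeatureConfig().feature_names()

    def test_three_track_config_has_22_columns(self):
        cfg = FeatureConfig(tracks=("CTCF", "RAD21", "DNase"))
        X = featurize([_loop(50_000, 150_000)], self._bundle(), cfg)
        assert X.shape[1] == 22

    def test_missing_track_named_in_error(self):
        cfg = FeatureConfig(tracks=("CTCF", "RAD21", "DNase", "H3K27ac"))
        with pytest.raises(ValueError, match="H3K27ac"):
            LoopFeaturizer(self._bundle(), cfg).fit()

    def test_identical_loops_identical_rows(self):
        cfg = FeatureConfig(tracks=("CTCF", "RAD21", "DNase"))
        X = featurize([_loop(50_000, 150_000)] * 3, self._bundle(), cfg)
        assert (X.nunique() == 1).all()

    def test_rows_finite_and_deterministic(self, default_training):
        X = default_training["X"]
        assert np.isfinite(X.to_numpy()).all()
        again = featurize(
            default_training["positives"][:10], default_training["bundle"]
        )
        pd.testing.assert_frame_equal(X.iloc[:10].reset_index(drop=True), again)

    def test_orientation_feature_uses_normalised_left_right(self):
        cfg = FeatureConfig(tracks=("CTCF", "RAD21", "DNase"))
        bundle = self._bundle()
        # anchors given right-to-left: record normalises, so (+,-) stays convergent
        loop = LoopRecord(
            GenomicInterval("chr1", 149_500, 150_500),
            GenomicInterval("chr1", 49_500, 50_500),
            summit1=150_000,
            summit2=50_000,
        )
        X = featurize([loop], bundle, cfg)
        assert X.loc[0, "motif_orientation"] == 4
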