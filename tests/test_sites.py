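"""Binding-site construction, motif attachment, cross-cell repertoires."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopforest.core import GenomicInterval
from loopforest.io import PeakRecord, ReadSet, SignalTrack
from loopforest.sites import (
    BindingSite,
    MotifOccurrence,
    attach_best_motif,
    attach_motifs,
    build_sites,
    classify_sites_across_celltypes,
    relative_fluctuation,
)


def _site(chrom, summit, intensity=1.0, strand=None, score=10.0):
    motif = (
        MotifOccurrence(GenomicInterval(chrom, summit - 9, summit + 10, strand), score)
        if strand
        else None
    )
    return BindingSite(
        chrom, summit, GenomicInterval(chrom, max(0, summit - 500), summit + 500), intensity, motif
    )


class TestBuildSites:
    def test_extent_and_summit(self):
        peaks = [PeakRecord(GenomicInterval("chr1", 10_000, 11_000), 500)]
        (site,) = build_sites(peaks)
        assert site.summit == 10_500
        assert (site.extent.start, site.extent.end) == (10_000, 11_000)

    def test_sorted_regardless_of_input_order(self):
        peaks = [
            PeakRecord(GenomicInterval("chr1", 50_000, 51_000), 500),
            PeakRecord(GenomicInterval("chr1", 10_000, 11_000), 500),
        ]
        sites = build_sites(peaks)
        assert [s.summit for s in sites] == [10_500, 50_500]

    def test_intensity_rpkm(self):
        # 20 reads in the +-2 kb window, 2 M library -> 20 / (4 x 2) = 2.5
        reads = ReadSet(
            [GenomicInterval("chr1", 10_400 + i, 10_500 + i) for i in range(20)],
            2_000_000,
        )
        track = SignalTrack("CTCF", reads, [])
        peaks = [PeakRecord(GenomicInterval("chr1", 10_000, 11_000), 500)]
        (site,) = build_sites(peaks, track)
        assert site.intensity == pytest.approx(2.5)

    def test_summit_outside_peak_errors(self):
        with pytest.raises(ValueError, match="summit"):
            build_sites([PeakRecord(GenomicInterval("chr1", 100, 200), 500)])


class TestAttachMotif:
    def test_argmax_and_no_occurrence(self):
        site = _site("chr1", 5_000)
        motifs = [
            MotifOccurrence(GenomicInterval("chr1", 4_500, 4_519, "+"), 12.3),
            MotifOccurrence(GenomicInterval("chr1", 5_300, 5_319, "-"), 18.1),
        ]
        out = attach_best_motif(site, motifs)
        assert out.best_motif.score == 18.1
        assert attach_best_motif(site, []).best_motif is None
        assert attach_best_motif(site, []).motif_score == 0.0  # missing -> 0

    def test_window_respected(self):
        site = _site("chr1", 5_000)
        far = [MotifOccurrence(GenomicInterval("chr1", 6_100, 6_119, "+"), 30.0)]
        assert attach_best_motif(site, far).best_motif is None

    def test_tie_broken_by_distance_then_coordinate(self):
        site = _site("chr1", 5_000)
        near = MotifOccurrence(GenomicInterval("chr1", 4_950, 4_969, "+"), 15.0)
        farther = MotifOccurrence(GenomicInterval("chr1", 5_400, 5_419, "-"), 15.0)
        assert attach_best_motif(site, [farther, near]).best_motif == near

    def test_batch_matches_single(self):
        rng = np.random.default_rng(0)
        sites = [_site("chr1", int(p)) for p in rng.integers(2_000, 100_000, size=30)]
        motifs = [
            MotifOccurrence(
                GenomicInterval("chr1", int(p), int(p) + 19, "+" if rng.random() < 0.5 else "-"),
                float(rng.uniform(5, 20)),
            )
            for p in rng.integers(1_000, 101_000, size=60)
        ]
        batch = attach_motifs(sites, motifs)
        for s, b in zip(sites, batch):
            assert attach_best_motif(s, motifs).best_motif == b.best_motif


class TestCrossCellClassification:
    def test_simple_patterns(self):
        a = [_site("chr1", 10_000), _site("chr1", 50_000)]
        b = [_site("chr1", 10_200)]  # overlaps the first site's extent
        c = [_site("chr1", 90_000)]
        df = classify_sites_across_celltypes([a, b, c])
        patterns = sorted(df["pattern"])
        assert patterns == ["++-", "+--", "--+"]

    def test_group_sizes_match_bruteforce(self):
        rng = np.random.default_rng(42)
        sets = []
        for _ in range(3):
            summits = rng.integers(1_000, 500_000, size=25)
            sets.append([_site("chr1", int(p), float(rng.uniform(1, 5))) for p in summits])
        df = classify_sites_across_celltypes(sets)
        # brute force: pattern of every union site by pairwise extent overlap
        union = []
        for ss in sets:
            for s in ss:
                if not any(s.extent.overlaps(u.extent) for u in union):
                    union.append(s)
        assert len(df) == len(union)  # groups partition the union
        expected = {}
        for u in union:
            pat = "".join(
                "+" if any(s.extent.overlaps(u.extent) for s in ss) else "-" for ss in sets
            )
            expected[pat] = expected.get(pat, 0) + 1
        assert df["pattern"].value_counts().to_dict() == expected

    def test_requires_two_cell_types(self):
        with pytest.raises(ValueError):
            classify_sites_across_celltypes([[_site("chr1", 1_000)]])


class TestRelativeFluctuation:
    @pytest.mark.parametrize(
        "v1,v2,expected", [(5, 5, 0.0), (3, 5, 0.25), (30, 50, 0.25), (0, 4, 1.0)]
    )
    def test_values(self, v1, v2, expected):
        assert relative_fluctuation(v1, v2) == pytest.approx(expected)

    def test_zero_pair_undefined(self):
        with pytest.raises(ValueError):
            relative_fluctuation(0.0, 0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    def test_bounded_in_unit_interval(self, v1, v2):
        if v1 == 0 and v2 == 0:
            return
        assert 0.0 <= relative_fluctuation(v1, v2) <= 1.0
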