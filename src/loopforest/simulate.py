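"""Self-consistent synthetic data with planted loop structure.

The generator emits a complete toy input bundle — CTCF peaks, per-track
reads with enriched regions, motif occurrences, ChIA-PET-style loop calls,
an expression table, conservation scores, and a sparse Hi-C matrix with a
KR vector — in which a known set of "true" loops carries the discriminative
structure real CTCF loops show: elevated CTCF/RAD21 binding at their
anchors, a bias toward convergent motif orientation, suppressed gene
expression inside the loop, and enriched Hi-C contact at their bin pairs.
Every stage of the pipeline can therefore be scored against known truth,
offline and in seconds.

What the toy world deliberately lacks: realistic chromosome-scale coverage
(reads are only sampled on enriched regions, since masking discards the
rest), copy-number/mappability artefacts, fragment-length effects, and any
sequence content.  A green test on fixtures establishes algorithmic
correctness and statistical calibration, not real-data performance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, LoopRecord
from .features import CANONICAL_TRACKS, DataBundle, FeatureConfig
from .io import (
    ConservationTrack,
    ContactMatrix,
    ExpressionRecord,
    LoopFileDialect,
    PeakRecord,
    ReadSet,
    SignalTrack,
    write_bed,
    write_contact_matrix,
    write_expression_table,
    write_loop_file,
)
from .sites import BindingSite, MotifOccurrence, attach_motifs, build_sites

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "generate_second_celltype"]


@dataclass(frozen=True)
class FixtureSpec:
    """The stated world of the synthetic genome.

    Effect sizes are multiplicative folds (>= 1 enriches, 1 is neutral) or
    probabilities/fractions in (0, 1].  Defaults plant strong, realistic
    class structure: ~600 significant loops whose anchors carry 3x CTCF and
    RAD21 signal, an 85% convergent-motif rate at true loops versus random
    orientation elsewhere, 3.3x expression suppression inside loops and 5x
    Hi-C contact enrichment at loop bin pairs.
    """

    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 10_000_000), ("chr2", 10_000_000))
    n_sites: int = 1600
    n_loop_sites: int = 500
    n_true_loops: int = 600
    n_subthreshold_calls: int = 400
    ctcf_fold: float = 3.0
    rad21_fold: float = 3.0
    convergent_prob: float = 0.85
    motif_prob: float = 0.9
    expression_suppression: float = 0.3
    hic_enrichment: float = 5.0
    base_local_reads: float = 40.0
    library_size: int = 1_000_000
    read_length: int = 100
    n_genes: int = 300
    resolution: int = 10_000
    hic_base_count: float = 60.0
    hic_max_span: int = 1_200_000
    tracks: tuple[str, ...] = CANONICAL_TRACKS
    seed: int = 0

    def neutral(self) -> "FixtureSpec":
        """All effect sizes switched off: classes become exchangeable.

        ``convergent_prob`` is the probability of *forcing* convergence on a
        true loop on top of the chance rate, so neutral means 0.  Restricting
        loops to a designated subset of sites is itself an effect (it makes
        anchor identity informative), so the neutral world lets every site
        loop.
        """
        return replace(
            self,
            ctcf_fold=1.0,
            rad21_fold=1.0,
            convergent_prob=0.0,
            expression_suppression=1.0,
            hic_enrichment=1.0,
            n_loop_sites=self.n_sites,
        )

    def validate(self) -> None:
        genome = dict(self.chrom_sizes)
        if self.n_loop_sites > self.n_sites:
            raise ValueError("n_loop_sites exceeds n_sites")
        total = sum(genome.values())
        if self.n_sites * 6000 > total:
            raise ValueError("infeasible spec: too many sites for the genome")
        # generous capacity bound: every looping site can partner ~a handful
        if self.n_true_loops > 8 * self.n_loop_sites:
            raise ValueError("infeasible spec: loops exceed genome capacity")


@dataclass
class Fixture:
    """In-memory synthetic bundle plus the planted truth sidecar."""

    spec: FixtureSpec
    peaks: list[PeakRecord]
    tracks: dict[str, SignalTrack]
    motifs: list[MotifOccurrence]
    loop_calls: list[LoopRecord]
    hic_loops: list[LoopRecord]
    expression: list[ExpressionRecord]
    conservation: ConservationTrack
    matrices: dict[str, ContactMatrix]
    truth: list[LoopRecord]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.spec.chrom_sizes)

    def sites(self) -> list[BindingSite]:
        """Binding sites built from the peaks, with motifs attached."""
        ctcf = self.tracks["CTCF"].masked()
        return attach_motifs(build_sites(self.peaks, ctcf), self.motifs)

    def bundle(self) -> DataBundle:
        """Featurizer-ready bundle (tracks masked to enriched regions)."""
        return DataBundle(
            tracks={n: t.masked() for n, t in self.tracks.items()},
            ctcf_sites=self.sites(),
            conservation=self.conservation,
            expression=self.expression,
        )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [lp.chrom for lp in self.truth],
                "summit1": [lp.summit1 for lp in self.truth],
                "summit2": [lp.summit2 for lp in self.truth],
                "pet": [lp.pet_count for lp in self.truth],
                "fdr": [lp.fdr for lp in self.truth],
            }
        )


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _sample_summits(spec: FixtureSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Jittered-grid summits: deterministic counts with >= ~20% slot spacing."""
    genome = dict(spec.chrom_sizes)
    total = sum(genome.values())
    out: dict[str, np.ndarray] = {}
    remaining = spec.n_sites
    chroms = list(genome)
    for idx, chrom in enumerate(chroms):
        size = genome[chrom]
        n = remaining if idx == len(chroms) - 1 else int(round(spec.n_sites * size / total))
        remaining -= n
        usable = size - 100_000
        slot = usable / n
        jitter = rng.integers(int(0.1 * slot), int(0.9 * slot), size=n)
        out[chrom] = (50_000 + np.arange(n) * slot).astype(np.int64) + jitter
    return out


def _sample_loops(
    spec: FixtureSpec,
    rng: np.random.Generator,
    summits: Mapping[str, np.ndarray],
    n_loops: int,
    loop_site_ids: Mapping[str, np.ndarray],
    forbidden: set | None = None,
) -> list[tuple[str, int, int]]:
    """Sample distinct (chrom, site_i, site_j) pairs with 10 kb–1 Mb spans."""
    chroms = [c for c in loop_site_ids if len(loop_site_ids[c]) >= 2]
    weights = np.array([len(loop_site_ids[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    id_sets = {c: set(int(x) for x in loop_site_ids[c]) for c in chroms}
    chosen: list[tuple[str, int, int]] = []
    seen = set(forbidden or set())
    attempts = 0
    while len(chosen) < n_loops:
        attempts += 1
        if attempts > 500 * n_loops:
            raise ValueError("infeasible spec: cannot place the requested loops")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        ids = loop_site_ids[chrom]
        i = int(rng.choice(ids))
        pos = summits[chrom]
        lo = np.searchsorted(pos, pos[i] + 10_000, side="left")
        hi = np.searchsorted(pos, pos[i] + 1_000_000, side="right")
        cand = [j for j in range(lo, hi) if j in id_sets[chrom]]
        if not cand:
            continue
        j = int(cand[int(rng.integers(len(cand)))])
        key = (chrom, i, j)
        if key in seen:
            continue
        seen.add(key)
        chosen.append(key)
    return chosen


def _reads_for_track(
    name: str,
    spec: FixtureSpec,
    rng: np.random.Generator,
    summits: Mapping[str, np.ndarray],
    anchor_mask: Mapping[str, np.ndarray],
) -> SignalTrack:
    """Sample reads around every site; loop anchors get the track's fold."""
    fold = {"CTCF": spec.ctcf_fold, "RAD21": spec.rad21_fold}.get(name, 1.0)
    base = spec.base_local_reads * {"DNase": 1.5}.get(name, 1.0)
    per_chrom: dict[str, np.ndarray] = {}
    regions: list[GenomicInterval] = []
    for chrom, pos in summits.items():
        rates = np.where(anchor_mask[chrom], base * fold, base)
        counts = rng.poisson(rates)
        reps = np.repeat(pos, counts)
        offsets = rng.integers(-1000, 1000 - spec.read_length, size=len(reps))
        starts = np.maximum(0, reps + offsets)
        arr = np.stack([starts, starts + spec.read_length], axis=1)
        per_chrom[chrom] = arr
        regions.extend(
            GenomicInterval(chrom, max(0, int(p) - 1500), int(p) + 1500) for p in pos
        )
    reads = ReadSet(per_chrom, spec.library_size)
    return SignalTrack(name, reads, regions)


def _emit(
    spec: FixtureSpec,
    rng: np.random.Generator,
    summits: Mapping[str, np.ndarray],
    loop_keys: Sequence[tuple[str, int, int]],
) -> Fixture:
    genome = dict(spec.chrom_sizes)

    # which sites anchor a true loop
    anchor_mask = {c: np.zeros(len(p), dtype=bool) for c, p in summits.items()}
    for chrom, i, j in loop_keys:
        anchor_mask[chrom][i] = True
        anchor_mask[chrom][j] = True

    # peaks (narrowPeak-style: summit at offset 400 of an 800 bp peak)
    peaks = [
        PeakRecord(GenomicInterval(c, max(0, int(p) - 400), int(p) + 400), min(400, int(p)), 10.0)
        for c, pos in summits.items()
        for p in pos
    ]

    # motifs: presence, score, strand (convergent bias at true-loop anchors)
    has_motif: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    for chrom, pos in summits.items():
        has_motif[chrom] = rng.random(len(pos)) < spec.motif_prob
        strands[chrom] = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        scores[chrom] = np.clip(rng.normal(15.0, 3.0, size=len(pos)), 5.0, None)
    for chrom, i, j in loop_keys:
        if rng.random() < spec.convergent_prob:
            has_motif[chrom][i] = True
            has_motif[chrom][j] = True
            strands[chrom][i] = "+"
            strands[chrom][j] = "-"
    motifs = [
        MotifOccurrence(
            GenomicInterval(c, int(p) - 9, int(p) + 10, str(strands[c][k])),
            float(scores[c][k]),
        )
        for c, pos in summits.items()
        for k, p in enumerate(pos)
        if has_motif[c][k]
    ]

    # signal tracks
    tracks = {
        name: _reads_for_track(name, spec, rng, summits, anchor_mask)
        for name in spec.tracks
    }

    # true loops -> significant ChIA-PET calls
    truth: list[LoopRecord] = []
    for chrom, i, j in loop_keys:
        s1, s2 = int(summits[chrom][i]), int(summits[chrom][j])
        truth.append(
            LoopRecord(
                GenomicInterval(chrom, max(0, s1 - 500), s1 + 500),
                GenomicInterval(chrom, max(0, s2 - 500), s2 + 500),
                pet_count=int(2 + rng.poisson(6)),
                fdr=float(rng.uniform(0.0, 0.05)),
                summit1=s1,
                summit2=s2,
            )
        )

    # sub-threshold calls: weak PET-1 or high-FDR pairs over random sites
    loop_calls = list(truth)
    existing = {(c, i, j) for c, i, j in loop_keys}
    sub_keys = _sample_loops(
        spec,
        rng,
        summits,
        spec.n_subthreshold_calls,
        {c: np.arange(len(p)) for c, p in summits.items()},
        forbidden=existing,
    )
    for chrom, i, j in sub_keys:
        s1, s2 = int(summits[chrom][i]), int(summits[chrom][j])
        weak = rng.random() < 0.7
        loop_calls.append(
            LoopRecord(
                GenomicInterval(chrom, max(0, s1 - 500), s1 + 500),
                GenomicInterval(chrom, max(0, s2 - 500), s2 + 500),
                pet_count=1 if weak else int(2 + rng.poisson(2)),
                fdr=float(rng.uniform(0.0, 0.05)) if weak else float(rng.uniform(0.06, 0.5)),
                summit1=s1,
                summit2=s2,
            )
        )

    # expression: genes uniform over the genome, suppressed inside true loops
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for lp in truth:
        spans[lp.chrom].append((lp.summit1, lp.summit2))
    expression = []
    chrom_names = list(genome)
    sizes = np.array([genome[c] for c in chrom_names], dtype=float)
    pick = rng.choice(len(chrom_names), size=spec.n_genes, p=sizes / sizes.sum())
    for g in range(spec.n_genes):
        chrom = chrom_names[int(pick[g])]
        tss = int(rng.integers(10_000, genome[chrom] - 10_000))
        fpkm = float(rng.lognormal(1.0, 1.0))
        inside = any(s1 + 2000 <= tss - 2000 and tss + 2000 <= s2 for s1, s2 in spans[chrom])
        if inside:
            fpkm *= spec.expression_suppression
        strand = "+" if rng.random() < 0.5 else "-"
        expression.append(
            ExpressionRecord(f"gene{g:04d}", GenomicInterval(chrom, tss, tss + 1, strand), fpkm)
        )

    # conservation: elevated over motifs, sparse low-level background
    cons: dict[str, list[list[float]]] = {c: [] for c in genome}
    for m in motifs:
        cons[m.interval.chrom].append(
            [m.interval.start, m.interval.end, float(rng.uniform(0.5, 1.0))]
        )
    for chrom in genome:
        n_bg = 200
        starts = rng.integers(0, genome[chrom] - 100, size=n_bg)
        for s in starts:
            cons[chrom].append([int(s), int(s) + 100, float(rng.uniform(0.0, 0.2))])
    conservation = ConservationTrack({c: np.asarray(v) for c, v in cons.items() if v})

    # Hi-C: distance-decayed background + enrichment at true-loop bin pairs
    matrices: dict[str, ContactMatrix] = {}
    res = spec.resolution
    for chrom, size in genome.items():
        n_bins = size // res
        entries: dict[tuple[int, int], float] = {}
        max_off = spec.hic_max_span // res
        for off in range(1, max_off + 1):
            lam = spec.hic_base_count / (1.0 + off)
            counts = rng.poisson(lam, size=n_bins - off)
            nz = np.flatnonzero(counts)
            for i in nz:
                entries[(int(i), int(i) + off)] = float(counts[i])
        for lp in truth:
            if lp.chrom != chrom:
                continue
            bi, bj = lp.summit1 // res, lp.summit2 // res
            off = abs(bj - bi)
            lam = spec.hic_enrichment * spec.hic_base_count / (1.0 + off)
            entries[(min(bi, bj), max(bi, bj))] = float(rng.poisson(lam))
        kr = rng.lognormal(0.0, 0.05, size=n_bins)
        kr[:2] = np.nan  # unmappable chromosome start
        matrices[chrom] = ContactMatrix(res, entries, kr)

    return Fixture(
        spec=spec,
        peaks=peaks,
        tracks=tracks,
        motifs=motifs,
        loop_calls=loop_calls,
        hic_loops=list(truth),
        expression=expression,
        conservation=conservation,
        matrices=matrices,
        truth=truth,
    )


def generate_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate the full synthetic bundle; byte-deterministic per spec+seed."""
    spec = spec or FixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    summits = _sample_summits(spec, rng)
    # designate looping sites proportionally per chromosome
    loop_site_ids: dict[str, np.ndarray] = {}
    remaining = spec.n_loop_sites
    chroms = list(summits)
    for idx, chrom in enumerate(chroms):
        n = (
            remaining
            if idx == len(chroms) - 1
            else int(round(spec.n_loop_sites * len(summits[chrom]) / spec.n_sites))
        )
        remaining -= n
        loop_site_ids[chrom] = np.sort(
            rng.choice(len(summits[chrom]), size=min(n, len(summits[chrom])), replace=False)
        )
    loop_keys = _sample_loops(spec, rng, summits, spec.n_true_loops, loop_site_ids)
    return _emit(spec, rng, summits, loop_keys)


def generate_second_celltype(
    fixture: Fixture, divergence: float = 0.5, seed: int | None = None
) -> Fixture:
    """A second cell type sharing the planted rules.

    ``divergence`` is the fraction of true loops rewired (and of non-anchor
    sites replaced); 0 reproduces a statistically identical cell.  The same
    effect sizes apply, so a model trained on one cell transfers to the
    other exactly as far as the shared rules allow.
    """
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must be in [0, 1]")
    spec = fixture.spec
    seed = spec.seed + 7919 if seed is None else seed
    rng = np.random.default_rng(seed)
    summits = _sample_summits(spec, np.random.default_rng(spec.seed))  # same site grid
    # recover the original planted loop keys from the truth sidecar
    pos_index = {c: {int(p): k for k, p in enumerate(ps)} for c, ps in summits.items()}
    orig_keys = [
        (lp.chrom, pos_index[lp.chrom][lp.summit1], pos_index[lp.chrom][lp.summit2])
        for lp in fixture.truth
    ]
    n_rewire = int(round(divergence * len(orig_keys)))
    keep_idx = rng.choice(len(orig_keys), size=len(orig_keys) - n_rewire, replace=False)
    kept = [orig_keys[i] for i in sorted(keep_idx)]
    dropped = [orig_keys[i] for i in range(len(orig_keys)) if i not in set(keep_idx)]
    kept_site_ids = {c: set() for c in summits}
    for chrom, i, j in kept:
        kept_site_ids[chrom].update((i, j))
    # replace a matching fraction of non-anchor sites with fresh positions
    new_summits: dict[str, np.ndarray] = {}
    for chrom, pos in summits.items():
        pos = pos.copy()
        free = np.array(
            [k for k in range(len(pos)) if k not in kept_site_ids[chrom]], dtype=int
        )
        n_replace = int(round(divergence * len(free)))
        if n_replace:
            repl = rng.choice(free, size=n_replace, replace=False)
            size = dict(spec.chrom_sizes)[chrom]
            pos[repl] = rng.integers(50_000, size - 50_000, size=n_replace)
        order = np.argsort(pos, kind="stable")
        new_summits[chrom] = pos[order]
        # remap key indices through the re-sort (dropped loops are forbidden
        # from being re-sampled, so the rewired fraction is exact)
        remap = {int(old): int(new) for new, old in enumerate(order)}
        kept = [
            (c, remap[i], remap[j]) if c == chrom else (c, i, j) for c, i, j in kept
        ]
        dropped = [
            (c, remap[i], remap[j]) if c == chrom else (c, i, j) for c, i, j in dropped
        ]
    kept = [(c, min(i, j), max(i, j)) for c, i, j in kept]
    dropped = [(c, min(i, j), max(i, j)) for c, i, j in dropped]
    loop_site_ids = {
        c: np.arange(len(p)) for c, p in new_summits.items()
    }  # rewired loops may use any site
    new_keys = _sample_loops(
        spec, rng, new_summits, n_rewire, loop_site_ids, forbidden=set(kept) | set(dropped)
    )
    return _emit(spec, rng, new_summits, kept + new_keys)


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------


def write_fixture(fixture: Fixture, outdir) -> dict[str, str]:
    """Write every component as plain text; returns SHA-256 per file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "peaks.narrowPeak", "w") as fh:
        for pk in fixture.peaks:
            iv = pk.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t.\t{pk.score:.6g}\t-1\t-1\t{pk.summit_offset}\n"
            )
    for name, track in fixture.tracks.items():
        write_bed(track.reads.to_intervals(), outdir / f"reads_{name}.bed")
        write_bed(track.enriched_regions, outdir / f"enriched_{name}.bed")
    with open(outdir / "motifs.tsv", "w") as fh:
        fh.write("chrom\tstart\tstop\tstrand\tscore\n")
        for m in fixture.motifs:
            iv = m.interval
            fh.write(f"{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t{m.score:.6g}\n")
    write_loop_file(fixture.loop_calls, outdir / "loops.bedpe")
    write_loop_file(fixture.hic_loops, outdir / "hic_loops.bedpe")
    write_expression_table(fixture.expression, outdir / "expression.tsv")
    with open(outdir / "conservation.bedGraph", "w") as fh:
        for chrom in sorted(fixture.conservation._data):
            for s, e, v in fixture.conservation._data[chrom]:
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")
    for chrom, mat in fixture.matrices.items():
        write_contact_matrix(mat, outdir / f"hic_{chrom}.txt", outdir / f"kr_{chrom}.txt")
    fixture.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in fixture.spec.chrom_sizes:
            fh.write(f"{chrom}\t{size}\n")
    hashes = {}
    for path in sorted(outdir.iterdir()):
        hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return hashes
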