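"""Exact seed-and-verify read placement with multi-mapping awareness.

This stands in for a general-purpose aligner at simulation scale.  The
guarantee matters more than speed: with ``max_mismatches = m`` the read is
split into ``m + 1`` disjoint seeds, so any alignment with at most ``m``
substitutions leaves at least one seed exact (pigeonhole) and *every*
best-scoring location is discovered.  Ties among equal-best locations are
broken uniformly at random (seeded) and the chosen placement gets MAPQ 0 —
the behavior that makes read depth split 1/c across a c-copy tandem array
and drives the q0 signal.

Placements are array-backed (one genome-scale run produces millions), with
iteration yielding per-read :class:`ReadPlacement` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genome import GenomeSequence
from .reads import ReadSet

_SENTINEL = np.uint8(4)  # non-base between concatenated chromosomes
_MAPQ_UNIQUE = 60
_VERIFY_CHUNK = 400_000


@dataclass
class ReadPlacement:
    read_id: int
    chrom: str
    pos: int  # 0-based start
    length: int
    mapq: int
    n_best_hits: int


@dataclass
class Placements:
    """Column-oriented read placements plus the unplaced-read counter."""

    chrom_names: list[str]
    read_length: int
    read_id: np.ndarray  # (n,) int64
    chrom_index: np.ndarray  # (n,) int32
    pos: np.ndarray  # (n,) int64
    mapq: np.ndarray  # (n,) int16
    n_best_hits: np.ndarray  # (n,) int32
    n_unplaced: int = 0
    extra: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return self.pos.size

    def __iter__(self) -> Iterator[ReadPlacement]:
        for i in range(len(self)):
            yield ReadPlacement(
                read_id=int(self.read_id[i]),
                chrom=self.chrom_names[self.chrom_index[i]],
                pos=int(self.pos[i]),
                length=self.read_length,
                mapq=int(self.mapq[i]),
                n_best_hits=int(self.n_best_hits[i]),
            )


def _window_codes(rows: np.ndarray, offset: int, k: int) -> np.ndarray:
    """Exact 3-bit packed codes of rows[:, offset:offset+k] (k <= 21)."""
    h = np.zeros(rows.shape[0], dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(3)) | rows[:, offset + j].astype(np.uint64)
    return h


def _genome_codes(arr: np.ndarray, k: int) -> np.ndarray:
    n = arr.size - k + 1
    h = np.zeros(n, dtype=np.uint64)
    a = arr.astype(np.uint64)
    for j in range(k):
        h = (h << np.uint64(3)) | a[j : j + n]
    return h


def place_reads(
    reads: ReadSet,
    reference: GenomeSequence,
    max_mismatches: int = 2,
    seed: int = 0,
) -> Placements:
    """Place every read at its best-scoring location(s) on the forward strand.

    Reads whose best alignment has more than ``max_mismatches`` substitutions
    are dropped and counted in ``n_unplaced``.  A read with ``n`` equal-best
    locations is assigned one uniformly at random with MAPQ 0 when n >= 2,
    MAPQ 60 otherwise.
    """
    rl = reads.read_length
    n_seeds = max_mismatches + 1
    k = min(21, rl // n_seeds)
    if k < 8:
        raise ValueError(
            f"read length {rl} too short for {n_seeds} disjoint seeds of >= 8 bp"
        )
    step = rl // n_seeds
    seed_offsets = [i * step for i in range(n_seeds)]
    rng = np.random.default_rng(seed)
    names = reference.names

    # concatenate chromosomes with a sentinel base between them
    lengths = np.array([reference.length(n) for n in names], dtype=np.int64)
    offs = np.zeros(len(names), dtype=np.int64)
    for i in range(1, len(names)):
        offs[i] = offs[i - 1] + lengths[i - 1] + 1
    total = int(offs[-1] + lengths[-1])
    concat = np.full(total, _SENTINEL, dtype=np.uint8)
    for i, n in enumerate(names):
        concat[offs[i] : offs[i] + lengths[i]] = reference.encoded(n)

    gcodes = _genome_codes(concat, k)
    order = np.argsort(gcodes, kind="stable")
    sorted_codes = gcodes[order]

    n_reads = len(reads)
    cand_reads: list[np.ndarray] = []
    cand_starts: list[np.ndarray] = []
    for o in seed_offsets:
        rcodes = _window_codes(reads.sequences, o, k)
        left = np.searchsorted(sorted_codes, rcodes, side="left")
        right = np.searchsorted(sorted_codes, rcodes, side="right")
        counts = right - left
        nz = counts > 0
        c = counts[nz]
        if c.size == 0:
            continue
        tot = int(c.sum())
        csum = np.cumsum(c) - c
        sel = np.repeat(left[nz], c) + (np.arange(tot) - np.repeat(csum, c))
        cand_reads.append(np.repeat(np.flatnonzero(nz), c))
        cand_starts.append(order[sel] - o)

    if not cand_reads:
        return _empty_placements(reads, names, n_reads)

    r = np.concatenate(cand_reads)
    s = np.concatenate(cand_starts)
    keep = (s >= 0) & (s + rl <= total)
    r, s = r[keep], s[keep]
    # window must lie inside a single chromosome
    ci = (np.searchsorted(offs, s, side="right") - 1).astype(np.int64)
    keep = (s >= offs[ci]) & (s + rl <= offs[ci] + lengths[ci])
    r, s = r[keep], s[keep]
    # dedupe (read, start) pairs found via several seeds
    key = r * np.int64(total) + s
    _, uniq_idx = np.unique(key, return_index=True)
    r, s = r[uniq_idx], s[uniq_idx]

    # verify candidates: mismatch count of the full read window
    ref_windows = np.lib.stride_tricks.sliding_window_view(concat, rl)
    mism = np.empty(r.size, dtype=np.int32)
    for lo in range(0, r.size, _VERIFY_CHUNK):
        hi = min(lo + _VERIFY_CHUNK, r.size)
        mism[lo:hi] = (ref_windows[s[lo:hi]] != reads.sequences[r[lo:hi]]).sum(
            axis=1, dtype=np.int32
        )
    ok = mism <= max_mismatches
    r, s, mism = r[ok], s[ok], mism[ok]

    if r.size == 0:
        return _empty_placements(reads, names, n_reads)

    # per read: keep equal-best locations, draw one uniformly
    o2 = np.lexsort((s, mism, r))
    r, s, mism = r[o2], s[o2], mism[o2]
    firsts = np.flatnonzero(np.concatenate(([True], r[1:] != r[:-1])))
    sizes = np.diff(np.concatenate((firsts, [r.size])))
    best = mism[firsts]
    is_best = mism == np.repeat(best, sizes)
    n_best = np.add.reduceat(is_best, firsts).astype(np.int32)
    pick = firsts + rng.integers(0, n_best)  # best entries are contiguous
    sel_s = s[pick]
    sel_r = r[firsts]

    sel_ci = (np.searchsorted(offs, sel_s, side="right") - 1).astype(np.int32)
    pos = sel_s - offs[sel_ci]
    mapq = np.where(n_best >= 2, 0, _MAPQ_UNIQUE).astype(np.int16)
    return Placements(
        chrom_names=list(names),
        read_length=rl,
        read_id=sel_r.astype(np.int64),
        chrom_index=sel_ci,
        pos=pos.astype(np.int64),
        mapq=mapq,
        n_best_hits=n_best,
        n_unplaced=n_reads - sel_r.size,
    )


def _empty_placements(reads: ReadSet, names: list[str], n_reads: int) -> Placements:
    return Placements(
        chrom_names=list(names),
        read_length=reads.read_length,
        read_id=np.empty(0, dtype=np.int64),
        chrom_index=np.empty(0, dtype=np.int32),
        pos=np.empty(0, dtype=np.int64),
        mapq=np.empty(0, dtype=np.int16),
        n_best_hits=np.empty(0, dtype=np.int32),
        n_unplaced=n_reads,
    )


def placements_from_alignments(path, chrom_names: list[str] | None = None) -> Placements:
    """Load placements from a coordinate-sorted SAM/BAM file (real-data mode).

    MAPQ-0 records are treated as multi-mapped; unmapped, secondary,
    supplementary and duplicate-marked records are skipped (PCR duplicates
    are assumed to have been marked upstream).
    """
    import pysam

    ids, cis, poss, mapqs = [], [], [], []
    rl = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        names = chrom_names or list(fh.references)
        name_to_idx = {n: i for i, n in enumerate(names)}
        for i, rec in enumerate(fh):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                continue
            ids.append(i)
            cis.append(name_to_idx[rec.reference_name])
            poss.append(rec.reference_start)
            mapqs.append(rec.mapping_quality)
            rl = max(rl, rec.query_length or rec.infer_read_length() or 0)
    mq = np.array(mapqs, dtype=np.int16)
    return Placements(
        chrom_names=names,
        read_length=rl or 150,
        read_id=np.array(ids, dtype=np.int64),
        chrom_index=np.array(cis, dtype=np.int32),
        pos=np.array(poss, dtype=np.int64),
        mapq=mq,
        n_best_hits=np.where(mq == 0, 2, 1).astype(np.int32),
        n_unplaced=0,
    )
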