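"""Multi-sample intersection, known-CNV exclusion and summary statistics.

A locus enters the shared set only when *every* sample contributes one call
of the same genotype class and all supporting calls overlap pairwise
reciprocally by more than ``min_shared_frac`` (default 0.5).  Reciprocal —
the minimum of the two one-sided fractions — keeps the shared set invariant
under permutation of the samples.  Loci whose span is covered more than
``max_known_frac`` (default 0.10) by known CNV regions of the reference
species are excluded as within-species polymorphism rather than a
cross-species difference.
"""

from __future__ import annotations

from collections import Counter, namedtuple
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .caller import CNVCall
from .classify import GenotypeClass

Interval = namedtuple("Interval", ["chrom", "start", "end"])


@dataclass
class OverlapParams:
    min_shared_frac: float = 0.5
    max_known_frac: float = 0.10

    def __post_init__(self) -> None:
        for v in (self.min_shared_frac, self.max_known_frac):
            if not 0.0 < v < 1.0:
                raise ValueError("overlap fractions must be in (0, 1)")


@dataclass
class SharedCNV:
    chrom: str
    start: int  # union of the supporting calls
    end: int
    cls: GenotypeClass
    per_sample_calls: list[CNVCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap(a, b) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); 0 for different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def _check_same_build(callsets: Sequence[Sequence[CNVCall]]) -> None:
    namesets = [{c.chrom for c in cs} for cs in callsets]
    for i in range(len(namesets)):
        for j in range(i + 1, len(namesets)):
            if namesets[i] and namesets[j] and not (namesets[i] & namesets[j]):
                raise ValueError(
                    "chromosome name mismatch between samples "
                    f"{i} and {j}; are the calls on the same genome build?"
                )


def shared_calls(
    callsets: Sequence[Sequence[CNVCall]], params: OverlapParams | None = None
) -> list[SharedCNV]:
    """Loci supported by one same-class call from every sample.

    Enumerates every tuple (one call per sample, identical genotype class,
    all pairwise reciprocal overlaps > ``min_shared_frac``), then greedily
    emits tuples in genomic order, consuming each call at most once.  The
    tuple set and the ordering key are both symmetric in the samples, so the
    result is invariant under permutation of sample order.
    """
    params = params or OverlapParams()
    if len(callsets) < 2:
        raise ValueError("need at least two samples to intersect")
    _check_same_build(callsets)

    tuples: list[tuple] = []

    def extend(partial: list[CNVCall], sample_idx: int) -> None:
        if sample_idx == len(callsets):
            tuples.append(tuple(partial))
            return
        for cand in callsets[sample_idx]:
            if cand.genotype is not partial[0].genotype:
                continue
            if all(reciprocal_overlap(cand, p) > params.min_shared_frac for p in partial):
                extend(partial + [cand], sample_idx + 1)

    for first in callsets[0]:
        if first.genotype is None:
            raise ValueError("calls must be classified before intersection")
        extend([first], 1)

    def key(tup):
        starts = sorted((c.chrom, c.start, c.end) for c in tup)
        return (
            tup[0].chrom,
            min(c.start for c in tup),
            max(c.end for c in tup),
            starts,
        )

    shared: list[SharedCNV] = []
    used: set[int] = set()
    for tup in sorted(tuples, key=key):
        ids = [id(c) for c in tup]
        if any(i in used for i in ids):
            continue
        used.update(ids)
        shared.append(
            SharedCNV(
                chrom=tup[0].chrom,
                start=min(c.start for c in tup),
                end=max(c.end for c in tup),
                cls=tup[0].genotype,
                per_sample_calls=list(tup),
            )
        )
    return shared


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def known_overlap_fraction(cnv, known_by_chrom: dict[str, list[tuple[int, int]]]) -> float:
    """Fraction of the CNV span covered by (merged) known regions."""
    covered = 0
    for s, e in known_by_chrom.get(cnv.chrom, []):
        covered += max(0, min(e, cnv.end) - max(s, cnv.start))
    return covered / (cnv.end - cnv.start)


def exclude_known(
    shared: Sequence[SharedCNV],
    known: Sequence[tuple[str, int, int]],
    params: OverlapParams | None = None,
) -> list[SharedCNV]:
    """Drop shared loci covered > ``max_known_frac`` by known CNV regions."""
    params = params or OverlapParams()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in known:
        by_chrom.setdefault(chrom, []).append((s, e))
    by_chrom = {c: _merge_intervals(v) for c, v in by_chrom.items()}
    return [
        cnv
        for cnv in shared
        if known_overlap_fraction(cnv, by_chrom) <= params.max_known_frac
    ]


def summarize(shared: Sequence[SharedCNV], genome_size: Optional[int] = None) -> dict:
    """Per-class counts and length statistics of the final shared set.

    For an even number of loci the median length is the lower of the two
    middle values.  An empty input yields an all-zero summary.
    """
    lengths = sorted(c.length for c in shared)
    n = len(lengths)
    counts = Counter(c.cls.name for c in shared)
    summary = {
        "n": n,
        "class_counts": dict(counts),
        "total_bp": sum(lengths),
        "min_length": lengths[0] if n else 0,
        "median_length": lengths[(n - 1) // 2] if n else 0,
        "max_length": lengths[-1] if n else 0,
    }
    if genome_size:
        summary["genome_fraction"] = summary["total_bp"] / genome_size
    return summary
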