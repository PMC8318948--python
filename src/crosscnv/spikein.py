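"""Planting tandem-duplication spike-ins into a reference genome.

A spike-in replaces a single-copy unit of the background with ``ref_copies``
exact tandem copies.  Reads simulated from the *unmodified* genome (the test
species, carrying one copy) then split their placements across the copies,
producing the reference-duplication signature: normalized read depth near
1/ref_copies with a high zero-mapping-quality (q0) fraction inside the array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import GenomeSequence


class SpikeInError(ValueError):
    pass


@dataclass
class SpikeInTruth:
    """One planted duplication.

    ``start``/``end`` delimit the original single-copy unit in the
    *unmodified* genome (0-based half-open).  After ``apply_spikeins`` the
    returned truth records additionally carry ``array_start``/``array_end``:
    the span of the full tandem array in the spiked genome's (shifted)
    coordinates, which is what depth profiles and calls are measured against.
    """

    chrom: str
    start: int
    end: int
    unit_length: int
    ref_copies: int
    test_copies: int = 1
    array_start: Optional[int] = None
    array_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_length:
            raise SpikeInError("unit_length must equal end - start")
        if self.ref_copies < 2:
            raise SpikeInError("ref_copies must be >= 2")

    @property
    def truth_interval(self) -> tuple[str, int, int]:
        """Array interval in spiked coordinates (falls back to unit coords)."""
        if self.array_start is not None:
            return (self.chrom, self.array_start, self.array_end)
        return (self.chrom, self.start, self.end)


def plan_spikeins(
    genome: GenomeSequence,
    per_chrom: int,
    copy_numbers: Sequence[int] = (2, 4),
    size_range: tuple[int, int] = (3000, 176000),
    seed: int = 0,
) -> list[SpikeInTruth]:
    """Choose spike-in loci: ``per_chrom`` sites per chromosome.

    Copy numbers cycle through ``copy_numbers`` (default: one 2-copy and one
    4-copy site per chromosome); unit lengths are drawn uniformly from
    ``size_range`` (inclusive).  Each chromosome is split into ``per_chrom``
    equal slots and one site is placed uniformly inside each slot with a
    one-unit margin on both sides, which guarantees that sites stay at least
    one unit length away from chromosome ends and from each other.
    """
    if per_chrom < 0:
        raise ValueError("per_chrom must be >= 0")
    if per_chrom == 0:
        return []
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo > hi or lo < 1:
        raise ValueError(f"invalid size_range {size_range}")
    rng = np.random.default_rng(seed)
    plan: list[SpikeInTruth] = []
    cycle = list(copy_numbers)
    for name in genome.names:
        length = genome.length(name)
        if per_chrom * hi * max(cycle) > length:
            raise SpikeInError(
                f"infeasible packing on chromosome {name}: "
                f"{per_chrom} sites x {hi} bp x {max(cycle)} copies "
                f"exceed length {length}"
            )
        slot = length // per_chrom
        for i in range(per_chrom):
            unit = int(rng.integers(lo, hi + 1))
            # start in [slot_start + unit, slot_end - 2*unit]
            lo_start = i * slot + unit
            hi_start = (i + 1) * slot - 2 * unit
            if hi_start < lo_start:
                raise SpikeInError(
                    f"infeasible packing on chromosome {name}: unit {unit} bp "
                    f"does not fit a {slot} bp slot with one-unit margins"
                )
            start = int(rng.integers(lo_start, hi_start + 1))
            plan.append(
                SpikeInTruth(
                    chrom=name,
                    start=start,
                    end=start + unit,
                    unit_length=unit,
                    ref_copies=cycle[i % len(cycle)],
                )
            )
    return plan


def apply_spikeins(
    genome: GenomeSequence, plan: Sequence[SpikeInTruth]
) -> tuple[GenomeSequence, list[SpikeInTruth]]:
    """Return the spiked genome and truth records with shifted coordinates.

    Each unit is replaced by ``ref_copies`` exact tandem copies, so the
    genome grows by exactly sum (ref_copies - 1) * unit_length.  The returned
    truth records carry ``array_start``/``array_end`` — the tandem array's
    span in the spiked genome — while ``start``/``end`` keep the original
    coordinates.
    """
    by_chrom: dict[str, list[SpikeInTruth]] = {}
    for t in plan:
        if t.chrom not in genome.chromosomes:
            raise SpikeInError(f"unknown chromosome {t.chrom!r}")
        if t.end > genome.length(t.chrom):
            raise SpikeInError(f"spike-in beyond end of {t.chrom}")
        by_chrom.setdefault(t.chrom, []).append(t)

    new_chroms: dict[str, str] = {}
    new_truth: list[SpikeInTruth] = []
    for name, seq in genome.chromosomes.items():
        sites = sorted(by_chrom.get(name, []), key=lambda t: t.start)
        for a, b in zip(sites, sites[1:]):
            if b.start < a.end:
                raise SpikeInError(
                    f"overlapping spike-ins on {name}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        pieces: list[str] = []
        cursor = 0
        shift = 0
        for t in sites:
            pieces.append(seq[cursor : t.start])
            unit = seq[t.start : t.end]
            pieces.append(unit * t.ref_copies)
            new_truth.append(
                SpikeInTruth(
                    chrom=name,
                    start=t.start,
                    end=t.end,
                    unit_length=t.unit_length,
                    ref_copies=t.ref_copies,
                    test_copies=t.test_copies,
                    array_start=t.start + shift,
                    array_end=t.start + shift + t.ref_copies * t.unit_length,
                )
            )
            shift += (t.ref_copies - 1) * t.unit_length
            cursor = t.end
        pieces.append(seq[cursor:])
        new_chroms[name] = "".join(pieces)
    return GenomeSequence(new_chroms), new_truth


def write_truth_bed(truth: Sequence[SpikeInTruth], path) -> None:
    """BED6 of tandem arrays in spiked coordinates; name=class, score=ref_copies."""
    from .io import write_bed

    rows = []
    for t in truth:
        chrom, start, end = t.truth_interval
        rows.append((chrom, start, end, "DUP_REF", t.ref_copies, "+"))
    write_bed(rows, path)


def read_truth_bed(path) -> list[SpikeInTruth]:
    """Inverse of :func:`write_truth_bed` (array coords only; unit unknown)."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            copies = int(fields[4]) if len(fields) > 4 else 2
            unit = (end - start) // copies
            out.append(
                SpikeInTruth(
                    chrom=chrom,
                    start=start,
                    end=start + unit,
                    unit_length=unit,
                    ref_copies=copies,
                    array_start=start,
                    array_end=end,
                )
            )
    return out
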