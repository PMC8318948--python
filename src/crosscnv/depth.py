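"""Binned read-depth profiles: raw counts, GC correction, normalization, q0.

A read contributes to the bin containing its start position.  The corrected
read depth (RD) is the raw depth divided by the mean depth of bins in the
same 1%-wide GC stratum, rescaled so the genome-wide mean over full bins is
exactly 1; copy-neutral background therefore sits at RD ~ 1 and a c-copy
reference duplication sampled from a single-copy test genome at RD ~ 1/c.
q0 is the per-bin fraction of reads whose placement had mapping quality 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import Placements
from .genome import GenomeSequence

_GC_MIN_BINS = 100  # strata with fewer full bins fall back to the global mean


@dataclass
class DepthProfile:
    """Per-bin depth table for a whole genome.

    ``frame`` columns: chrom, start, end, full (terminal partial bins are
    flagged and excluded from all statistics), read_count, q0_reads, gc,
    raw_depth, q0, corrected_rd (NaN until :func:`gc_correct`).
    """

    frame: pd.DataFrame
    bin_size: int
    read_length: int
    corrected: bool = False
    meta: dict = field(default_factory=dict)

    def chrom_view(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    @property
    def full_mask(self) -> np.ndarray:
        return self.frame["full"].to_numpy()

    def mean_rd(self, chrom: str, start: int, end: int, column: str = "corrected_rd") -> float:
        """Mean RD over the full bins contained in [start, end)."""
        sub = self.frame[
            (self.frame["chrom"] == chrom)
            & (self.frame["start"] >= start)
            & (self.frame["end"] <= end)
            & self.frame["full"]
        ]
        return float(sub[column].mean())

    def write_tsv(self, path) -> None:
        cols = ["chrom", "start", "end", "corrected_rd", "q0"]
        self.frame.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")


def _gc_per_bin(g: np.ndarray, starts: np.ndarray, widths: np.ndarray) -> np.ndarray:
    gc = (g == 1) | (g == 2)
    csum = np.concatenate(([0], np.cumsum(gc)))
    return (csum[starts + widths] - csum[starts]) / widths


def bin_depth(
    placements: Placements, genome: GenomeSequence, bin_size: int
) -> DepthProfile:
    """Count read starts per bin and compute raw depth, GC and q0."""
    if bin_size < 50:
        raise ValueError("bin_size must be >= 50")
    if len(placements) == 0:
        raise ValueError("empty placement set")
    rl = placements.read_length
    frames = []
    for ci, name in enumerate(placements.chrom_names):
        length = genome.length(name)
        n_bins = -(-length // bin_size)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        mask = placements.chrom_index == ci
        bins_of_reads = placements.pos[mask] // bin_size
        counts = np.bincount(bins_of_reads, minlength=n_bins).astype(np.int64)
        q0_reads = np.bincount(
            bins_of_reads[placements.mapq[mask] == 0], minlength=n_bins
        ).astype(np.int64)
        widths = ends - starts
        gc = _gc_per_bin(genome.encoded(name), starts, widths)
        with np.errstate(invalid="ignore"):
            q0 = np.where(counts > 0, q0_reads / np.maximum(counts, 1), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "start": starts,
                    "end": ends,
                    "full": widths == bin_size,
                    "read_count": counts,
                    "q0_reads": q0_reads,
                    "gc": gc,
                    "raw_depth": counts * rl / bin_size,
                    "q0": q0,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    frame["corrected_rd"] = np.nan
    return DepthProfile(frame=frame, bin_size=bin_size, read_length=rl)


def gc_correct(profile: DepthProfile, genome: GenomeSequence | None = None) -> DepthProfile:
    """GC-stratified depth correction followed by mean-1 normalization.

    corrected_rd(bin) = raw_depth(bin) * global_mean / stratum_mean, where a
    stratum is a 1%-wide GC band; strata with fewer than 100 full bins (or a
    zero mean) fall back to the global mean.  Finally RD is rescaled so the
    mean over full bins is exactly 1.
    """
    frame = profile.frame
    full = frame["full"].to_numpy()
    raw = frame["raw_depth"].to_numpy(dtype=float)
    strata = np.clip(np.round(frame["gc"].to_numpy() * 100).astype(int), 0, 100)
    global_mean = raw[full].mean()
    corrected = raw.copy()
    if global_mean > 0:
        for st in np.unique(strata):
            sel = strata == st
            sel_full = sel & full
            if sel_full.sum() >= _GC_MIN_BINS:
                sm = raw[sel_full].mean()
                if sm > 0:
                    corrected[sel] = raw[sel] * (global_mean / sm)
        mean_corr = corrected[full].mean()
        if mean_corr > 0:
            corrected = corrected / mean_corr
    out = frame.copy()
    out["corrected_rd"] = corrected
    return DepthProfile(
        frame=out,
        bin_size=profile.bin_size,
        read_length=profile.read_length,
        corrected=True,
        meta=dict(profile.meta, global_mean_raw=float(global_mean)),
    )


def depth_sd_ratio(
    placements: Placements, genome: GenomeSequence, bin_size: int
) -> float:
    """mean(raw_depth) / sd(raw_depth) over full bins (raw counts, no GC)."""
    prof = bin_depth(placements, genome, bin_size)
    raw = prof.frame.loc[prof.frame["full"], "raw_depth"].to_numpy()
    sd = raw.std()
    return float(raw.mean() / sd) if sd > 0 else float("inf")


def select_bin_size(
    placements: Placements,
    genome: GenomeSequence,
    candidates: Sequence[int] = (100, 200, 300, 500),
) -> int:
    """Smallest bin size whose depth signal-to-noise ratio lies in [4, 5].

    The ratio is mean/sd of the raw binned depth over full bins; under
    near-Poisson counts it grows like sqrt(expected reads per bin), so
    deeper coverage admits smaller bins.  If no candidate lands in [4, 5]
    the one closest to 4.5 is returned with a warning.
    """
    if not candidates:
        raise ValueError("no candidate bin sizes")
    cands = sorted(int(c) for c in candidates)
    ratios = {c: depth_sd_ratio(placements, genome, c) for c in cands}
    for c in cands:
        if 4.0 <= ratios[c] <= 5.0:
            return c
    best = min(cands, key=lambda c: abs(ratios[c] - 4.5))
    warnings.warn(
        f"no candidate bin size has depth SNR in [4, 5] "
        f"(ratios: {ratios}); falling back to {best}",
        stacklevel=2,
    )
    return best
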