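"""Segmentation of the corrected RD signal into candidate CNV calls.

A deliberately simple, deterministic segmenter: smooth RD with a centered
moving average, flag bins below/above fixed loss/gain thresholds, merge
nearby same-direction runs, drop short runs, and score each surviving run
with its unsmoothed mean RD, a two-sided one-sample t-test against 1.0, and
the read-weighted mean q0.  The flag thresholds (0.75 / 1.25) sit strictly
between neutrality and the downstream classifier's cut-offs (0.7 / 1.2-1.5)
so candidate generation never pre-empts classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .depth import DepthProfile


@dataclass
class SegmentParams:
    smooth_window: int = 3  # centered moving-average width, bins
    merge_gap: int = 2  # same-direction runs separated by < this many bins merge
    loss_threshold: float = 0.75
    gain_threshold: float = 1.25
    min_length: int = 1000  # bp


@dataclass
class CNVCall:
    chrom: str
    start: int
    end: int
    rd: float
    p_value: float
    q0: float
    direction: str  # "loss" | "gain"
    genotype: Optional[object] = None  # GenotypeClass, set by classification

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2], edges[1::2]))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def segment(profile: DepthProfile, params: SegmentParams | None = None) -> list[CNVCall]:
    """Emit non-overlapping loss/gain calls per chromosome."""
    if not profile.corrected:
        raise ValueError("profile must be GC-corrected before segmentation")
    params = params or SegmentParams()
    w = params.smooth_window
    calls: list[CNVCall] = []
    for chrom in profile.frame["chrom"].unique():
        sub = profile.chrom_view(chrom)
        if len(sub) < w:
            raise ValueError(f"chromosome {chrom} has fewer bins than the smoothing window")
        rd = sub["corrected_rd"].to_numpy(dtype=float)
        counts = sub["read_count"].to_numpy(dtype=float)
        q0r = sub["q0_reads"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        smoothed = (
            sub["corrected_rd"].rolling(w, center=True, min_periods=1).mean().to_numpy()
        )
        for direction, flags in (
            ("loss", smoothed < params.loss_threshold),
            ("gain", smoothed > params.gain_threshold),
        ):
            for s, e in _merge_runs(_runs(flags), params.merge_gap):
                bp_start, bp_end = int(starts[s]), int(ends[e - 1])
                if bp_end - bp_start < params.min_length:
                    continue
                vals = rd[s:e]
                if vals.size >= 2 and np.ptp(vals) > 0:
                    p = float(stats.ttest_1samp(vals, 1.0).pvalue)
                else:
                    p = 0.0 if (vals.size and vals[0] != 1.0) else 1.0
                total = counts[s:e].sum()
                q0 = float(q0r[s:e].sum() / total) if total > 0 else 0.0
                calls.append(
                    CNVCall(
                        chrom=str(chrom),
                        start=bp_start,
                        end=bp_end,
                        rd=float(vals.mean()),
                        p_value=p,
                        q0=q0,
                        direction=direction,
                    )
                )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls
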