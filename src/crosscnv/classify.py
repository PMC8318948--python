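"""Cross-species genotype classification of CNV calls.

Read depth (RD) is measured on the reference; the reads come from the test
genome.  The same RD deficit can therefore mean a deletion in the test
genome (reads simply missing: low q0) or extra copies in the reference
(reads present but split across the copies: high q0).  The four classes are
total, mutually exclusive regions of (rd, p, q0) space; everything else —
including every exact boundary value, since all comparisons are strict — is
discarded as unclassifiable.

    DEL_TEST      rd < 0.7  and p < 0.05 and q0 < 0.2   deletion in test genome
    DUP_TEST      rd > 1.5  and p < 0.05 and q0 < 0.2   duplication in test genome
    DUP_REF       rd < 0.7  and p < 0.05 and q0 > 0.7   duplication in reference
    DUP_REF_BOTH  rd > 1.20 and p < 0.05 and q0 > 0.7   duplicated in both;
                                                        reported as a ratio
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .caller import CNVCall


class GenotypeClass(enum.Enum):
    DEL_TEST = "deletion in test genome"
    DUP_TEST = "duplication in test genome"
    DUP_REF = "duplication in reference genome"
    DUP_REF_BOTH = "duplicated in reference, elevated in test"
    DISCARD = "unclassifiable"


@dataclass
class FilterThresholds:
    rd_loss: float = 0.7
    rd_gain_test: float = 1.5
    rd_gain_both: float = 1.20
    p_max: float = 0.05
    q0_unique_max: float = 0.2
    q0_multi_min: float = 0.7

    def __post_init__(self) -> None:
        if not (self.rd_loss < self.rd_gain_both < self.rd_gain_test):
            raise ValueError("thresholds must satisfy rd_loss < rd_gain_both < rd_gain_test")
        if not self.q0_unique_max < self.q0_multi_min:
            raise ValueError("q0_unique_max must be below q0_multi_min")


@dataclass
class CopyEstimate:
    ref_copies: Optional[int]
    test_copies: Optional[int]
    ratio: Optional[float] = None
    note: str = ""


def classify_call(call: CNVCall, t: FilterThresholds | None = None) -> GenotypeClass:
    """Total classification of one call; strict inequalities throughout."""
    t = t or FilterThresholds()
    rd, p, q0 = call.rd, call.p_value, call.q0
    if p < t.p_max:
        if q0 < t.q0_unique_max:
            if rd < t.rd_loss:
                return GenotypeClass.DEL_TEST
            if rd > t.rd_gain_test:
                return GenotypeClass.DUP_TEST
        elif q0 > t.q0_multi_min:
            if rd < t.rd_loss:
                return GenotypeClass.DUP_REF
            if rd > t.rd_gain_both:
                return GenotypeClass.DUP_REF_BOTH
    return GenotypeClass.DISCARD


def estimate_copies(call: CNVCall, cls: GenotypeClass) -> CopyEstimate:
    """Copy counts implied by the RD model (E[rd] = test copies / ref copies).

    For a reference duplication sampled from a single-copy test genome,
    rd ~ 1/ref_copies, so ref_copies = floor(1/rd) (an rd of 0.21 reads as
    4 reference copies), never below the definitional minimum of 2.
    """
    if cls is GenotypeClass.DISCARD:
        raise ValueError("cannot estimate copies for a discarded call")
    rd = call.rd
    if cls is GenotypeClass.DUP_REF:
        ref = max(2, math.floor(1.0 / rd)) if rd > 0 else 2
        return CopyEstimate(ref_copies=ref, test_copies=1)
    if cls is GenotypeClass.DEL_TEST:
        return CopyEstimate(ref_copies=1, test_copies=round(rd))
    if cls is GenotypeClass.DUP_TEST:
        return CopyEstimate(ref_copies=1, test_copies=round(rd))
    # DUP_REF_BOTH: both genomes duplicated; absolute counts are not
    # identifiable from a single RD ratio, so report the ratio itself.
    return CopyEstimate(
        ref_copies=None, test_copies=None, ratio=rd, note="both duplicated"
    )


def filter_calls(
    calls: Sequence[CNVCall], t: FilterThresholds | None = None
) -> list[CNVCall]:
    """Order-preserving subset of classifiable calls with genotype attached."""
    t = t or FilterThresholds()
    kept = []
    for call in calls:
        cls = classify_call(call, t)
        if cls is not GenotypeClass.DISCARD:
            call.genotype = cls
            kept.append(call)
    return kept


def class_counts(calls: Sequence[CNVCall]) -> Counter:
    return Counter(c.genotype for c in calls if c.genotype is not None)
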