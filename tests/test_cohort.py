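import numpy as np
import pytest

from crosscnv.caller import CNVCall
from crosscnv.classify import GenotypeClass
from crosscnv.cohort import (
    Interval,
    OverlapParams,
    exclude_known,
    reciprocal_overlap,
    shared_calls,
    summarize,
    SharedCNV,
)


def call(chrom, start, end, cls=GenotypeClass.DUP_REF, rd=0.5):
    c = CNVCall(chrom, start, end, rd, 0.01, 0.9, "loss")
    c.genotype = cls
    return c


def brute_force_reciprocal(a, b):
    if a.chrom != b.chrom:
        return 0.0
    abase = set(range(a.start, a.end))
    bbase = set(range(b.start, b.end))
    inter = len(abase & bbase)
    return min(inter / len(abase), inter / len(bbase))


def test_reciprocal_overlap_analytic_cases():
    assert reciprocal_overlap(Interval("c", 0, 100), Interval("c", 0, 100)) == 1.0
    assert reciprocal_overlap(Interval("c", 0, 100), Interval("c", 50, 150)) == 0.5
    assert reciprocal_overlap(Interval("c", 0, 100), Interval("c", 100, 200)) == 0.0
    assert reciprocal_overlap(Interval("c", 0, 100), Interval("d", 0, 100)) == 0.0
    # asymmetric lengths: the minimum of the one-sided fractions
    assert reciprocal_overlap(Interval("c", 0, 1000), Interval("c", 0, 100)) == 0.1


def test_reciprocal_overlap_matches_per_base_oracle():
    rng = np.random.default_rng(71)
    for _ in range(300):
        s1, s2 = rng.integers(0, 5000, 2)
        a = Interval("c", int(s1), int(s1) + int(rng.integers(1, 5000)))
        b = Interval("c", int(s2), int(s2) + int(rng.integers(1, 5000)))
        assert reciprocal_overlap(a, b) == pytest.approx(brute_force_reciprocal(a, b))


def test_identical_interval_in_all_samples_is_shared():
    sets = [[call("c", 1000, 3000)] for _ in range(3)]
    shared = shared_calls(sets)
    assert len(shared) == 1
    assert (shared[0].start, shared[0].end) == (1000, 3000)
    assert shared[0].cls is GenotypeClass.DUP_REF
    assert len(shared[0].per_sample_calls) == 3


def test_interval_missing_from_one_sample_is_not_shared():
    sets = [[call("c", 1000, 3000)], [call("c", 1000, 3000)], []]
    assert shared_calls(sets) == []


def test_class_must_agree_across_samples():
    sets = [
        [call("c", 1000, 3000, GenotypeClass.DUP_REF)],
        [call("c", 1000, 3000, GenotypeClass.DUP_REF)],
        [call("c", 1000, 3000, GenotypeClass.DEL_TEST)],
    ]
    assert shared_calls(sets) == []


def test_overlap_must_exceed_threshold_reciprocally():
    # 50% reciprocal overlap is NOT > 0.5, so the pair is rejected
    sets = [[call("c", 0, 1000)], [call("c", 500, 1500)]]
    assert shared_calls(sets) == []
    sets = [[call("c", 0, 1000)], [call("c", 400, 1400)]]  # RO = 0.6
    assert len(shared_calls(sets)) == 1


def test_shared_interval_is_union():
    sets = [[call("c", 0, 1000)], [call("c", 200, 1300)]]
    (s,) = shared_calls(sets)
    assert (s.start, s.end) == (0, 1300)


def test_permutation_invariance():
    rng = np.random.default_rng(72)
    samples = []
    for _ in range(3):
        calls = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(2000, 6000))
            length = int(rng.integers(1000, 4000))
            cls = GenotypeClass.DUP_REF if rng.random() < 0.7 else GenotypeClass.DEL_TEST
            calls.append(call("c", pos + int(rng.integers(-300, 300)), pos + length, cls))
        samples.append(calls)

    def key(shared):
        return sorted((s.chrom, s.start, s.end, s.cls.name) for s in shared)

    base = key(shared_calls(samples))
    assert key(shared_calls([samples[2], samples[0], samples[1]])) == base
    assert key(shared_calls([samples[1], samples[2], samples[0]])) == base


def test_shared_count_bounded_by_smallest_sample():
    rng = np.random.default_rng(73)
    samples = [
        [call("c", i * 10_000, i * 10_000 + 2000) for i in range(n)] for n in (5, 3, 8)
    ]
    assert len(shared_calls(samples)) <= 3


def test_mixed_genome_builds_rejected():
    sets = [[call("chr1", 0, 1000)], [call("1", 0, 1000)]]
    with pytest.raises(ValueError, match="mismatch"):
        shared_calls(sets)


def test_unclassified_calls_rejected():
    c = CNVCall("c", 0, 1000, 0.5, 0.01, 0.9, "loss")
    with pytest.raises(ValueError, match="classified"):
        shared_calls([[c], [call("c", 0, 1000)]])


def shared(chrom, start, end, cls=GenotypeClass.DUP_REF):
    return SharedCNV(chrom=chrom, start=start, end=end, cls=cls)


def test_exclude_known_fraction_rule():
    known = [("c", 0, 200)]
    kept = exclude_known([shared("c", 0, 1000)], known)  # 20% covered -> dropped
    assert kept == []
    kept = exclude_known([shared("c", 150, 1150)], known)  # 50 of 1000 -> retained
    assert len(kept) == 1


def test_exclude_known_merges_overlapping_regions():
    # two known regions overlap; merged they cover 120 bp of 1000 (> 10%)
    known = [("c", 0, 100), ("c", 50, 120)]
    assert exclude_known([shared("c", 0, 1000)], known) == []


def test_exclude_known_idempotent_and_monotone():
    rng = np.random.default_rng(74)
    loci = [
        shared("c", int(s), int(s) + int(rng.integers(1000, 5000)))
        for s in rng.integers(0, 500_000, 40)
    ]
    known = [("c", int(s), int(s) + int(rng.integers(200, 3000))) for s in rng.integers(0, 500_000, 30)]
    once = exclude_known(loci, known)
    twice = exclude_known(once, known)
    assert twice == once
    assert len(once) <= len(loci)


def test_summarize_median_is_lower_middle():
    loci = [shared("c", 0, 1000), shared("c", 0, 2000), shared("c", 0, 3000)]
    s = summarize(loci)
    assert s["median_length"] == 2000
    s4 = summarize(loci + [shared("c", 0, 4000)])
    assert s4["median_length"] == 2000  # lower of the two middle values


def test_summarize_single_and_empty():
    one = summarize([shared("c", 0, 1500)])
    assert one["min_length"] == one["median_length"] == one["max_length"] == 1500
    empty = summarize([])
    assert empty["n"] == 0 and empty["total_bp"] == 0 and empty["median_length"] == 0


def test_summarize_class_counts_and_genome_fraction():
    loci = [
        shared("c", 0, 1000, GenotypeClass.DUP_REF),
        shared("c", 5000, 7000, GenotypeClass.DEL_TEST),
    ]
    s = summarize(loci, genome_size=100_000)
    assert s["class_counts"] == {"DUP_REF": 1, "DEL_TEST": 1}
    assert s["genome_fraction"] == pytest.approx(0.03)


def test_overlap_params_validated():
    with pytest.raises(ValueError):
        OverlapParams(min_shared_frac=0.0)
    with pytest.raises(ValueError):
        OverlapParams(max_known_frac=1.0)
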