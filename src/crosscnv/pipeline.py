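"""End-to-end synthetic benchmark: simulate → place → profile → call → score.

This is the built-in validation experiment: plant one 2-copy and one 4-copy
tandem duplication per chromosome of a copy-number-neutral reference,
sequence the *unmodified* genome (the test species carries a single copy of
every unit), place the reads against the spiked reference, and recover the
reference-duplication signature (RD ~ 1/copies, q0 ~ 1) with the caller and
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align, caller, classify, depth, evaluate, reads, spikein
from .genome import GenomeSequence, generate_reference


@dataclass
class BenchmarkConfig:
    n_chroms: int = 10
    chrom_length: int = 1_000_000
    gc_target: float = 0.42
    per_chrom: int = 2
    copy_numbers: tuple[int, ...] = (2, 4)
    size_range: tuple[int, int] = (3000, 10000)
    coverage: float = 30.0
    read_length: int = 150
    error_rate: float = 0.001
    bin_size: int = 100
    max_mismatches: int = 2
    seed: int = 1


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    reference: GenomeSequence  # unmodified (test-genome) reference
    spiked: GenomeSequence
    truth: list[spikein.SpikeInTruth]
    placements: align.Placements
    profile: depth.DepthProfile
    calls: list[caller.CNVCall]
    matches: list[evaluate.TruthMatch] = field(default_factory=list)

    def rd_over_truth(self, copies: int) -> float:
        """Mean corrected RD across truth arrays with the given copy number
        (per-site means averaged)."""
        site_means = [
            self.profile.mean_rd(*t.truth_interval)
            for t in self.truth
            if t.ref_copies == copies
        ]
        return float(np.mean(site_means))

    def min_site_q0(self) -> float:
        """Minimum across detected sites of the matched call's read-weighted q0."""
        q0s = [m.call.q0 for m in self.matches if m.matched]
        if not q0s:
            raise ValueError("no detected sites")
        return float(min(q0s))


def run_benchmark(config: BenchmarkConfig | None = None) -> BenchmarkResult:
    cfg = config or BenchmarkConfig()
    rng = np.random.default_rng(cfg.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    reference = generate_reference(
        cfg.n_chroms,
        cfg.chrom_length,
        gc_target=cfg.gc_target,
        seed=sub[0],
        unique_k=cfg.read_length,
    )
    plan = spikein.plan_spikeins(
        reference,
        per_chrom=cfg.per_chrom,
        copy_numbers=cfg.copy_numbers,
        size_range=cfg.size_range,
        seed=sub[1],
    )
    spiked, truth = spikein.apply_spikeins(reference, plan)

    readset = reads.simulate_reads(
        reference,
        coverage=cfg.coverage,
        read_length=cfg.read_length,
        error_rate=cfg.error_rate,
        seed=sub[2],
    )
    placements = align.place_reads(
        readset, spiked, max_mismatches=cfg.max_mismatches, seed=sub[3]
    )
    profile = depth.gc_correct(depth.bin_depth(placements, spiked, cfg.bin_size), spiked)
    calls = caller.segment(profile)
    matches = evaluate.match_calls(calls, truth)
    return BenchmarkResult(
        config=cfg,
        reference=reference,
        spiked=spiked,
        truth=truth,
        placements=placements,
        profile=profile,
        calls=calls,
        matches=matches,
    )


def benchmark_report(result: BenchmarkResult) -> str:
    confusion = evaluate.confusion_matrix(result.matches)
    filtered = classify.filter_calls(list(result.calls))
    from .cohort import summarize

    # single-sample run: summarize the classified calls as pseudo-shared loci
    from .cohort import SharedCNV

    pseudo = [
        SharedCNV(chrom=c.chrom, start=c.start, end=c.end, cls=c.genotype, per_sample_calls=[c])
        for c in filtered
    ]
    return evaluate.report(
        result.truth,
        result.matches,
        confusion=confusion,
        cohort_summary=summarize(pseudo, genome_size=result.spiked.total_length),
    )
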