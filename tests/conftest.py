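import numpy as np
import pytest

from crosscnv.align import Placements
from crosscnv.genome import GenomeSequence, generate_reference
from crosscnv.pipeline import BenchmarkConfig, run_benchmark


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeSequence:
    """20 kbp single-chromosome unique-background genome."""
    return generate_reference(1, 20_000, gc_target=0.42, seed=101, unique_k=150)


@pytest.fixture(scope="session")
def small_benchmark():
    """End-to-end synthetic run small enough for the unit-test suite.

    Two chromosomes of 300 kbp, one 2-copy and one 4-copy spike-in each with
    units of 5-8 kbp, 30x single-end 150 bp reads.
    """
    cfg = BenchmarkConfig(
        n_chroms=2,
        chrom_length=300_000,
        size_range=(5000, 8000),
        seed=7,
    )
    return run_benchmark(cfg)


def make_placements(
    genome: GenomeSequence,
    pos_by_chrom: dict[str, np.ndarray],
    mapq_by_chrom: dict[str, np.ndarray] | None = None,
    read_length: int = 150,
) -> Placements:
    """Hand-build a Placements object from per-chromosome start arrays."""
    names = genome.names
    cis, poss, mqs = [], [], []
    for ci, name in enumerate(names):
        p = np.asarray(pos_by_chrom.get(name, []), dtype=np.int64)
        cis.append(np.full(p.size, ci, dtype=np.int32))
        poss.append(p)
        if mapq_by_chrom and name in mapq_by_chrom:
            mqs.append(np.asarray(mapq_by_chrom[name], dtype=np.int16))
        else:
            mqs.append(np.full(p.size, 60, dtype=np.int16))
    pos = np.concatenate(poss) if poss else np.empty(0, dtype=np.int64)
    mapq = np.concatenate(mqs) if mqs else np.empty(0, dtype=np.int16)
    return Placements(
        chrom_names=list(names),
        read_length=read_length,
        read_id=np.arange(pos.size, dtype=np.int64),
        chrom_index=np.concatenate(cis) if cis else np.empty(0, dtype=np.int32),
        pos=pos,
        mapq=mapq,
        n_best_hits=np.where(mapq == 0, 2, 1).astype(np.int32),
    )
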