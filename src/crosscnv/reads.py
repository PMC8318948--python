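"""Single-end read simulation.

Reads are drawn with uniform start positions across all chromosomes (each
chromosome weighted by its number of valid full-length starts), carry i.i.d.
per-base substitution errors, and are stored as an array-backed set rather
than per-read objects: ``sequences`` is an (n_reads, read_length) uint8
matrix in the package's 0..3 encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeSequence


@dataclass
class ReadSet:
    chrom_names: list[str]
    chrom_index: np.ndarray  # (n,) int32 — index into chrom_names
    start: np.ndarray  # (n,) int64 — 0-based source position
    sequences: np.ndarray  # (n, read_length) uint8
    read_length: int

    def __len__(self) -> int:
        return self.start.size

    def to_fastq(self, path) -> None:
        from .io import write_fastq

        write_fastq(self, path)


def simulate_reads(
    genome: GenomeSequence,
    coverage: float = 30.0,
    read_length: int = 150,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Simulate ``round(coverage * genome_length / read_length)`` reads.

    Forward-strand, single-end; substitution errors only.  Deterministic
    given the seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_length < 50:
        raise ValueError("read_length must be >= 50")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    names = genome.names
    n_reads = int(round(coverage * genome.total_length / read_length))

    valid = np.array([genome.length(n) - read_length + 1 for n in names], dtype=np.int64)
    if (valid <= 0).any():
        short = names[int(np.argmax(valid <= 0))]
        raise ValueError(f"chromosome {short} shorter than the read length")
    offsets = np.concatenate([[0], np.cumsum(valid)])
    flat = rng.integers(0, offsets[-1], size=n_reads)
    chrom_index = (np.searchsorted(offsets, flat, side="right") - 1).astype(np.int32)
    start = flat - offsets[chrom_index]

    sequences = np.empty((n_reads, read_length), dtype=np.uint8)
    for ci, name in enumerate(names):
        mask = chrom_index == ci
        if mask.any():
            windows = np.lib.stride_tricks.sliding_window_view(
                genome.encoded(name), read_length
            )
            sequences[mask] = windows[start[mask]]

    if error_rate > 0:
        # draw the genome-wide error count once, then scatter flat positions;
        # equivalent to i.i.d. per-base errors up to negligible collisions
        n_err = rng.binomial(n_reads * read_length, error_rate)
        if n_err:
            flat_idx = rng.integers(0, n_reads * read_length, size=n_err)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            flat = sequences.reshape(-1)
            flat[flat_idx] = (flat[flat_idx] + shift) % 4

    return ReadSet(
        chrom_names=list(names),
        chrom_index=chrom_index,
        start=start.astype(np.int64),
        sequences=sequences,
        read_length=read_length,
    )
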