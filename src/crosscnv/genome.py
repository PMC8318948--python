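"""Synthetic reference genomes with a copy-number-neutral background.

The generator draws i.i.d. bases at a target GC content and then verifies
that no k-mer of read length occurs twice anywhere in the genome (a k-mer
uniqueness screen).  A background with no exact repeat at read scale is
copy-number neutral by construction: every read placed against it has a
single best hit, so read depth is flat and q0 is zero outside planted
duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import decode_sequence, encode_sequence

#: multiplier for the 64-bit rolling k-mer hash (FNV prime); collisions are
#: resolved by exact comparison before declaring a duplicate.
_HASH_BASE = np.uint64(1099511628211)


class GenomeGenerationError(RuntimeError):
    """Raised when a unique-background genome cannot be produced."""


@dataclass
class GenomeSequence:
    """Named chromosomes with A/C/G/T sequence.

    ``chromosomes`` preserves insertion order; names are unique by dict
    construction.  Encoded uint8 views are cached per chromosome.
    """

    chromosomes: dict[str, str]
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def encoded(self, name: str) -> np.ndarray:
        """uint8 (0..3) view of a chromosome; validates the alphabet once."""
        arr = self._encoded.get(name)
        if arr is None:
            arr = encode_sequence(self.chromosomes[name])
            self._encoded[name] = arr
        return arr


def _kmer_hashes(arr: np.ndarray, k: int) -> np.ndarray:
    """Rolling 64-bit polynomial hash of every k-window (wraparound arithmetic)."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    a = arr.astype(np.uint64)
    for j in range(k):
        h = h * _HASH_BASE + a[j : j + n]
    return h


def duplicate_kmer_count(genome: GenomeSequence, k: int) -> int:
    """Number of k-mers occurring more than once genome-wide (exact).

    Hash-based prefilter; hash ties are verified by comparing the actual
    windows so a hash collision never counts as a duplicate.
    """
    hashes = []
    where = []  # (chrom index, position)
    for ci, name in enumerate(genome.names):
        h = _kmer_hashes(genome.encoded(name), k)
        hashes.append(h)
        where.append(
            np.stack(
                [np.full(h.size, ci, dtype=np.int64), np.arange(h.size, dtype=np.int64)],
                axis=1,
            )
        )
    allh = np.concatenate(hashes)
    allw = np.concatenate(where)
    order = np.argsort(allh, kind="stable")
    allh, allw = allh[order], allw[order]
    same = np.flatnonzero(allh[1:] == allh[:-1])
    dup = 0
    names = genome.names
    for i in same:
        (c1, p1), (c2, p2) = allw[i], allw[i + 1]
        s1 = genome.encoded(names[c1])[p1 : p1 + k]
        s2 = genome.encoded(names[c2])[p2 : p2 + k]
        if np.array_equal(s1, s2):
            dup += 1
    return dup


def generate_reference(
    n_chroms: int,
    chrom_length: int,
    gc_target: float = 0.42,
    seed: int = 0,
    unique_k: int = 150,
    max_attempts: int = 5,
) -> GenomeSequence:
    """Generate a random genome with no repeated ``unique_k``-mer.

    Parameters
    ----------
    n_chroms, chrom_length
        Number of chromosomes (named ``chr1`` ...) and their common length.
    gc_target
        Expected GC fraction of the i.i.d. base draw, in (0, 1).
    unique_k
        Word size of the uniqueness screen; use the read length so that the
        background is copy-number neutral for that read length.
    max_attempts
        Bounded retry count; exceeding it raises ``GenomeGenerationError``
        rather than looping silently.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must be in (0, 1)")
    if chrom_length < unique_k:
        raise ValueError("chrom_length shorter than the uniqueness word size")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    cum = np.cumsum(p)
    for _ in range(max_attempts):
        chroms = {
            f"chr{i + 1}": decode_sequence(
                np.searchsorted(cum, rng.random(int(chrom_length))).astype(np.uint8)
            )
            for i in range(n_chroms)
        }
        genome = GenomeSequence(chroms)
        if duplicate_kmer_count(genome, unique_k) == 0:
            return genome
    raise GenomeGenerationError(
        f"could not generate a genome free of duplicate {unique_k}-mers "
        f"in {max_attempts} attempts (length {chrom_length}, GC {gc_target})"
    )
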