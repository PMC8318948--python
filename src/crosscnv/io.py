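"""Sequence encoding and on-disk formats.

Nucleotides are encoded A=0, C=1, G=2, T=3 in uint8 arrays; everything
numeric in the package works on these arrays.  Coordinates are 0-based
half-open internally; FASTA/GFF3 1-based conventions are converted at
this boundary only.
"""

from __future__ import annotations

import io as _io
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .genome import GenomeSequence
    from .reads import ReadSet

_BASES = b"ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(_BASES, dtype=np.uint8)


class BedFormatError(ValueError):
    """Malformed BED line; message carries the 1-based line number."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string into a uint8 array (0..3)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = np.flatnonzero(arr > 3)[0]
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return arr


def decode_sequence(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def read_fasta(path) -> "GenomeSequence":
    from Bio import SeqIO

    from .genome import GenomeSequence

    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(chroms)


def write_fasta(genome: "GenomeSequence", path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: "ReadSet", path) -> None:
    qual = "I" * reads.read_length
    with open(path, "w") as fh:
        for i in range(len(reads)):
            fh.write(
                f"@read{i}\n{decode_sequence(reads.sequences[i])}\n+\n{qual}\n"
            )


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read the first three BED columns; 0-based half-open on disk and in memory."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if end <= start or start < 0:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            out.append((fields[0], start, end))
    return out


def write_bed(records: Iterable[tuple], path) -> None:
    """Write BED rows; each record is a tuple of 3-6 fields."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def load_gene_models(gff3_path):
    """Parse GFF3 gene models via gffutils (in-memory db).

    Returns a list of :class:`crosscnv.annotate.GeneModel`.  GFF3 is 1-based
    inclusive; coordinates are converted to 0-based half-open here.
    """
    import gffutils

    from .annotate import GeneModel

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(g, featuretype="exon", order_by="start")
        ]
        utrs = [
            (f.start - 1, f.end)
            for f in db.children(
                g,
                featuretype=("five_prime_UTR", "three_prime_UTR", "UTR"),
                order_by="start",
            )
        ]
        biotype = g.attributes.get("biotype", g.attributes.get("gene_biotype", ["protein_coding"]))[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                biotype=biotype,
                exons=exons,
                utrs=utrs,
            )
        )
    return genes


def calls_to_frame(calls):
    """Tabulate CNV calls (list of CNVCall) into a pandas DataFrame."""
    import pandas as pd

    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "rd": c.rd,
            "p_value": c.p_value,
            "q0": c.q0,
            "direction": c.direction,
            "genotype": getattr(c.genotype, "name", "") if c.genotype else "",
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "rd", "p_value", "q0", "direction", "genotype"],
    )


def frame_to_calls(frame):
    from .caller import CNVCall
    from .classify import GenotypeClass

    import pandas as pd

    calls = []
    for row in frame.itertuples(index=False):
        geno = getattr(row, "genotype", "")
        if pd.isna(geno):
            geno = None
        calls.append(
            CNVCall(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                rd=float(row.rd),
                p_value=float(row.p_value),
                q0=float(row.q0),
                direction=row.direction,
                genotype=GenotypeClass[geno] if geno else None,
            )
        )
    return calls


def read_calls_tsv(path):
    import pandas as pd

    return frame_to_calls(pd.read_csv(path, sep="\t"))


def write_calls_tsv(calls, path):
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
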