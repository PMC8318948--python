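"""Gene-model annotation of shared CNVs and tandem-duplication checks.

Region categories per (CNV, gene) pair, in precedence order:

    whole_gene  CNV contains the entire transcript span
    exonic      CNV intersects at least one exon
    UTR         CNV intersects a UTR but no exon interval
    intronic    CNV lies inside the span touching no exon/UTR
    upstream /  CNV within ``flank`` bp of the span on the
    downstream  strand-appropriate side
    intergenic  none of the above

A CNV hitting several genes takes the highest-precedence category among
them.  ``tandem_check`` reproduces the dot-plot reading used to confirm
reference tandem duplications: an off-main-diagonal self-match run parallel
to the diagonal marks a tandem array; failing that, a long high-identity
match elsewhere in the genome marks a dispersed (segmental) duplicate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .io import encode_sequence

CATEGORY_ORDER = [
    "whole_gene",
    "exonic",
    "UTR",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
]
_RANK = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # transcript span, 0-based half-open
    end: int
    strand: str  # "+" | "-"
    biotype: str = "protein_coding"
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty span")
        for s, e in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


def _intersects(s1: int, e1: int, ivals: Sequence[tuple[int, int]]) -> bool:
    return any(min(e1, e) > max(s1, s) for s, e in ivals)


def classify_region(cnv, gene: GeneModel, flank: int = 5000) -> str:
    """Category of one CNV relative to one gene (total, one answer)."""
    if cnv.chrom != gene.chrom:
        return "intergenic"
    s, e = cnv.start, cnv.end
    if s <= gene.start and e >= gene.end:
        return "whole_gene"
    if _intersects(s, e, gene.exons):
        return "exonic"
    if _intersects(s, e, gene.utrs):
        return "UTR"
    if min(e, gene.end) > max(s, gene.start):
        return "intronic"
    # strand-appropriate flanks
    if gene.strand == "+":
        up = (gene.start - flank, gene.start)
        down = (gene.end, gene.end + flank)
    else:
        up = (gene.end, gene.end + flank)
        down = (gene.start - flank, gene.start)
    if min(e, up[1]) > max(s, up[0]):
        return "upstream"
    if min(e, down[1]) > max(s, down[0]):
        return "downstream"
    return "intergenic"


def annotate_set(
    shared: Sequence, genes: Sequence[GeneModel], flank: int = 5000
) -> pd.DataFrame:
    """Per-CNV category (highest precedence across genes), genes and biotypes."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    if shared and by_chrom:
        cnv_chroms = {c.chrom for c in shared}
        if not cnv_chroms & set(by_chrom):
            raise ValueError(
                "chromosome names of the call set do not match the gene models"
            )
    rows = []
    for cnv in shared:
        hits: list[tuple[str, GeneModel]] = []
        for g in by_chrom.get(cnv.chrom, []):
            cat = classify_region(cnv, g, flank=flank)
            if cat != "intergenic":
                hits.append((cat, g))
        if hits:
            category = min((h[0] for h in hits), key=_RANK.__getitem__)
            gene_ids = sorted({g.gene_id for _, g in hits})
            biotypes = Counter(g.biotype for _, g in hits)
        else:
            category, gene_ids, biotypes = "intergenic", [], Counter()
        rows.append(
            {
                "chrom": cnv.chrom,
                "start": cnv.start,
                "end": cnv.end,
                "class": getattr(getattr(cnv, "cls", None), "name", ""),
                "category": category,
                "genes": ",".join(gene_ids),
                "biotypes": ";".join(f"{k}:{v}" for k, v in sorted(biotypes.items())),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "class", "category", "genes", "biotypes"]
    )


def category_counts(annotation: pd.DataFrame) -> dict[str, int]:
    counts = annotation["category"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CATEGORY_ORDER}


def _kmer_positions(arr: np.ndarray, k: int) -> dict[int, list[int]]:
    pos: dict[int, list[int]] = {}
    code = 0
    mask = (1 << (2 * k)) - 1
    for i, b in enumerate(arr):
        code = ((code << 2) | int(b)) & mask
        if i >= k - 1:
            pos.setdefault(code, []).append(i - k + 1)
    return pos


def tandem_check(
    cnv_sequence: str,
    genome: Optional[GenomeSequence] = None,
    k: int = 11,
    min_identity: float = 0.8,
    exclude: Optional[tuple[str, int, int]] = None,
) -> str:
    """Self dot-plot verdict: ``tandem``, ``dispersed_duplicate`` or ``unique``.

    Tandem: some off-diagonal offset d > 0 whose exact k-word self matches
    cover at least half the sequence.  Dispersed: a gapless k-word chain
    elsewhere in the genome (the source locus can be masked via ``exclude``)
    reaching ``min_identity`` over at least half the sequence.
    """
    seq = encode_sequence(cnv_sequence.upper())
    n = seq.size
    if n < 2 * k:
        raise ValueError(f"sequence length {n} shorter than 2k = {2 * k}")

    kpos = _kmer_positions(seq, k)
    # coverage of the sequence by self-matches at each positive offset
    offset_cover: dict[int, set[int]] = {}
    for positions in kpos.values():
        if len(positions) < 2:
            continue
        for a in positions:
            for b in positions:
                if b > a:
                    offset_cover.setdefault(b - a, set()).add(a)
    for d, starts in offset_cover.items():
        covered = _covered_bases(sorted(starts), k)
        if covered >= 0.5 * n:
            return "tandem"

    if genome is not None:
        for name in genome.names:
            g = genome.encoded(name)
            gpos = _kmer_positions(g, k) if g.size >= k else {}
            # best gapless chain: most common (genome_pos - seq_pos) offset
            diag: Counter = Counter()
            for code, spos in kpos.items():
                for gp in gpos.get(code, []):
                    for sp in spos:
                        diag[gp - sp] += 1
            for d, _count in diag.most_common(5):
                g_start, g_end = d, d + n
                if g_start < 0 or g_end > g.size:
                    continue
                if exclude is not None and exclude[0] == name:
                    if min(g_end, exclude[2]) > max(g_start, exclude[1]):
                        continue
                identity = float((g[g_start:g_end] == seq).mean())
                if identity >= min_identity:
                    return "dispersed_duplicate"
    return "unique"


def _covered_bases(sorted_starts: list[int], k: int) -> int:
    covered = 0
    last_end = -1
    for s in sorted_starts:
        e = s + k
        covered += e - max(s, last_end) if e > last_end else 0
        last_end = max(last_end, e)
    return covered
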