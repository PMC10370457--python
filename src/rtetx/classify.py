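"""Transcript contig classification against gene and repeat annotations.

Assigns each assembled contig an overlap category (gene/RTE 2x2), an intron
category (fully intronic / no intron overlap / other), the set of RTE
classes and subfamilies it touches, and builds terminal position-frequency
matrices from the contigs' spliced sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .annotation import AnnotationBundle, GenomicInterval, TranscriptContig

logger = logging.getLogger(__name__)

PFM_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class OverlapCategory(str, Enum):
    GENE_AND_RTE = "gene_and_rte"
    GENE_ONLY = "gene_only"
    RTE_ONLY = "rte_only"
    NEITHER = "neither"


class IntronCategory(str, Enum):
    FULLY_INTRONIC = "fully_intronic"
    NO_INTRON_OVERLAP = "no_intron_overlap"
    OTHER = "other"


@dataclass
class RteContent:
    transcript_id: str
    classes_hit: set[str]
    subfamilies_hit: set[str]


def overlap_category(
    contig: TranscriptContig, bundle: AnnotationBundle
) -> OverlapCategory:
    """Category from whether any block shares >=1 base with a gene body
    and/or any repeat (strand-agnostic)."""
    hits_gene = any(bundle.genes_overlapping(b) for b in contig.blocks)
    hits_rte = any(bundle.repeats_overlapping(b) for b in contig.blocks)
    if hits_gene and hits_rte:
        return OverlapCategory.GENE_AND_RTE
    if hits_gene:
        return OverlapCategory.GENE_ONLY
    if hits_rte:
        return OverlapCategory.RTE_ONLY
    return OverlapCategory.NEITHER


def intron_category(
    contig: TranscriptContig, bundle: AnnotationBundle
) -> IntronCategory:
    """fully_intronic: every base of every block lies within the introns of a
    single gene.  no_intron_overlap: zero bases overlap any intron of any
    gene.  Everything else: other.

    Containment is required within one gene's introns (blocks may sit in
    different introns of that gene); a contig spread over introns of two
    different genes is classified other.
    """
    hit_genes: set[str] = set()
    any_overlap = False
    for block in contig.blocks:
        for gene_id, _, _ in bundle.introns_overlapping(block):
            any_overlap = True
            hit_genes.add(gene_id)
    if not any_overlap:
        return IntronCategory.NO_INTRON_OVERLAP
    for gene_id in hit_genes:
        gene = bundle.genes_by_id[gene_id]
        if _contained_in_introns(contig, gene.introns):
            return IntronCategory.FULLY_INTRONIC
    return IntronCategory.OTHER


def _contained_in_introns(
    contig: TranscriptContig, introns: list[GenomicInterval]
) -> bool:
    for block in contig.blocks:
        covered = False
        for intron in introns:
            if intron.start <= block.start and block.end <= intron.end:
                covered = True
                break
        if not covered:
            return False
    return True


def rte_group_content(
    contig: TranscriptContig, bundle: AnnotationBundle
) -> RteContent:
    """RTE classes and subfamilies with >=1 base overlap with any block."""
    classes: set[str] = set()
    subfamilies: set[str] = set()
    for block in contig.blocks:
        for rep_id in bundle.repeats_overlapping(block):
            rep = bundle.repeats_by_id[rep_id]
            classes.add(rep.rte_class)
            subfamilies.add(rep.subfamily)
    return RteContent(contig.transcript_id, classes, subfamilies)


def classify_contigs(bundle: AnnotationBundle) -> pd.DataFrame:
    """Classification table for every contig in the bundle.

    Columns: transcript_id, overlap_category, intron_category, classes_hit,
    subfamilies_hit (comma-joined sorted sets).
    """
    rows = []
    for contig in bundle.contigs:
        content = rte_group_content(contig, bundle)
        rows.append(
            {
                "transcript_id": contig.transcript_id,
                "overlap_category": overlap_category(contig, bundle).value,
                "intron_category": intron_category(contig, bundle).value,
                "classes_hit": ",".join(sorted(content.classes_hit)),
                "subfamilies_hit": ",".join(sorted(content.subfamilies_hit)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "overlap_category",
            "intron_category",
            "classes_hit",
            "subfamilies_hit",
        ],
    )


# ---------------------------------------------------------------------------
# Terminal position-frequency matrices
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyMatrix:
    """Base counts per terminal position over {A,C,G,T}.

    counts has shape (4, L) with rows in PFM_ALPHABET order.  Ambiguous
    bases are excluded, so column sums are <= n_sequences.
    """

    counts: np.ndarray
    n_sequences: int
    n_skipped: int = 0

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        colsums = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(colsums > 0, self.counts / colsums, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=list(PFM_ALPHABET),
            columns=[str(i + 1) for i in range(self.length)],
        )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(contig: TranscriptContig, fasta: Fasta) -> str:
    """Concatenated block sequence, reverse-complemented for '-' strand."""
    if contig.chrom not in fasta:
        raise KeyError(f"chromosome {contig.chrom!r} missing from FASTA")
    seq = "".join(
        str(fasta[contig.chrom][b.start:b.end]) for b in contig.blocks
    ).upper()
    if contig.strand == "-":
        seq = reverse_complement(seq)
    return seq


def terminal_pfm(
    contigs: list[TranscriptContig],
    genome_fasta,
    k: int = 40,
    end: str = "three_prime",
) -> PositionFrequencyMatrix:
    """Position-frequency matrix of the terminal ``k`` bases of each contig's
    spliced sequence at the requested end ('five_prime' or 'three_prime').

    Contigs with spliced length < k are skipped (counted in n_skipped).
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    if not contigs:
        raise ValueError("no sequences: empty contig list")
    fasta = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(str(genome_fasta))
    counts = np.zeros((4, k), dtype=int)
    base_index = {b: i for i, b in enumerate(PFM_ALPHABET)}
    n_used = 0
    n_skipped = 0
    for contig in contigs:
        seq = spliced_sequence(contig, fasta)
        if len(seq) < k:
            n_skipped += 1
            continue
        terminal = seq[:k] if end == "five_prime" else seq[-k:]
        for col, base in enumerate(terminal):
            idx = base_index.get(base)
            if idx is not None:
                counts[idx, col] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no sequences: all contigs shorter than k")
    if n_skipped:
        logger.info("terminal_pfm: skipped %d contigs shorter than %d", n_skipped, k)
    return PositionFrequencyMatrix(counts=counts, n_sequences=n_used, n_skipped=n_skipped)
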