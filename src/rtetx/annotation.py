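"""Genomic annotation model and I/O.

Gene models (exon-union structure with derived introns), repeat elements
(RepeatMasker-style subfamily/family/class with LTR-internal merging), and
assembled transcript contigs (BED12 blocks), bundled with per-chromosome
interval indexes.

All internal coordinates are 0-based half-open.  GTF and RepeatMasker-style
tables use 1-based inclusive coordinates on disk and are converted on
read/write, so a single convention holds everywhere in memory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: RepeatMasker class string -> retrotransposon class used throughout.
#: Anything not listed maps to "Other" (with a warning, never dropped).
RTE_CLASS_LOOKUP = {
    "LINE": "LINE",
    "SINE": "SINE",
    "LTR": "LTR",
    "SVA": "SVA",
    "Retroposon": "SVA",  # RepeatMasker files carry SVA as Retroposon/SVA
}

#: Default LTR-internal pairing: internal-model base name -> LTR model
#: patterns (a trailing "*" matches any suffix).  Editable by callers.
DEFAULT_LTR_PAIRING = {
    "HERVH": ("LTR7*",),
    "HERVK": ("LTR5*",),
    "HERVL": ("MLT2*",),
}

INTERNAL_SUFFIX = "-int"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval. strand is '+', '-' or '.' (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared base; half-open abutment does not count."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene as the union of its isoforms' exons.

    ``exons`` is the sorted, disjoint exon union; ``introns`` are the gaps
    inside the gene body, so exons and introns tile the body exactly.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    introns: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has zero exons")
        self.exons = union_intervals(self.exons)
        self.introns = derive_introns_from_union(self.exons)

    @property
    def gene_body(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class RepeatElement:
    repeat_id: str
    interval: GenomicInterval
    subfamily: str
    family: str
    rte_class: str
    genic: bool | None = None  # derived by flag_genic_repeats


@dataclass
class TranscriptContig:
    """An assembled transcript: >=1 sorted disjoint exon blocks."""

    transcript_id: str
    chrom: str
    strand: str
    blocks: list[GenomicInterval]

    def __post_init__(self):
        if not self.blocks:
            raise ValueError(f"contig {self.transcript_id} has no blocks")
        blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(blocks, blocks[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"contig {self.transcript_id} has overlapping blocks"
                )
        self.blocks = blocks

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    @property
    def spliced_length(self) -> int:
        return sum(len(b) for b in self.blocks)


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def union_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sorted disjoint union (merging adjacent/overlapping intervals)."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda i: (i.start, i.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom != last.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def derive_introns_from_union(
    exon_union: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Gaps between consecutive exon-union intervals."""
    return [
        GenomicInterval(a.chrom, a.end, b.start, a.strand)
        for a, b in zip(exon_union, exon_union[1:])
    ]


def derive_introns(gene: GeneModel) -> list[GenomicInterval]:
    """Introns of a gene: gene body minus exon union."""
    return derive_introns_from_union(gene.exons)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def _gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from a GTF (GENCODE/Ensembl dialect).

    Exon records are grouped by gene_id; 1-based inclusive coordinates become
    0-based half-open; the per-gene exon union and introns are derived.
    """
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    strand_by_gene: dict[str, str] = {}
    seen_genes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attr = _gtf_attributes(attrs)
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                seen_genes.add(gene_id)
            if feature != "exon":
                continue
            seen_genes.add(gene_id)
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            exons_by_gene.setdefault(gene_id, []).append(iv)
            strand_by_gene[gene_id] = strand
    exonless = seen_genes - set(exons_by_gene)
    if exonless:
        raise ParseError(
            f"{path}: gene(s) with zero exons: {', '.join(sorted(exonless))}"
        )
    genes = []
    for gene_id in sorted(exons_by_gene):
        exons = exons_by_gene[gene_id]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=exons[0].chrom,
                strand=strand_by_gene[gene_id],
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.gene_body.start, g.gene_id))
    return genes


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write gene + exon records (exon union) in deterministic order."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.gene_body.start, g.gene_id)):
            body = gene.gene_body
            fh.write(
                f"{gene.chrom}\trtetx\tgene\t{body.start + 1}\t{body.end}\t.\t"
                f'{gene.strand}\t.\tgene_id "{gene.gene_id}";\n'
            )
            for exon in gene.exons:
                fh.write(
                    f"{gene.chrom}\trtetx\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f'{gene.strand}\t.\tgene_id "{gene.gene_id}";\n'
                )


# ---------------------------------------------------------------------------
# BED12 I/O
# ---------------------------------------------------------------------------

def read_bed12(path) -> list[TranscriptContig]:
    """Read transcript contigs from BED12 (0-based half-open)."""
    contigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(f)}"
                )
            chrom, chrom_start, chrom_end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if f[5] in STRANDS else "."
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount {block_count} does not match "
                    f"blockSizes/blockStarts lengths"
                )
            blocks = []
            for size, off in zip(sizes, starts):
                b_start = chrom_start + off
                b_end = b_start + size
                if b_end > chrom_end:
                    raise ParseError(
                        f"{path}:{lineno}: block [{b_start},{b_end}) extends "
                        f"past chromEnd {chrom_end}"
                    )
                blocks.append(GenomicInterval(chrom, b_start, b_end, strand))
            contigs.append(TranscriptContig(name, chrom, strand, blocks))
    return contigs


def write_bed12(contigs: list[TranscriptContig], path) -> None:
    with open(path, "w") as fh:
        ordered = sorted(
            contigs, key=lambda c: (c.chrom, c.span.start, c.transcript_id)
        )
        for c in ordered:
            span = c.span
            sizes = ",".join(str(len(b)) for b in c.blocks)
            starts = ",".join(str(b.start - span.start) for b in c.blocks)
            fh.write(
                f"{c.chrom}\t{span.start}\t{span.end}\t{c.transcript_id}\t0\t"
                f"{c.strand}\t{span.start}\t{span.end}\t0\t{len(c.blocks)}\t"
                f"{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Repeat table I/O and LTR-internal merging
# ---------------------------------------------------------------------------

@dataclass
class RepeatRow:
    """One raw repeat annotation row (pre-merge)."""

    chrom: str
    start: int  # 0-based half-open after reading
    end: int
    strand: str
    subfamily: str
    class_family: str  # e.g. "SINE/Alu"

    @property
    def family(self) -> str:
        parts = self.class_family.split("/", 1)
        return parts[1] if len(parts) == 2 else parts[0]

    @property
    def rte_class(self) -> str:
        head = self.class_family.split("/", 1)[0]
        if self.class_family == "Retroposon/SVA" or self.subfamily.startswith("SVA"):
            return "SVA"
        return RTE_CLASS_LOOKUP.get(head, "Other")


def read_repeat_table(path) -> list[RepeatRow]:
    """Read a RepeatMasker-out-dialect TSV.

    Expected tab-separated columns: chrom, start, end, strand, subfamily,
    class/family (1-based inclusive coordinates).  Unknown class strings map
    to Other with a warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(f)}"
                )
            chrom, start, end, strand, subfamily, class_family = f[:6]
            row = RepeatRow(
                chrom=chrom,
                start=int(start) - 1,
                end=int(end),
                strand=strand if strand in STRANDS else ".",
                subfamily=subfamily,
                class_family=class_family,
            )
            if row.rte_class == "Other" and class_family.split("/")[0] not in (
                "DNA",
                "Simple_repeat",
                "Low_complexity",
                "Satellite",
                "Other",
            ):
                warnings.warn(
                    f"unknown repeat class {class_family!r} at {path}:{lineno}; "
                    "mapped to Other"
                )
            rows.append(row)
    return rows


def write_repeat_table(repeats: list[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        ordered = sorted(
            repeats, key=lambda r: (r.interval.chrom, r.interval.start, r.repeat_id)
        )
        for r in ordered:
            class_family = (
                f"{r.rte_class}/{r.family}" if r.family != r.rte_class else r.rte_class
            )
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start + 1}\t{r.interval.end}\t"
                f"{r.interval.strand}\t{r.subfamily}\t{class_family}\n"
            )


def _pattern_match(name: str, pattern: str) -> bool:
    if pattern.endswith("*"):
        return name.startswith(pattern[:-1])
    return name == pattern


def _element_base(subfamily: str) -> str | None:
    """Base name of an internal repeat model, or None if not internal."""
    if subfamily.endswith(INTERNAL_SUFFIX):
        return subfamily[: -len(INTERNAL_SUFFIX)]
    return None


def _belongs_to(subfamily: str, base: str, pairing: dict) -> bool:
    """True if ``subfamily`` is part of element ``base`` (internal or LTR)."""
    if subfamily == base + INTERNAL_SUFFIX:
        return True
    return any(_pattern_match(subfamily, p) for p in pairing.get(base, ()))


def _mergeable(a: RepeatRow, b: RepeatRow, gap_tolerance: int, pairing: dict) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if b.start - a.end > gap_tolerance:
        return False
    for row, other in ((a, b), (b, a)):
        base = _element_base(row.subfamily)
        if base is not None and _belongs_to(other.subfamily, base, pairing):
            return True
    return False


def merge_ltr_internal(
    rows: list[RepeatRow],
    gap_tolerance: int = 100,
    pairing: dict | None = None,
) -> list[RepeatElement]:
    """Merge adjacent LTR and internal annotations of the same element.

    Repeat annotators report the LTRs and the internal region of a provirus
    separately; consecutive same-strand rows whose models belong together
    (internal model paired to its LTR model via ``pairing``; default rule
    strips the "-int" suffix) and lie within ``gap_tolerance`` bases merge
    into a single element named after the internal model's base name.  All
    other rows pass through unchanged.  Idempotent: merged elements carry the
    base name, which is never an internal model.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be non-negative")
    if pairing is None:
        pairing = DEFAULT_LTR_PAIRING
    rows = sorted(rows, key=lambda r: (r.chrom, r.start, r.end))
    elements: list[RepeatElement] = []
    chain: list[RepeatRow] = []

    def flush(chain: list[RepeatRow]) -> None:
        internals = [r for r in chain if _element_base(r.subfamily)]
        if len(chain) > 1 and internals:
            rep = internals[0]
            base = _element_base(rep.subfamily)
            elements.append(
                RepeatElement(
                    repeat_id="",
                    interval=GenomicInterval(
                        chain[0].chrom, chain[0].start, chain[-1].end, chain[0].strand
                    ),
                    subfamily=base,
                    family=rep.family,
                    rte_class=rep.rte_class,
                )
            )
        else:
            for r in chain:
                elements.append(
                    RepeatElement(
                        repeat_id="",
                        interval=GenomicInterval(r.chrom, r.start, r.end, r.strand),
                        subfamily=r.subfamily,
                        family=r.family,
                        rte_class=r.rte_class,
                    )
                )

    for row in rows:
        if chain and _mergeable(chain[-1], row, gap_tolerance, pairing):
            chain.append(row)
        else:
            if chain:
                flush(chain)
            chain = [row]
    if chain:
        flush(chain)

    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    for i, el in enumerate(elements):
        el.repeat_id = f"rep{i:06d}"
    return elements


# ---------------------------------------------------------------------------
# Genic flagging and the bundle
# ---------------------------------------------------------------------------

def _build_tree(intervals: list[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def flag_genic_repeats(
    repeats: list[RepeatElement], genes: list[GeneModel]
) -> list[RepeatElement]:
    """Set genic=True iff the repeat shares >=1 base with any gene body.

    Strand-agnostic, matching the usual genic-repeat definition; introns
    count because the test is against the gene body, not exons.
    """
    trees = _build_tree([(g.gene_body, g.gene_id) for g in genes])
    for rep in repeats:
        tree = trees.get(rep.interval.chrom)
        rep.genic = bool(tree and tree.overlap(rep.interval.start, rep.interval.end))
    return repeats


class AnnotationBundle:
    """Genes, repeats and contigs with per-chromosome interval indexes."""

    def __init__(
        self,
        genes: list[GeneModel],
        repeats: list[RepeatElement],
        contigs: list[TranscriptContig],
    ):
        self.genes = genes
        self.repeats = repeats
        self.contigs = contigs
        self.genes_by_id = {g.gene_id: g for g in genes}
        self.repeats_by_id = {r.repeat_id: r for r in repeats}
        self.contigs_by_id = {c.transcript_id: c for c in contigs}
        if len(self.genes_by_id) != len(genes):
            raise ValueError("duplicate gene ids")
        if len(self.repeats_by_id) != len(repeats):
            raise ValueError("duplicate repeat ids")
        if len(self.contigs_by_id) != len(contigs):
            raise ValueError("duplicate contig ids")
        self.gene_body_index = _build_tree(
            [(g.gene_body, g.gene_id) for g in genes]
        )
        self.intron_index = _build_tree(
            [(iv, g.gene_id) for g in genes for iv in g.introns]
        )
        self.repeat_index = _build_tree(
            [(r.interval, r.repeat_id) for r in repeats]
        )
        logger.debug(
            "bundle: %d genes, %d repeats, %d contigs",
            len(genes), len(repeats), len(contigs),
        )

    def genes_overlapping(self, iv: GenomicInterval) -> set[str]:
        tree = self.gene_body_index.get(iv.chrom)
        if not tree:
            return set()
        return {hit.data for hit in tree.overlap(iv.start, iv.end)}

    def repeats_overlapping(self, iv: GenomicInterval) -> set[str]:
        tree = self.repeat_index.get(iv.chrom)
        if not tree:
            return set()
        return {hit.data for hit in tree.overlap(iv.start, iv.end)}

    def introns_overlapping(self, iv: GenomicInterval) -> set[tuple[str, int, int]]:
        """(gene_id, intron_start, intron_end) for introns sharing >=1 base."""
        tree = self.intron_index.get(iv.chrom)
        if not tree:
            return set()
        return {(hit.data, hit.begin, hit.end) for hit in tree.overlap(iv.start, iv.end)}
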