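"""Synthetic-data generator with known ground truth.

Generates a miniature genome annotation (genes, repeats including split
LTR/internal provirus annotations, transcript contigs of planted
categories), a genome FASTA with poly(A) tracts at the tails of
target-primed elements, TPM expression matrices with planted
cancer-overexpressed transcripts, a bimodal subtype-defining provirus,
a latent per-sample splicing-deficiency theta that raises intronic and
depresses exonic signal of coupled genes, survival times with planted
hazard ratios, and subtype-dependent driver alterations.

Every component draws from its own stream derived from the master seed
(``numpy.random.SeedSequence(master_seed, spawn_key=(k,))`` with a fixed
``k`` per component), so e.g. enlarging a cohort does not perturb the
annotation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation import (
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    RepeatElement,
    RepeatRow,
    TranscriptContig,
    flag_genic_repeats,
    merge_ltr_internal,
    write_bed12,
    write_gtf,
    write_repeat_table,
)
from .expression import write_expression

logger = logging.getLogger(__name__)

# component stream keys for seed derivation
_STREAMS = {"annotation": 0, "expression": 1, "survival": 2, "drivers": 3}

POLYA_LENGTH = 15


@dataclass
class RepeatSpec:
    """One repeat subfamily in the catalogue."""

    subfamily: str
    class_family: str  # e.g. "SINE/Alu"
    length: int
    copies: int
    genic_fraction: float
    polya_prob: float = 0.0  # target-primed classes get a poly(A) tail


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions the
    downstream analyses assume."""

    seed: int = 0
    # genome / annotation
    chromosome_lengths: dict = field(
        default_factory=lambda: {"chr1": 450_000, "chr2": 350_000}
    )
    n_genes: int = 40
    exons_per_gene: tuple = (3, 7)  # inclusive range
    exon_length: tuple = (150, 300)
    intron_length: tuple = (800, 2500)
    gene_gap: tuple = (4000, 9000)
    repeat_catalogue: list = field(
        default_factory=lambda: [
            RepeatSpec("AluSx", "SINE/Alu", 300, 40, 0.7, 0.8),
            RepeatSpec("AluY", "SINE/Alu", 300, 25, 0.7, 0.8),
            RepeatSpec("L1PA2", "LINE/L1", 1200, 18, 0.6, 0.7),
            RepeatSpec("L1HS", "LINE/L1", 1500, 10, 0.6, 0.7),
            RepeatSpec("SVA_D", "Retroposon/SVA", 800, 8, 0.5, 0.7),
        ]
    )
    n_proviruses: int = 5  # LTR7Y + HERVH-int + LTR7Y triplets (intergenic)
    n_solo_ltr: int = 3
    ltr_length: int = 450
    internal_length: int = 2500
    # contig plan: planted category counts
    contig_plan: dict = field(
        default_factory=lambda: {
            "fully_intronic": 40,
            "exonic": 25,
            "standalone_rte": 18,
            "chimeric": 15,
            "neither": 10,
        }
    )
    # cohorts
    cancer_cohorts: tuple = ("OCCAMS1", "OCCAMS2")
    n_cancer_per_cohort: int = 60
    cancer_condition: str = "EAC"
    matched_tissue: str = "esophagus"
    healthy_tissues: dict = field(
        default_factory=lambda: {"esophagus": 30, "stomach": 15}
    )
    n_be: int = 20
    # expression model (log2-TPM scale)
    baseline_log2_mean: float = 2.5
    baseline_log2_sd: float = 1.0
    sample_log2_sd: float = 0.5
    overexpressed_fraction: float = 0.3
    overexpressed_log2_mean: float = 2.0  # cancer mean of planted features (4 TPM)
    overexpressed_log2_sd: float = 0.5
    be_expressed_prob: float = 0.5  # planted features also seen in BE
    # subtype-defining provirus mixture
    provirus_high_tpm: float = 10.0
    provirus_low_tpm: float = 0.1
    provirus_high_weight: float = 0.5
    provirus_log2_sd: float = 0.4
    # splicing deficiency
    theta_mid: float = 0.45
    theta_scale: float = 0.2
    theta_rho: float = 0.8  # correlation of theta with provirus expression
    theta_floor: float = 0.02  # basal intronic signal, and healthy theta
    coupling_kappa: float = 0.9
    coupled_fraction: float = 0.25
    gene_level_log2_mean: float = 3.0
    gene_level_log2_sd: float = 0.8
    interval_noise_log2_sd: float = 0.2
    # survival
    n_prognostic: int = 5
    prognostic_hr: float = 0.4
    subtype_log_hr: float = 0.0
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censoring_fraction: float = 0.3
    # drivers
    driver_rates: dict = field(
        default_factory=lambda: {
            "TP53": (0.7, 0.7),
            "SMARCA4": (0.5, 0.1),
            "ARID1A": (0.1, 0.4),
        }
    )

    provirus_feature_id: str = "HERVH_Xp22.32"
    exclusive_partner_id: str = "GNGT1_L1PB1"

    def rng(self, component: str) -> np.random.Generator:
        key = _STREAMS[component]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


@dataclass
class SyntheticTruth:
    contig_overlap: dict = field(default_factory=dict)  # id -> overlap category
    contig_intron: dict = field(default_factory=dict)  # id -> intron category
    planted_overexpressed: list = field(default_factory=list)
    planted_prognostic: dict = field(default_factory=dict)  # id -> true HR
    prognostic_high_samples: dict = field(default_factory=dict)
    coupled_genes: list = field(default_factory=list)
    subtype_labels: dict = field(default_factory=dict)  # cancer sample -> label
    theta: dict = field(default_factory=dict)  # sample -> theta
    polya_planted_fraction: float = 0.0
    be_expressed: dict = field(default_factory=dict)  # planted id -> bool
    exclusive_pair: tuple = ()

    def to_json(self) -> str:
        payload = asdict(self)
        payload["exclusive_pair"] = list(self.exclusive_pair)
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list
    repeat_rows: list
    repeats: list
    contigs: list
    genome: dict  # chrom -> str
    expr: pd.DataFrame
    intervals: pd.DataFrame
    meta: pd.DataFrame
    survival: pd.DataFrame
    drivers: pd.DataFrame
    truth: SyntheticTruth

    def bundle(self) -> AnnotationBundle:
        return AnnotationBundle(self.genes, self.repeats, self.contigs)


class PlacementError(RuntimeError):
    pass


class _Allocator:
    """Carves non-overlapping regions out of free intergenic segments,
    keeping ``sep`` bases between allocations."""

    def __init__(self, segments: list[tuple[str, int, int]], sep: int = 200):
        self.segments = list(segments)
        self.sep = sep

    def alloc(self, length: int, what: str) -> tuple[str, int, int]:
        for i, (chrom, start, end) in enumerate(self.segments):
            if end - start >= length + 2 * self.sep:
                a = start + self.sep
                self.segments[i] = (chrom, a + length, end)
                return chrom, a, a + length
        raise PlacementError(
            f"chromosomes too small to place {what} of length {length}; "
            "increase chromosome_lengths or reduce the catalogue/plan"
        )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig):
    """Genes, repeats (raw + merged), contigs, genome FASTA and truth labels.

    Contigs are planted so that their category labels agree with the
    classifier run on the same annotations (self-consistency contract).
    """
    rng = config.rng("annotation")
    chroms = list(config.chromosome_lengths)
    cursor = {c: 1000 for c in chroms}
    free_segments: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []

    for i in range(config.n_genes):
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[i % len(chroms)]
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(*config.exon_length, size=n_ex)
            in_lens = rng.integers(*config.intron_length, size=max(n_ex - 1, 0))
            total = int(ex_lens.sum() + in_lens.sum())
            start = cursor[chrom]
            if start + total + 1000 > config.chromosome_lengths[chrom]:
                chroms = chroms[1:] + chroms[:1]  # try next chromosome
                continue
            exons = []
            pos = start
            for j, el in enumerate(ex_lens):
                exons.append(GenomicInterval(chrom, pos, pos + int(el)))
                pos += int(el)
                if j < len(in_lens):
                    pos += int(in_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{i:03d}", chrom, strand, exons))
            gap = int(rng.integers(*config.gene_gap))
            free_segments.append((chrom, pos + 200, min(pos + gap, config.chromosome_lengths[chrom]) - 200))
            cursor[chrom] = pos + gap
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"chromosomes too small to place gene {i}; "
                "increase chromosome_lengths or reduce n_genes"
            )
    for chrom in config.chromosome_lengths:
        end = config.chromosome_lengths[chrom] - 500
        if cursor[chrom] + 400 < end:
            free_segments.append((chrom, cursor[chrom] + 200, end))
    alloc = _Allocator(free_segments)

    # --- repeats -----------------------------------------------------------
    rows: list[RepeatRow] = []
    intronic_placements: list[tuple[GeneModel, GenomicInterval, RepeatRow]] = []
    intergenic_simple: list[RepeatRow] = []
    genes_with_introns = [g for g in genes if g.introns]
    intron_used: dict[tuple[str, int], list[tuple[int, int]]] = {}

    def place_in_intron(length: int) -> tuple[GeneModel, GenomicInterval] | None:
        for _ in range(200):
            gene = genes_with_introns[int(rng.integers(len(genes_with_introns)))]
            k = int(rng.integers(len(gene.introns)))
            intron = gene.introns[k]
            pad = 60
            if len(intron) < length + 2 * pad:
                continue
            lo = intron.start + pad
            hi = intron.end - pad - length
            start = int(rng.integers(lo, hi + 1))
            key = (gene.gene_id, k)
            clash = any(
                start < e and s < start + length for s, e in intron_used.get(key, [])
            )
            if clash:
                continue
            intron_used.setdefault(key, []).append((start, start + length))
            return gene, GenomicInterval(intron.chrom, start, start + length)
        return None

    for spec in config.repeat_catalogue:
        n_genic = int(round(spec.copies * spec.genic_fraction))
        for j in range(spec.copies):
            strand = "+" if rng.random() < 0.5 else "-"
            if j < n_genic:
                hit = place_in_intron(spec.length)
                if hit is None:
                    raise PlacementError(
                        f"no intron large enough for {spec.subfamily} "
                        f"({spec.length} bp); enlarge intron_length"
                    )
                gene, iv = hit
                row = RepeatRow(iv.chrom, iv.start, iv.end, strand,
                                spec.subfamily, spec.class_family)
                rows.append(row)
                intron = next(
                    i for i in gene.introns
                    if i.start <= iv.start and iv.end <= i.end
                )
                intronic_placements.append((gene, intron, row))
            else:
                chrom, a, b = alloc.alloc(spec.length, spec.subfamily)
                row = RepeatRow(chrom, a, b, strand, spec.subfamily, spec.class_family)
                rows.append(row)
                intergenic_simple.append(row)

    provirus_spans: list[tuple[str, int, int]] = []
    for j in range(config.n_proviruses):
        size = 2 * config.ltr_length + config.internal_length + 20
        chrom, a, b = alloc.alloc(size, "HERVH provirus")
        strand = "+"
        p = a
        rows.append(RepeatRow(chrom, p, p + config.ltr_length, strand, "LTR7Y", "LTR/ERV1"))
        p += config.ltr_length + 10
        rows.append(RepeatRow(chrom, p, p + config.internal_length, strand,
                              "HERVH-int", "LTR/ERV1"))
        p += config.internal_length + 10
        rows.append(RepeatRow(chrom, p, p + config.ltr_length, strand, "LTR7Y", "LTR/ERV1"))
        provirus_spans.append((chrom, a, b))
    for j in range(config.n_solo_ltr):
        chrom, a, b = alloc.alloc(config.ltr_length, "solo LTR")
        rows.append(RepeatRow(chrom, a, b, "+", "LTR7Y", "LTR/ERV1"))

    rows.sort(key=lambda r: (r.chrom, r.start, r.end))
    repeats = merge_ltr_internal(rows)
    repeats = flag_genic_repeats(repeats, genes)

    # --- contigs -----------------------------------------------------------
    truth = SyntheticTruth()
    contigs: list[TranscriptContig] = []
    polya_targets: list[TranscriptContig] = []
    n_polya = 0
    counter = 0

    def add(contig, overlap, intron):
        truth.contig_overlap[contig.transcript_id] = overlap
        truth.contig_intron[contig.transcript_id] = intron
        contigs.append(contig)

    plan = config.contig_plan
    for _ in range(plan.get("fully_intronic", 0)):
        gene, intron, rep = intronic_placements[
            int(rng.integers(len(intronic_placements)))
        ]
        start = max(intron.start + 5, rep.start - int(rng.integers(20, 100)))
        end = min(intron.end - 5, rep.end + int(rng.integers(20, 100)))
        c = TranscriptContig(
            f"tx{counter:04d}", intron.chrom, "+",
            [GenomicInterval(intron.chrom, start, end)],
        )
        counter += 1
        add(c, "gene_and_rte", "fully_intronic")

    for _ in range(plan.get("exonic", 0)):
        gene = genes[int(rng.integers(len(genes)))]
        exon = gene.exons[int(rng.integers(len(gene.exons)))]
        strand = "-" if rng.random() < 0.3 else "+"
        c = TranscriptContig(
            f"tx{counter:04d}", gene.chrom, strand,
            [GenomicInterval(gene.chrom, exon.start, exon.end)],
        )
        counter += 1
        add(c, "gene_only", "no_intron_overlap")

    special = {0: config.provirus_feature_id, 1: config.exclusive_partner_id}
    l1_rows = [r for r in intergenic_simple if r.class_family.startswith("LINE")]
    for j in range(plan.get("standalone_rte", 0)):
        if j == 0:
            chrom, a, b = provirus_spans[0]
            start, end = a + 20, b - 20
            name = special[0]
            polya = False
        elif j == 1 and l1_rows:
            rep = l1_rows[0]
            chrom, start, end = rep.chrom, rep.start + 10, rep.end - 10
            name = special[1]
            polya = rng.random() < 0.7
        else:
            rep = intergenic_simple[int(rng.integers(len(intergenic_simple)))]
            chrom, start, end = rep.chrom, rep.start + 10, rep.end - 10
            spec_polya = {s.subfamily: s.polya_prob for s in config.repeat_catalogue}
            polya = rng.random() < spec_polya.get(rep.subfamily, 0.0)
            name = f"tx{counter:04d}"
            counter += 1
        c = TranscriptContig(name, chrom, "+", [GenomicInterval(chrom, start, end)])
        add(c, "rte_only", "no_intron_overlap")
        if polya:
            polya_targets.append(c)
            n_polya += 1

    chimeric_sources = [t for t in intronic_placements if len(t[0].exons) >= 2]
    for _ in range(plan.get("chimeric", 0)):
        gene, intron, rep = chimeric_sources[
            int(rng.integers(len(chimeric_sources)))
        ]
        exon = gene.exons[0]
        istart = max(intron.start + 5, rep.start - 30)
        iend = min(intron.end - 5, rep.end + 30)
        blocks = [
            GenomicInterval(gene.chrom, exon.start, exon.end),
            GenomicInterval(gene.chrom, istart, iend),
        ]
        c = TranscriptContig(f"tx{counter:04d}", gene.chrom, "+", blocks)
        counter += 1
        add(c, "gene_and_rte", "other")

    for _ in range(plan.get("neither", 0)):
        chrom, a, b = alloc.alloc(400, "repeat-free contig")
        c = TranscriptContig(f"tx{counter:04d}", chrom, "+",
                             [GenomicInterval(chrom, a, b)])
        counter += 1
        add(c, "neither", "no_intron_overlap")

    n_standalone = plan.get("standalone_rte", 0)
    truth.polya_planted_fraction = n_polya / n_standalone if n_standalone else 0.0

    # --- genome ------------------------------------------------------------
    genome = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom, length in config.chromosome_lengths.items():
        genome[chrom] = rng.integers(0, 4, size=length).astype(np.uint8)
    for c in polya_targets:
        block = c.blocks[-1]
        arr = genome[c.chrom]
        arr[block.end - POLYA_LENGTH:block.end] = 0  # 'A'
    genome_str = {
        chrom: bases[arr].tobytes().decode()
        for chrom, arr in genome.items()
    }
    return genes, rows, repeats, contigs, genome_str, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _build_metadata(config: SimulationConfig) -> pd.DataFrame:
    records = []
    for cohort in config.cancer_cohorts:
        for i in range(config.n_cancer_per_cohort):
            records.append(
                {
                    "sample_id": f"{cohort}_{config.cancer_condition}_{i:03d}",
                    "cohort": cohort,
                    "condition": config.cancer_condition,
                    "matched_tissue": config.matched_tissue,
                }
            )
    for tissue, n in config.healthy_tissues.items():
        for i in range(n):
            records.append(
                {
                    "sample_id": f"NORMAL_{tissue}_{i:03d}",
                    "cohort": "NORMALS",
                    "condition": tissue,
                    "matched_tissue": "",
                }
            )
    for i in range(config.n_be):
        records.append(
            {
                "sample_id": f"OCCAMS1_BE_{i:03d}",
                "cohort": "OCCAMS1",
                "condition": "BE",
                "matched_tissue": "",
            }
        )
    meta = pd.DataFrame.from_records(records).set_index("sample_id")
    meta["survival_days"] = np.nan
    meta["event"] = np.nan
    return meta


def simulate_expression(
    config: SimulationConfig,
    truth: SyntheticTruth,
    contigs: list[TranscriptContig],
    genes: list[GeneModel],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix (TPM), interval-level quantification and metadata.

    Planted overexpressed transcripts are identically zero in healthy
    tissues and log-normal in cancer; the subtype-defining provirus is a
    two-component mixture; theta (splicing deficiency) tracks provirus
    expression with correlation rho and drives the exon/intron coupling of
    coupled genes.
    """
    rng = config.rng("expression")
    meta = _build_metadata(config)
    samples = list(meta.index)
    cancer = [s for s in samples if meta.loc[s, "condition"] == config.cancer_condition]
    healthy = [
        s for s in samples
        if meta.loc[s, "condition"] in config.healthy_tissues
    ]
    be = [s for s in samples if meta.loc[s, "condition"] == "BE"]

    feature_ids = [c.transcript_id for c in contigs]
    special = {config.provirus_feature_id, config.exclusive_partner_id}
    regular = [f for f in feature_ids if f not in special]

    n_planted = int(round(len(regular) * config.overexpressed_fraction))
    planted = list(rng.choice(regular, size=n_planted, replace=False))
    prognostic = planted[: config.n_prognostic]
    planted_all = planted + sorted(special & set(feature_ids))
    # the provirus/partner pair is cancer-specific too but bimodal, so it is
    # recorded under exclusive_pair, not the log-normal overexpressed truth
    truth.planted_overexpressed = sorted(planted)
    truth.planted_prognostic = {f: config.prognostic_hr for f in prognostic}

    # subtype truth and provirus expression in cancer samples
    is_high = rng.random(len(cancer)) < config.provirus_high_weight
    truth.subtype_labels = {
        s: ("high" if h else "low") for s, h in zip(cancer, is_high)
    }
    provirus_log2 = np.where(
        is_high, np.log2(config.provirus_high_tpm), np.log2(config.provirus_low_tpm)
    ) + rng.normal(0, config.provirus_log2_sd, len(cancer))

    # theta correlated with provirus expression (Gaussian copula on the
    # standardized log2 provirus values)
    x_std = (provirus_log2 - provirus_log2.mean()) / provirus_log2.std()
    eps = rng.normal(0, 1, len(cancer))
    raw = config.theta_rho * x_std + np.sqrt(1 - config.theta_rho**2) * eps
    theta_cancer = np.clip(
        config.theta_mid + config.theta_scale * raw, config.theta_floor, 0.95
    )
    theta = {s: float(t) for s, t in zip(cancer, theta_cancer)}
    for s in healthy + be:
        theta[s] = config.theta_floor
    truth.theta = theta

    expr = pd.DataFrame(0.0, index=feature_ids, columns=samples)
    n_s = len(samples)
    for f in feature_ids:
        if f == config.provirus_feature_id:
            vals = np.zeros(n_s)
            vals[[samples.index(s) for s in cancer]] = 2.0**provirus_log2
            # BE and normals: provirus silent (planted cancer-specific)
            expr.loc[f] = vals
        elif f == config.exclusive_partner_id:
            vals = np.zeros(n_s)
            partner_log2 = np.where(
                is_high, np.log2(config.provirus_low_tpm), 2.5
            ) + rng.normal(0, config.provirus_log2_sd, len(cancer))
            vals[[samples.index(s) for s in cancer]] = 2.0**partner_log2
            expr.loc[f] = vals
        elif f in truth.planted_prognostic:
            vals = np.zeros(n_s)
            high_half = rng.random(len(cancer)) < 0.5
            lvl = np.where(high_half, 3.0, 0.0) + rng.normal(0, 0.3, len(cancer))
            vals[[samples.index(s) for s in cancer]] = 2.0**lvl
            expr.loc[f] = vals
            truth.prognostic_high_samples[f] = sorted(
                s for s, h in zip(cancer, high_half) if h
            )
        elif f in planted_all:
            vals = np.zeros(n_s)
            lvl = config.overexpressed_log2_mean + rng.normal(
                0, config.overexpressed_log2_sd, len(cancer)
            )
            vals[[samples.index(s) for s in cancer]] = 2.0**lvl
            in_be = bool(rng.random() < config.be_expressed_prob)
            truth.be_expressed[f] = in_be
            if in_be:
                be_lvl = config.overexpressed_log2_mean - 1 + rng.normal(
                    0, config.overexpressed_log2_sd, len(be)
                )
                vals[[samples.index(s) for s in be]] = 2.0**be_lvl
            expr.loc[f] = vals
        else:
            mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
            expr.loc[f] = 2.0 ** rng.normal(mu, config.sample_log2_sd, n_s)
    truth.exclusive_pair = (config.provirus_feature_id, config.exclusive_partner_id)

    # interval-level quantification for gene exon/intron layers
    n_coupled = int(round(len(genes) * config.coupled_fraction))
    genes_w_introns = [g for g in genes if g.introns]
    coupled = [g.gene_id for g in genes_w_introns[:n_coupled]]
    truth.coupled_genes = sorted(coupled)
    theta_vec = np.array([theta[s] for s in samples])
    rows = []
    n_clamped = 0
    for g in genes:
        g_level = 2.0 ** rng.normal(config.gene_level_log2_mean, config.gene_level_log2_sd)
        sample_factor = 2.0 ** rng.normal(0, 0.3, n_s)
        base = g_level * sample_factor
        exon_total = sum(len(e) for e in g.exons)
        if g.gene_id in coupled:
            exon_factor = 1.0 - config.coupling_kappa * theta_vec
            clamp = exon_factor <= 0.01
            n_clamped += int(clamp.sum())
            exon_factor = np.maximum(exon_factor, 0.01)
            intron_factor = theta_vec + config.theta_floor
        else:
            exon_factor = np.ones(n_s)
            intron_factor = np.full(n_s, config.theta_floor)
        for i, exon in enumerate(g.exons):
            w = len(exon) / exon_total
            noise = 2.0 ** rng.normal(0, config.interval_noise_log2_sd, n_s)
            rows.append(
                [f"{g.gene_id}:exon:{i}", g.gene_id, "exon"]
                + list(base * exon_factor * w * noise)
            )
        intron_total = sum(len(iv) for iv in g.introns) or 1
        for i, intron in enumerate(g.introns):
            v = len(intron) / intron_total
            noise = 2.0 ** rng.normal(0, config.interval_noise_log2_sd, n_s)
            rows.append(
                [f"{g.gene_id}:intron:{i}", g.gene_id, "intron"]
                + list(base * intron_factor * v * noise)
            )
    if n_clamped:
        logger.warning(
            "simulate_expression: exon factor clamped at floor for %d "
            "gene-sample pairs (kappa*theta >= 1)", n_clamped,
        )
    intervals = pd.DataFrame(
        rows, columns=["interval_id", "gene_id", "layer"] + samples
    )
    return expr, intervals, meta


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def _calibrate_uniform_censoring(lam: np.ndarray, fraction: float) -> float:
    """Upper bound c of U(0, c) censoring giving the target expected
    censored fraction for exponential event times with rates ``lam``."""

    def censored_frac(c):
        lc = lam * c
        return float(np.mean((1 - np.exp(-lc)) / lc)) - fraction

    lo, hi = 1e-9, 1e12
    return brentq(censored_frac, lo, hi)


def simulate_survival(
    config: SimulationConfig,
    truth: SyntheticTruth,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Exponential survival for cancer samples with planted hazard ratios.

    The hazard is h0 * exp(sum beta_f * x_f + beta_subtype * I[high]) where
    x_f indicates membership of the planted prognostic feature's
    high-expression half.  Censoring is independent uniform, calibrated to
    the configured censoring fraction.  Returns (time, event) per cancer
    sample and writes the fields into ``meta`` in place.
    """
    if config.censoring_fraction >= 1:
        raise ValueError("censoring_fraction must be < 1")
    rng = config.rng("survival")
    cancer = [
        s for s in meta.index if meta.loc[s, "condition"] == config.cancer_condition
    ]
    log_lam = np.full(len(cancer), np.log(config.baseline_hazard))
    for f, hr in truth.planted_prognostic.items():
        high = set(truth.prognostic_high_samples.get(f, []))
        x = np.array([1.0 if s in high else 0.0 for s in cancer])
        log_lam += np.log(hr) * x
    if config.subtype_log_hr:
        x = np.array(
            [1.0 if truth.subtype_labels.get(s) == "high" else 0.0 for s in cancer]
        )
        log_lam += config.subtype_log_hr * x
    lam = np.exp(log_lam)
    t_event = rng.exponential(1.0 / lam)
    if config.censoring_fraction > 0:
        c = _calibrate_uniform_censoring(lam, config.censoring_fraction)
        t_cens = rng.uniform(0, c, len(cancer))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(cancer), dtype=int)
    time = np.maximum(time, 1e-3)
    surv = pd.DataFrame({"time": time, "event": event},
                        index=pd.Index(cancer, name="sample_id"))
    meta.loc[cancer, "survival_days"] = time
    meta.loc[cancer, "event"] = event
    return surv


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def simulate_drivers(
    config: SimulationConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Binary driver-alteration matrix with subtype-conditional rates."""
    rng = config.rng("drivers")
    samples = sorted(truth.subtype_labels)
    rows = {}
    for driver, (rate_high, rate_low) in config.driver_rates.items():
        if not (0 <= rate_high <= 1 and 0 <= rate_low <= 1):
            raise ValueError(f"driver rates for {driver} outside [0, 1]")
        p = np.array(
            [rate_high if truth.subtype_labels[s] == "high" else rate_low
             for s in samples]
        )
        rows[driver] = (rng.random(len(samples)) < p).astype(int)
    return pd.DataFrame(rows, index=samples).T


# ---------------------------------------------------------------------------
# Orchestration and file output
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run every generator component under the master seed."""
    if config is None:
        config = SimulationConfig()
    genes, rows, repeats, contigs, genome, truth = simulate_annotation(config)
    expr, intervals, meta = simulate_expression(config, truth, contigs, genes)
    survival = simulate_survival(config, truth, expr, meta)
    drivers = simulate_drivers(config, truth)
    return SyntheticDataset(
        config=config, genes=genes, repeat_rows=rows, repeats=repeats,
        contigs=contigs, genome=genome, expr=expr, intervals=intervals,
        meta=meta, survival=survival, drivers=drivers, truth=truth,
    )


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every component to ``outdir``; returns the manifest
    (filename -> sha256), also saved as manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(dataset.genes, outdir / "genes.gtf")
    write_bed12(dataset.contigs, outdir / "contigs.bed12")
    write_repeat_table(dataset.repeats, outdir / "repeats.tsv")
    with open(outdir / "repeats_raw.tsv", "w") as fh:
        for r in dataset.repeat_rows:
            fh.write(
                f"{r.chrom}\t{r.start + 1}\t{r.end}\t{r.strand}\t"
                f"{r.subfamily}\t{r.class_family}\n"
            )
    write_fasta(dataset.genome, outdir / "genome.fa")
    write_expression(dataset.expr, outdir / "expression.tsv")
    dataset.intervals.to_csv(
        outdir / "intervals.tsv", sep="\t", index=False, float_format="%.6g"
    )
    dataset.meta.to_csv(
        outdir / "metadata.tsv", sep="\t", index_label="sample_id",
        float_format="%.6g",
    )
    dataset.drivers.to_csv(
        outdir / "drivers.tsv", sep="\t", index_label="driver"
    )
    (outdir / "truth.json").write_text(dataset.truth.to_json())
    manifest = {}
    for name in sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"):
        manifest[name] = _checksum(outdir / name)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
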