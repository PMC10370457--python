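"""File-based pipeline stages and their orchestration.

Each stage reads its inputs from, and writes its outputs to, a working
directory, so runs are inspectable and resumable and re-running a stage
with unchanged inputs and seed is byte-identical.  The CLI wraps these
functions; tests call them directly.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import expression as _expression
from . import signature as _signature
from . import introns as _introns
from . import survival as _survival
from . import subtype as _subtype
from .annotation import AnnotationBundle, read_bed12, read_gtf, read_repeat_table
from .simulate import SimulationConfig, SyntheticTruth, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"

STAGES = (
    "simulate", "classify", "select", "enrich", "signature",
    "survival", "introns", "subtype", "report",
)


@dataclasses.dataclass
class PipelineConfig:
    """Run-wide configuration: seed plus the numeric cut-offs of every
    stage, all overridable from a YAML file (unknown keys rejected)."""

    seed: int = 0
    selection: _expression.SelectionThresholds = dataclasses.field(
        default_factory=_expression.SelectionThresholds
    )
    panel: _signature.PanelCriteria = dataclasses.field(
        default_factory=_signature.PanelCriteria
    )
    prognostic: _survival.PrognosticFilter = dataclasses.field(
        default_factory=_survival.PrognosticFilter
    )
    subtype_cutoff: float = 1.0
    n_variable_genes: int = 100
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    config = PipelineConfig()
    sections = {
        "selection": config.selection,
        "panel": config.panel,
        "prognostic": config.prognostic,
        "simulation": config.simulation,
    }
    for key, value in raw.items():
        if key in sections:
            target = sections[key]
            valid = {f.name for f in dataclasses.fields(target)}
            for k, v in value.items():
                if k not in valid:
                    raise ValueError(f"unknown config key {key}.{k}")
                setattr(target, k, v)
        elif key in ("seed", "subtype_cutoff", "n_variable_genes"):
            setattr(config, key, value)
        else:
            raise ValueError(f"unknown config key {key}")
    return config


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}: run the '{stage}' stage first"
        )
    return path


def _load_bundle(outdir: Path) -> AnnotationBundle:
    genes = read_gtf(_require(outdir / "genes.gtf", "simulate"))
    contigs = read_bed12(_require(outdir / "contigs.bed12", "simulate"))
    rows = read_repeat_table(_require(outdir / "repeats.tsv", "simulate"))
    from .annotation import RepeatElement, GenomicInterval, flag_genic_repeats

    repeats = [
        RepeatElement(
            repeat_id=f"rep{i:06d}",
            interval=GenomicInterval(r.chrom, r.start, r.end, r.strand),
            subfamily=r.subfamily,
            family=r.family,
            rte_class=r.rte_class,
        )
        for i, r in enumerate(rows)
    ]
    flag_genic_repeats(repeats, genes)
    return AnnotationBundle(genes, repeats, contigs)


def _load_meta(outdir: Path) -> pd.DataFrame:
    return _expression.read_metadata(_require(outdir / "metadata.tsv", "simulate"))


def _load_expr(outdir: Path) -> pd.DataFrame:
    return _expression.read_expression(_require(outdir / "expression.tsv", "simulate"))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir, config: PipelineConfig) -> dict:
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    dataset = simulate_dataset(sim)
    manifest = write_dataset(dataset, outdir)
    logger.info("simulate: wrote %d files to %s", len(manifest), outdir)
    return manifest


def stage_classify(outdir, config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(outdir)
    bundle = _load_bundle(outdir)
    table = _classify.classify_contigs(bundle)
    table.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    intronic_ids = set(
        table.loc[table["intron_category"] == "fully_intronic", "transcript_id"]
    )
    intronic = [c for c in bundle.contigs if c.transcript_id in intronic_ids]
    fasta = outdir / "genome.fa"
    if intronic and fasta.exists():
        for end in ("five_prime", "three_prime"):
            pfm = _classify.terminal_pfm(intronic, fasta, k=40, end=end)
            pfm.to_frame().to_csv(outdir / f"pfm_{end}.tsv", sep="\t")
    return table


def stage_select(outdir, config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(outdir)
    expr, meta = _load_expr(outdir), _load_meta(outdir)
    cancer = config.simulation.cancer_condition
    selected, table = _expression.select_overexpressed(
        expr, meta, cancer, config.selection
    )
    if not selected:
        logger.warning("select: no features passed the overexpression filter")
    table.to_csv(outdir / "selection.tsv", sep="\t", index_label="feature_id",
                 float_format=FLOAT_FMT)
    complexity = _expression.transcriptome_complexity(
        expr, config.selection.expr_floor
    )
    complexity.to_csv(outdir / "complexity.tsv", sep="\t", index_label="sample_id")
    return table


def stage_enrich(outdir, config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(outdir)
    classification = pd.read_csv(
        _require(outdir / "classification.tsv", "classify"), sep="\t",
        keep_default_na=False,
    )
    selection = pd.read_csv(
        _require(outdir / "selection.tsv", "select"), sep="\t", index_col=0
    )
    membership: dict[str, set] = {}
    for _, row in classification.iterrows():
        for subfam in str(row["subfamilies_hit"]).split(","):
            if subfam:
                membership.setdefault(subfam, set()).add(row["transcript_id"])
    selected = list(selection.index[selection["selected"]])
    background = list(classification["transcript_id"])
    selected = [f for f in selected if f in set(background)]
    table = _expression.subfamily_enrichment(selected, background, membership)
    table.to_csv(outdir / "enrichment.tsv", sep="\t", float_format=FLOAT_FMT)
    return table


def stage_signature(outdir, config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(outdir)
    expr, meta = _load_expr(outdir), _load_meta(outdir)
    sim = config.simulation
    negatives = sorted(sim.healthy_tissues)
    panel = _signature.define_panel(
        expr, meta, sim.cancer_condition, negatives, config.panel
    )
    _signature.write_panel(panel, outdir / "panel.tsv")
    if not panel.features:
        return pd.DataFrame()
    eval_samples = meta.index[
        meta["condition"].isin([sim.cancer_condition] + negatives)
    ]
    scores = _signature.score_samples(expr.loc[:, eval_samples], panel)
    labels = (meta.loc[eval_samples, "condition"] == sim.cancer_condition).astype(int)
    out = pd.DataFrame({"score": scores, "label": labels})
    out.to_csv(outdir / "scores.tsv", sep="\t", index_label="sample_id",
               float_format=FLOAT_FMT)
    roc = _signature.roc_curve(scores, labels)
    roc_df = pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )
    roc_df.to_csv(outdir / "roc.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    with open(outdir / "roc_summary.tsv", "w") as fh:
        fh.write("auc\toperating_threshold\tsensitivity\tspecificity\n")
        fh.write(
            f"{roc.auc:.6g}\t{roc.operating_threshold:.6g}\t"
            f"{roc.operating_sensitivity:.6g}\t{roc.operating_specificity:.6g}\n"
        )
    return out


def stage_survival(outdir, config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(outdir)
    expr, meta = _load_expr(outdir), _load_meta(outdir)
    selection = pd.read_csv(
        _require(outdir / "selection.tsv", "select"), sep="\t", index_col=0
    )
    features = list(selection.index[selection["selected"]])
    records = {}
    for cohort in sorted(config.simulation.cancer_cohorts):
        cohort_meta = meta[
            (meta["cohort"] == cohort)
            & (meta["condition"] == config.simulation.cancer_condition)
        ]
        surv = _survival.survival_from_metadata(cohort_meta)
        screen = _survival.cohort_survival_screen(
            expr.loc[features, cohort_meta.index], surv, cohort=cohort
        )
        records[cohort] = screen
        screen.to_csv(outdir / f"survival_{cohort}.tsv", sep="\t",
                      float_format=FLOAT_FMT)
    prognostic = _survival.dual_cohort_filter(records, config.prognostic)
    prognostic.to_csv(outdir / "prognostic.tsv", sep="\t", float_format=FLOAT_FMT)
    return prognostic


def stage_introns(outdir, config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(outdir)
    meta = _load_meta(outdir)
    genes = read_gtf(_require(outdir / "genes.gtf", "simulate"))
    intervals = _introns.read_interval_quantification(
        _require(outdir / "intervals.tsv", "simulate")
    )
    split = _introns.collapse_gene_counts(intervals, genes)
    _introns.write_split(split, outdir / "gene_split.tsv")

    sim = config.simulation
    cancer_meta = meta[meta["condition"] == sim.cancer_condition]
    survival_by_cohort, samples_by_cohort = {}, {}
    for cohort in sorted(sim.cancer_cohorts):
        sub = cancer_meta[cancer_meta["cohort"] == cohort]
        survival_by_cohort[cohort] = _survival.survival_from_metadata(sub)
        samples_by_cohort[cohort] = list(sub.index)
    exon_res, intron_res, concordance = _survival.gene_level_prognostics(
        split, survival_by_cohort, samples_by_cohort, config.prognostic
    )
    exon_res.to_csv(outdir / "prognostic_exon.tsv", sep="\t", float_format=FLOAT_FMT)
    intron_res.to_csv(outdir / "prognostic_intron.tsv", sep="\t",
                      float_format=FLOAT_FMT)
    concordance.to_csv(outdir / "concordance.tsv", sep="\t", float_format=FLOAT_FMT)

    sample = sorted(cancer_meta.index)[0]
    r = _introns.exon_intron_correlation(split, sample)
    with open(outdir / "exon_intron_correlation.tsv", "w") as fh:
        fh.write("sample_id\tpearson_r\n")
        fh.write(f"{sample}\t{r:.6g}\n")
    return concordance


def stage_subtype(outdir, config: PipelineConfig) -> pd.DataFrame:
    outdir = Path(outdir)
    expr, meta = _load_expr(outdir), _load_meta(outdir)
    genes = read_gtf(_require(outdir / "genes.gtf", "simulate"))
    intervals = _introns.read_interval_quantification(
        _require(outdir / "intervals.tsv", "simulate")
    )
    split = _introns.collapse_gene_counts(intervals, genes)
    sim = config.simulation

    cancer_samples = list(meta.index[meta["condition"] == sim.cancer_condition])
    sub_cfg = _subtype.SubtypeConfig(sim.provirus_feature_id, config.subtype_cutoff)
    labels = _subtype.assign_subtype(expr.loc[:, cancer_samples], sub_cfg)
    labels.to_frame().to_csv(outdir / "subtype.tsv", sep="\t", index_label="sample_id")

    provirus = expr.loc[sim.provirus_feature_id, cancer_samples]
    others = expr.drop(index=sim.provirus_feature_id).loc[:, cancer_samples]
    assoc_tx = _subtype.linear_association(others, provirus, "transcripts")
    assoc_tx.to_csv(outdir / "assoc_transcripts.tsv", sep="\t", float_format=FLOAT_FMT)
    assoc_exon = _subtype.linear_association(
        split.exon.loc[:, cancer_samples], provirus, "exon"
    )
    assoc_intron = _subtype.linear_association(
        split.intron.loc[:, cancer_samples], provirus, "intron"
    )
    assoc_exon.to_csv(outdir / "assoc_exon.tsv", sep="\t", float_format=FLOAT_FMT)
    assoc_intron.to_csv(outdir / "assoc_intron.tsv", sep="\t", float_format=FLOAT_FMT)

    drivers_path = outdir / "drivers.tsv"
    if drivers_path.exists():
        drivers = pd.read_csv(drivers_path, sep="\t", index_col=0)
        assoc_drv = _subtype.linear_association(
            drivers.loc[:, [s for s in cancer_samples if s in drivers.columns]],
            provirus, "drivers", log_transform=False,
        )
        assoc_drv.to_csv(outdir / "assoc_drivers.tsv", sep="\t",
                         float_format=FLOAT_FMT)

    high = list(labels.index[labels == "high"])
    low = list(labels.index[labels == "low"])
    de = _subtype.differential_expression(
        others, high, low
    )
    de.to_csv(outdir / "de.tsv", sep="\t", index_label="feature_id",
              float_format=FLOAT_FMT)

    inverse = _subtype.inverse_splicing_genes(
        assoc_exon, assoc_intron, split, provirus
    )
    inverse.to_csv(outdir / "inverse_splicing.tsv", sep="\t", float_format=FLOAT_FMT)

    be_samples = list(meta.index[meta["condition"] == "BE"])
    if be_samples:
        n_var = min(config.n_variable_genes, expr.shape[0])
        dist, u, p = _subtype.be_distance(expr, labels, be_samples, n_var)
        dist.to_frame().to_csv(outdir / "be_distance.tsv", sep="\t",
                               index_label="sample_id", float_format=FLOAT_FMT)
        with open(outdir / "be_distance_summary.tsv", "w") as fh:
            fh.write("mann_whitney_u\tp\n")
            fh.write(f"{u:.6g}\t{p:.6g}\n")
    return inverse


def stage_report(outdir, config: PipelineConfig) -> Path:
    """Collate per-stage row counts and headline numbers into report.md."""
    outdir = Path(outdir)
    lines = ["# Pipeline report", ""]

    def count(fname, pred=None):
        path = outdir / fname
        if not path.exists():
            return None
        df = pd.read_csv(path, sep="\t")
        return int(pred(df)) if pred else len(df)

    entries = [
        ("contigs classified", count("classification.tsv")),
        ("overexpressed transcripts selected",
         count("selection.tsv", lambda d: d["selected"].sum())),
        ("subfamilies tested for enrichment", count("enrichment.tsv")),
        ("diagnostic panel size", count("panel.tsv")),
        ("prognostic transcripts", count("prognostic.tsv")),
        ("prognostic genes (exon layer)", count("prognostic_exon.tsv")),
        ("prognostic genes (intron layer)", count("prognostic_intron.tsv")),
        ("genes at the prognostic intersection", count("concordance.tsv")),
        ("transcripts associated with the provirus",
         count("assoc_transcripts.tsv",
               lambda d: ((d["p"] < 0.05) & (d["q"] < 0.05)).sum())),
        ("differentially expressed features (q<0.05)",
         count("de.tsv", lambda d: d["significant"].sum())),
        ("inverse-splicing genes", count("inverse_splicing.tsv")),
    ]
    for label, value in entries:
        if value is not None:
            lines.append(f"- {label}: {value}")
    roc = outdir / "roc_summary.tsv"
    if roc.exists():
        auc = pd.read_csv(roc, sep="\t")["auc"].iloc[0]
        lines.append(f"- diagnostic score AUC (cancer vs normals): {auc:.4f}")
    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "select": stage_select,
    "enrich": stage_enrich,
    "signature": stage_signature,
    "survival": stage_survival,
    "introns": stage_introns,
    "subtype": stage_subtype,
    "report": stage_report,
}


def run_stage(stage: str, outdir, config: PipelineConfig):
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    logger.info("running stage %s (seed=%d)", stage, config.seed)
    return _STAGE_FUNCS[stage](outdir, config)


def run_pipeline(outdir, config: PipelineConfig | None = None):
    """Run every stage in order on one working directory."""
    if config is None:
        config = PipelineConfig()
    for stage in STAGES:
        run_stage(stage, outdir, config)
    return Path(outdir)
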