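"""Gene-level exon/intron quantitation and splicing-deficiency metrics.

Interval-level quantification (one row per exon-union interval or intron,
assigned to a gene and a layer) is collapsed to per-gene exon and intron
values; the exon/intron log ratio is the readout of splicing deficiency:
incomplete intron removal raises intronic signal while depressing the
fully spliced (exonic) signal of affected genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel

logger = logging.getLogger(__name__)

LAYERS = ("exon", "intron")


@dataclass
class GeneSplitExpression:
    """Per-gene, per-sample exon- and intron-collapsed values.

    ``exon`` and ``intron`` are genes x samples DataFrames with identical
    axes; genes without annotated introns carry zero intron values and are
    listed in ``intronless``.  ``unassigned`` collects per-sample totals of
    intervals that could not be assigned to a gene.
    """

    exon: pd.DataFrame
    intron: pd.DataFrame
    intronless: set[str] = field(default_factory=set)
    unassigned: pd.Series | None = None

    def __post_init__(self):
        if not self.exon.index.equals(self.intron.index) or not self.exon.columns.equals(
            self.intron.columns
        ):
            raise ValueError("exon and intron layers must share axes")
        if (self.exon.values < 0).any() or (self.intron.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.exon.index)

    @property
    def samples(self) -> list[str]:
        return list(self.exon.columns)

    def log_ratio(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2((exon + 1) / (intron + 1)) per gene per sample."""
        return np.log2(self.exon + pseudocount) - np.log2(self.intron + pseudocount)


def read_interval_quantification(path) -> pd.DataFrame:
    """Interval table TSV: interval_id, gene_id, layer, then sample columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"interval_id", "gene_id", "layer"}
    if not required <= set(df.columns):
        raise ValueError(f"interval table missing columns {sorted(required)}")
    return df


def collapse_gene_counts(
    intervals: pd.DataFrame, genes: list[GeneModel]
) -> GeneSplitExpression:
    """Sum interval-level values per gene and layer.

    ``intervals`` must have columns interval_id, gene_id, layer ('exon' or
    'intron'), followed by one column per sample.  Intervals with an empty
    or unknown gene_id are summed into the reported ``unassigned`` bucket
    rather than dropped silently.
    """
    bad_layer = ~intervals["layer"].isin(LAYERS)
    if bad_layer.any():
        raise ValueError(
            f"unknown layer value(s): {sorted(intervals.loc[bad_layer, 'layer'].unique())}"
        )
    sample_cols = [
        c for c in intervals.columns if c not in ("interval_id", "gene_id", "layer")
    ]
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)
    assigned_mask = intervals["gene_id"].isin(known)
    unassigned = intervals.loc[~assigned_mask, sample_cols].sum(axis=0)
    if (~assigned_mask).any():
        logger.warning(
            "collapse_gene_counts: %d interval(s) assigned to no known gene",
            int((~assigned_mask).sum()),
        )
    assigned = intervals.loc[assigned_mask]
    sums = assigned.groupby(["gene_id", "layer"], sort=False)[sample_cols].sum()
    layers = {}
    for layer in LAYERS:
        grid = pd.DataFrame(0.0, index=gene_ids, columns=sample_cols)
        present = sums.xs(layer, level="layer", drop_level=True) if layer in set(
            assigned["layer"]
        ) else pd.DataFrame(columns=sample_cols)
        grid.loc[present.index, :] = present.astype(float)
        layers[layer] = grid
    intronless = {g.gene_id for g in genes if not g.introns}
    return GeneSplitExpression(
        exon=layers["exon"],
        intron=layers["intron"],
        intronless=intronless,
        unassigned=unassigned,
    )


def write_split(split: GeneSplitExpression, path) -> None:
    long = pd.concat(
        [
            split.exon.stack().rename("exon_value"),
            split.intron.stack().rename("intron_value"),
        ],
        axis=1,
    )
    long.index.names = ["gene_id", "sample_id"]
    long.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def exon_intron_correlation(split: GeneSplitExpression, sample: str) -> float:
    """Pearson correlation of log2(exon+1) vs log2(intron+1) across genes
    for one sample (transcribed genes shed introns, so the layers should be
    positively correlated in real data)."""
    if sample not in split.exon.columns:
        raise KeyError(f"unknown sample {sample!r}")
    x = np.log2(split.exon[sample].to_numpy(dtype=float) + 1)
    y = np.log2(split.intron[sample].to_numpy(dtype=float) + 1)
    if len(x) < 3:
        raise ValueError("need >=3 genes")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant layer: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def exon_intron_ratio_test(
    split: GeneSplitExpression,
    group_high: list[str],
    group_low: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene test of exon/intron log ratios between two sample groups.

    ratio = log2((exon+1)/(intron+1)) per sample; groups are compared with a
    two-sided Student's t-test.  Genes without annotated introns are skipped
    (ratio undefined).  Returns mean ratios per group, t and p per gene.
    """
    if not group_high or not group_low:
        raise ValueError("both groups must be non-empty")
    ratios = split.log_ratio(pseudocount)
    testable = [g for g in ratios.index if g not in split.intronless]
    skipped = len(ratios.index) - len(testable)
    if skipped:
        logger.info("exon_intron_ratio_test: skipped %d intronless gene(s)", skipped)
    high = ratios.loc[testable, group_high].to_numpy(dtype=float)
    low = ratios.loc[testable, group_low].to_numpy(dtype=float)
    t, p = stats.ttest_ind(high, low, axis=1, equal_var=True)
    same = (high.std(axis=1) == 0) & (low.std(axis=1) == 0) & (
        high.mean(axis=1) == low.mean(axis=1)
    )
    t = np.where(same, 0.0, t)
    p = np.where(same | ~np.isfinite(p), 1.0, p)
    return pd.DataFrame(
        {
            "mean_ratio_high": high.mean(axis=1),
            "mean_ratio_low": low.mean(axis=1),
            "t": t,
            "p": p,
        },
        index=pd.Index(testable, name="gene_id"),
    )


def select_extreme_samples(
    values: pd.Series, n: int = 10
) -> tuple[list[str], list[str]]:
    """Top-n and bottom-n samples by value, ties broken by sample id."""
    if 2 * n > len(values):
        raise ValueError(f"need >= {2 * n} samples, have {len(values)}")
    order = sorted(values.index, key=lambda s: (values[s], s))
    return order[-n:], order[:n]
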