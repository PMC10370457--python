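"""HERVH-provirus subtype assignment and downstream associations.

Tumors are split into provirus-high and provirus-low subtypes at a TPM
cutoff (default 1 TPM on the subtype-defining provirus, e.g. the HERVH
element on Xp22.32).  Downstream: per-feature linear associations with
provirus expression (transcripts, gene exon/intron layers, binary driver
alterations, each corrected as its own family), differential expression
between subtypes, recovery of genes whose exon and intron layers move in
opposite directions with the provirus, and transcriptional distance of
tumors to the Barrett's-esophagus centroid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import PSEUDOCOUNT
from .introns import GeneSplitExpression, exon_intron_ratio_test, select_extreme_samples

logger = logging.getLogger(__name__)


@dataclass
class SubtypeConfig:
    provirus_id: str
    cutoff: float = 1.0
    high_if_equal: bool = True  # boundary value assigned to 'high' (>= rule)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def assign_subtype(expr: pd.DataFrame, config: SubtypeConfig) -> pd.Series:
    """Label each sample 'high' or 'low' by provirus TPM against the cutoff."""
    if config.provirus_id not in expr.index:
        raise KeyError(f"provirus feature {config.provirus_id!r} not in matrix")
    vals = expr.loc[config.provirus_id]
    if config.high_if_equal:
        high = vals >= config.cutoff
    else:
        high = vals > config.cutoff
    return pd.Series(np.where(high, "high", "low"), index=expr.columns, name="subtype")


def linear_association(
    features: pd.DataFrame,
    provirus: pd.Series,
    family: str,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-feature ordinary least-squares association with provirus
    expression.

    The response is log2(provirus TPM + 0.1); each feature (log2(TPM+0.1)
    for expression features, raw 0/1 for driver alterations) is regressed on
    the response.  p is the two-sided t-test on the slope;
    Benjamini-Hochberg q is computed within the declared family.  Constant
    features are skipped with a note.
    """
    common = features.columns.intersection(provirus.index)
    if len(common) < 10:
        raise ValueError("need >=10 samples")
    y = np.log2(provirus.loc[common].to_numpy(dtype=float) + PSEUDOCOUNT)
    x = features.loc[:, common].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + PSEUDOCOUNT)
    constant = x.max(axis=1) == x.min(axis=1)
    if constant.any():
        logger.info(
            "linear_association(%s): skipped %d constant feature(s)",
            family, int(constant.sum()),
        )
    if np.std(y) == 0:
        raise ValueError("constant provirus expression")
    x = x[~constant]
    index = features.index[~constant]

    # closed-form simple OLS per feature: x_f = a + b*y
    n = len(y)
    yc = y - y.mean()
    ss_y = (yc**2).sum()
    slope = (x @ yc) / ss_y
    intercept = x.mean(axis=1) - slope * y.mean()
    resid = x - (intercept[:, None] + np.outer(slope, y))
    dof = n - 2
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(sigma2 / ss_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isfinite(p), p, 0.0)  # zero residual variance: exact fit
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    return pd.DataFrame(
        {
            "slope": slope,
            "t": t,
            "p": p,
            "q": q,
            "sign": np.sign(slope).astype(int),
            "family": family,
        },
        index=index,
    )


def differential_expression(
    expr: pd.DataFrame, group_high: list[str], group_low: list[str]
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(TPM+0.1) between subtypes, with
    Benjamini-Hochberg q and the log2 difference of group means."""
    if len(group_high) < 2 or len(group_low) < 2:
        raise ValueError("need >=2 samples per group")
    a = np.log2(expr.loc[:, group_high].to_numpy(dtype=float) + PSEUDOCOUNT)
    b = np.log2(expr.loc[:, group_low].to_numpy(dtype=float) + PSEUDOCOUNT)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2_diff": a.mean(axis=1) - b.mean(axis=1),
            "t": np.where(zero_var, 0.0, t),
            "p": p,
            "q": q,
            "significant": q < 0.05,
        },
        index=expr.index,
    )


def inverse_splicing_genes(
    exon_assoc: pd.DataFrame,
    intron_assoc: pd.DataFrame,
    split: GeneSplitExpression,
    provirus: pd.Series,
    n_extreme: int = 10,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Genes whose intron layer rises and exon layer falls with provirus
    expression, confirmed by an exon/intron ratio test between extreme
    samples.

    Candidates need intron slope > 0 (q < q_max) and exon slope < 0
    (q < q_max); the ratio test then compares the top-n against the
    bottom-n samples by provirus TPM.  An empty candidate set returns an
    empty table, not an error.
    """
    common = exon_assoc.index.intersection(intron_assoc.index)
    ex = exon_assoc.loc[common]
    intr = intron_assoc.loc[common]
    candidates = common[
        (intr["slope"] > 0) & (intr["q"] < q_max)
        & (ex["slope"] < 0) & (ex["q"] < q_max)
    ]
    if len(candidates) == 0:
        return pd.DataFrame(
            columns=["mean_ratio_high", "mean_ratio_low", "t", "p"]
        ).rename_axis("gene_id")
    high, low = select_extreme_samples(provirus, n_extreme)
    ratio = exon_intron_ratio_test(split, high, low)
    keep = [g for g in candidates if g in ratio.index]
    return ratio.loc[keep]


def be_distance(
    expr: pd.DataFrame,
    subtype_labels: pd.Series,
    be_samples: list[str],
    n_variable_genes: int = 500,
) -> tuple[pd.Series, float, float]:
    """Distance of each tumor to the Barrett's-esophagus centroid.

    Top-variance genes (log2(TPM+0.1), across tumors and BE samples
    together) are z-scored; the distance is the Euclidean distance to the
    BE centroid; subtypes are compared with a two-sided Mann-Whitney test.

    Returns (per-tumor distances, Mann-Whitney U, p).
    """
    if not be_samples:
        raise ValueError("BE sample set is empty")
    eac_samples = list(subtype_labels.index)
    all_samples = eac_samples + list(be_samples)
    log_expr = np.log2(expr.loc[:, all_samples].astype(float) + PSEUDOCOUNT)
    if n_variable_genes > log_expr.shape[0]:
        raise ValueError(
            f"n_variable_genes={n_variable_genes} exceeds available genes "
            f"({log_expr.shape[0]})"
        )
    variances = log_expr.var(axis=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_variable_genes]
    sub = log_expr.loc[top]
    sd = sub.std(axis=1).replace(0, 1.0)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    centroid = z.loc[:, be_samples].mean(axis=1)
    diffs = z.loc[:, eac_samples].sub(centroid, axis=0)
    dist = pd.Series(
        np.sqrt((diffs**2).sum(axis=0).to_numpy()), index=eac_samples, name="be_distance"
    )
    high = dist[subtype_labels == "high"]
    low = dist[subtype_labels == "low"]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both subtypes must be present among tumors")
    u, p = stats.mannwhitneyu(high, low, alternative="two-sided")
    return dist, float(u), float(p)
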