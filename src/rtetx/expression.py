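"""Expression-level analyses: transcriptome complexity, the
cancer-overexpression selection filter, differential repeat expression,
subfamily enrichment, and the copy-number bias diagnostic.

Expression matrices are pandas DataFrames with feature ids as the row index
and sample ids as columns, in TPM.  Sample metadata is a DataFrame indexed
by sample_id with at least ``cohort``, ``condition`` and ``matched_tissue``
columns; conditions are cancer-type codes, healthy-tissue labels or "BE",
and ``matched_tissue`` names the healthy tissue paired with each cancer
condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.1

METADATA_COLUMNS = [
    "cohort",
    "condition",
    "matched_tissue",
    "survival_days",
    "event",
]


@dataclass
class SelectionThresholds:
    """Cut-offs of the cancer-overexpression filter.

    A feature is selected when its median TPM across the target cancer
    samples exceeds ``cancer_median_min``, and the healthy summary H =
    max(matched-tissue ``healthy_percentile``-th percentile, the largest
    per-tissue median over all healthy tissues) satisfies both
    fold * H <= cancer ``cancer_percentile``-th percentile and
    H < ``healthy_abs_max``.
    """

    expr_floor: float = 0.5
    cancer_median_min: float = 0.5
    fold: float = 3.0
    healthy_percentile: float = 90.0
    cancer_percentile: float = 75.0
    healthy_abs_max: float = 0.5

    def __post_init__(self):
        for name in ("expr_floor", "cancer_median_min", "fold", "healthy_abs_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("healthy_percentile", "cancer_percentile"):
            if not 0 < getattr(self, name) < 100:
                raise ValueError(f"{name} must be in (0, 100)")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if (expr.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValueError("expression matrix has duplicate feature or sample ids")
    return expr


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "feature_id"
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = {"cohort", "condition"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["condition"].isna().any() or (meta["condition"] == "").any():
        raise ValueError("metadata has empty condition values")
    has_days = meta.get("survival_days")
    has_event = meta.get("event")
    if has_days is not None and has_event is not None:
        mism = has_days.notna() != has_event.notna()
        if mism.any():
            raise ValueError("survival_days and event must be present together")
    return meta


def healthy_conditions(meta: pd.DataFrame) -> list[str]:
    """Healthy tissue labels = the set of matched_tissue values."""
    vals = meta["matched_tissue"].dropna()
    return sorted(v for v in vals.unique() if v)


# ---------------------------------------------------------------------------
# Transcriptome complexity
# ---------------------------------------------------------------------------

def transcriptome_complexity(expr: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Number of features expressed at >= threshold TPM per sample (an
    indirect measure of transcriptome complexity; boundary inclusive)."""
    return (expr >= threshold).sum(axis=0).rename("n_expressed")


# ---------------------------------------------------------------------------
# Cancer-overexpression selection filter
# ---------------------------------------------------------------------------

def select_overexpressed(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    cancer_condition: str,
    thresholds: SelectionThresholds | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Select features overexpressed in one cancer type versus all healthy
    tissues.

    Per feature: mC = median over the cancer samples; q75C = the cancer
    ``cancer_percentile``-th percentile; H = max(matched-tissue
    ``healthy_percentile``-th percentile, max over healthy tissues of that
    tissue's median).  Selected iff mC > cancer_median_min AND
    fold*H <= q75C AND H < healthy_abs_max.

    Returns (selected ids in matrix order, per-feature statistics table).
    Percentiles use linear interpolation between order statistics.
    """
    if thresholds is None:
        thresholds = SelectionThresholds()
    validate_expression(expr)
    meta = meta.loc[meta.index.intersection(expr.columns)]
    cancer_samples = meta.index[meta["condition"] == cancer_condition]
    if len(cancer_samples) == 0:
        raise ValueError(f"no samples with condition {cancer_condition!r}")
    matched = meta.loc[cancer_samples, "matched_tissue"].dropna().unique()
    matched = [m for m in matched if m]
    if not matched:
        raise ValueError(
            f"no matched healthy tissue defined for cancer type {cancer_condition!r}"
        )
    matched_tissue = matched[0]
    tissues = healthy_conditions(meta)
    tissue_samples = {
        t: meta.index[meta["condition"] == t] for t in tissues
    }
    if matched_tissue not in tissue_samples or len(tissue_samples[matched_tissue]) == 0:
        raise ValueError(
            f"matched healthy tissue {matched_tissue!r} has no samples"
        )

    if expr.shape[0] == 0:
        table = pd.DataFrame(
            columns=["median_cancer", "q_cancer", "healthy_summary", "selected"]
        )
        return [], table

    cancer = expr.loc[:, cancer_samples].to_numpy(dtype=float)
    m_cancer = np.median(cancer, axis=1)
    q_cancer = np.percentile(
        cancer, thresholds.cancer_percentile, axis=1, method="linear"
    )
    matched_vals = expr.loc[:, tissue_samples[matched_tissue]].to_numpy(dtype=float)
    h_matched = np.percentile(
        matched_vals, thresholds.healthy_percentile, axis=1, method="linear"
    )
    tissue_medians = np.column_stack(
        [
            np.median(expr.loc[:, samples].to_numpy(dtype=float), axis=1)
            for samples in tissue_samples.values()
        ]
    )
    h_summary = np.maximum(h_matched, tissue_medians.max(axis=1))

    selected_mask = (
        (m_cancer > thresholds.cancer_median_min)
        & (thresholds.fold * h_summary <= q_cancer)
        & (h_summary < thresholds.healthy_abs_max)
    )
    table = pd.DataFrame(
        {
            "median_cancer": m_cancer,
            "q_cancer": q_cancer,
            "healthy_summary": h_summary,
            "selected": selected_mask,
        },
        index=expr.index,
    )
    selected = list(expr.index[selected_mask])
    logger.info(
        "select_overexpressed(%s): %d/%d features selected",
        cancer_condition, len(selected), expr.shape[0],
    )
    return selected, table


def intersect_selections(*selections: list[str]) -> list[str]:
    """Features recurrently selected across cancer types (set intersection,
    order of the first selection preserved)."""
    if not selections:
        return []
    common = set(selections[0])
    for sel in selections[1:]:
        common &= set(sel)
    return [f for f in selections[0] if f in common]


# ---------------------------------------------------------------------------
# Differential repeat expression
# ---------------------------------------------------------------------------

def differential_repeat_expression(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fold_min: float = 6.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature differential expression between two sample groups.

    Fold-change is on group means of TPM with pseudocount 0.1; the test is a
    two-sided Welch t-test on log2(TPM + 0.1) with Benjamini-Hochberg
    correction.  ``pass`` requires |fold| > fold_min (strict) and p < alpha
    and q < alpha.  Features with zero variance in both groups get p = 1 and
    are flagged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >=2 samples per group")
    a = expr.loc[:, group_a].to_numpy(dtype=float)
    b = expr.loc[:, group_b].to_numpy(dtype=float)
    log_a = np.log2(a + PSEUDOCOUNT)
    log_b = np.log2(b + PSEUDOCOUNT)
    log2_fc = np.log2(a.mean(axis=1) + PSEUDOCOUNT) - np.log2(
        b.mean(axis=1) + PSEUDOCOUNT
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_stat, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    zero_var = (log_a.std(axis=1) == 0) & (log_b.std(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    passes = (np.abs(log2_fc) > np.log2(fold_min)) & (p < alpha) & (q < alpha)
    return pd.DataFrame(
        {
            "log2_fold_change": log2_fc,
            "t": t_stat,
            "p": p,
            "q": q,
            "zero_variance": zero_var,
            "pass": passes,
        },
        index=expr.index,
    )


# ---------------------------------------------------------------------------
# Subfamily enrichment (Fisher's exact tests)
# ---------------------------------------------------------------------------

def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def subfamily_enrichment(
    selected: list[str],
    background: list[str],
    membership: dict[str, set[str]],
) -> pd.DataFrame:
    """Enrichment of each repeat subfamily among selected transcripts.

    ``membership`` maps subfamily name -> set of transcript ids overlapping
    that subfamily.  For each subfamily a 2x2 table is built (overlapping vs
    not, in the selection vs the background minus the selection) and tested
    with a two-sided Fisher's exact test; the sample odds ratio uses a
    Haldane correction of 0.5 when any cell is zero; q is Benjamini-Hochberg
    over the tested subfamilies.
    """
    sel_set = set(selected)
    bg_set = set(background)
    if not sel_set <= bg_set:
        raise ValueError("selected must be a subset of background")
    rest = bg_set - sel_set
    rows = []
    for subfamily in sorted(membership):
        members = membership[subfamily]
        if not members & bg_set:
            warnings.warn(f"subfamily {subfamily!r} absent from background; skipped")
            continue
        a = len(members & sel_set)
        b = len(sel_set) - a
        c = len(members & rest)
        d = len(rest) - c
        p = fisher_two_sided(a, b, c, d)
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append(
            {"subfamily": subfamily, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds, "p": p}
        )
    result = pd.DataFrame(
        rows, columns=["subfamily", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("subfamily")
    if len(result):
        result["q"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    else:
        result["q"] = pd.Series(dtype=float)
    return result


def copy_number_bias(
    enrichment: pd.DataFrame, copy_number: pd.Series
) -> tuple[float, float]:
    """Spearman correlation between genomic copy number and log odds ratio
    across subfamilies (the copy-number bias of enrichment)."""
    common = enrichment.index.intersection(copy_number.index)
    odds = enrichment.loc[common, "odds_ratio"].to_numpy(dtype=float)
    cn = copy_number.loc[common].to_numpy(dtype=float)
    finite = np.isfinite(odds) & (odds > 0) & np.isfinite(cn)
    odds, cn = odds[finite], cn[finite]
    if len(odds) < 3:
        raise ValueError("need >=3 subfamilies with finite odds ratios")
    if np.all(cn == cn[0]) or np.all(odds == odds[0]):
        raise ValueError("undefined correlation: constant input vector")
    rho, p = stats.spearmanr(cn, np.log(odds))
    return float(rho), float(p)
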