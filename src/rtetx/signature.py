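"""Diagnostic transcript panels and cumulative z-score scoring.

A panel is a set of transcripts recurrently expressed in the positive
(cancer) class of every cohort and essentially absent from the negative
classes (normal tissues, optionally Barrett's esophagus for the stricter
sub-panel).  Samples are scored by the sum of per-feature z-scores and the
score is evaluated as a ROC curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PanelCriteria:
    """Inclusion rules for the diagnostic panel.

    A feature enters the panel when its expressed fraction (TPM >=
    ``expr_floor``) is at least ``min_recurrence`` among positive samples of
    every cohort and at most ``max_negative_fraction`` in every negative
    class.
    """

    expr_floor: float = 0.5
    min_recurrence: float = 0.5
    max_negative_fraction: float = 0.01

    def __post_init__(self):
        if not 0 <= self.min_recurrence <= 1:
            raise ValueError("min_recurrence must be in [0, 1]")
        if not 0 <= self.max_negative_fraction <= 1:
            raise ValueError("max_negative_fraction must be in [0, 1]")


@dataclass
class SignaturePanel:
    features: list[str]
    mean: pd.Series | None = None  # optional reference normalization
    sd: pd.Series | None = None
    reference_samples: list[str] = field(default_factory=list)


def define_panel(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    positive_condition: str,
    negative_classes: list[str],
    criteria: PanelCriteria | None = None,
) -> SignaturePanel:
    """Build the diagnostic panel from expressed-fraction criteria.

    Recurrence is evaluated per cohort among positive-class samples; all
    cohorts must individually meet ``min_recurrence``.  Every negative class
    (a condition label) must stay at or below ``max_negative_fraction``.
    Deterministic given matrix and criteria; returns features in matrix
    order.
    """
    if criteria is None:
        criteria = PanelCriteria()
    meta = meta.loc[meta.index.intersection(expr.columns)]
    pos = meta.index[meta["condition"] == positive_condition]
    if len(pos) == 0:
        raise ValueError(f"no positive samples for {positive_condition!r}")
    expressed = expr >= criteria.expr_floor

    keep = pd.Series(True, index=expr.index)
    for cohort, cohort_meta in meta.loc[pos].groupby("cohort"):
        frac = expressed.loc[:, cohort_meta.index].mean(axis=1)
        keep &= frac >= criteria.min_recurrence
    for neg in negative_classes:
        neg_samples = meta.index[meta["condition"] == neg]
        if len(neg_samples) == 0:
            raise ValueError(f"negative class {neg!r} has no samples")
        frac = expressed.loc[:, neg_samples].mean(axis=1)
        keep &= frac <= criteria.max_negative_fraction

    features = list(expr.index[keep])
    if not features:
        warnings.warn("panel definition produced an empty panel")
    logger.info("define_panel: %d features", len(features))
    return SignaturePanel(features=features)


def read_panel(path) -> SignaturePanel:
    """Read a panel TSV: feature_id, optional mean and sd columns."""
    df = pd.read_csv(path, sep="\t")
    features = df["feature_id"].astype(str).tolist()
    mean = sd = None
    if {"mean", "sd"} <= set(df.columns):
        mean = pd.Series(df["mean"].to_numpy(), index=features)
        sd = pd.Series(df["sd"].to_numpy(), index=features)
    return SignaturePanel(features=features, mean=mean, sd=sd)


def write_panel(panel: SignaturePanel, path) -> None:
    df = pd.DataFrame({"feature_id": panel.features})
    if panel.mean is not None and panel.sd is not None:
        df["mean"] = panel.mean.loc[panel.features].to_numpy()
        df["sd"] = panel.sd.loc[panel.features].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def score_samples(expr: pd.DataFrame, panel: SignaturePanel) -> pd.Series:
    """Sum of per-feature z-scores over the panel, per sample.

    By default z-statistics (mean, sd) are computed over all samples being
    scored — matching the cumulative-score definition, at the cost of a
    train/test leakage caveat.  Supplying ``panel.mean``/``panel.sd``
    switches to a fixed reference normalization.  Zero-variance features are
    dropped with a warning before scoring.
    """
    missing = [f for f in panel.features if f not in expr.index]
    if missing:
        raise KeyError(f"panel features missing from matrix: {missing[:5]}")
    sub = expr.loc[panel.features]
    if panel.mean is not None and panel.sd is not None:
        mean = panel.mean.loc[panel.features]
        sd = panel.sd.loc[panel.features]
    else:
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all panel features have zero variance")
    if (~usable).any():
        warnings.warn(
            f"dropped {int((~usable).sum())} zero-variance panel feature(s)"
        )
    z = sub.loc[usable].sub(mean[usable], axis=0).div(sd[usable], axis=0)
    return z.sum(axis=0).rename("score")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_threshold: float
    operating_sensitivity: float
    operating_specificity: float


def roc_curve(scores: pd.Series, labels: pd.Series) -> RocResult:
    """ROC of a score against binary labels (1 = positive class).

    AUC comes from the rank statistic with midrank tie correction (equal to
    the probability that a random positive outranks a random negative, ties
    counting half).  The operating point maximizes Youden's J = sensitivity
    + specificity - 1, ties broken toward higher specificity.  A sample is
    called positive when score >= threshold.
    """
    scores, labels = scores.align(labels, join="inner")
    y = labels.to_numpy(dtype=int)
    s = scores.to_numpy(dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.unique(s)[::-1]
    sens = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] < t).mean() for t in thresholds])
    j = sens + spec - 1
    best = np.flatnonzero(j == j.max())
    # ties toward higher specificity = larger threshold = smaller index order
    best_idx = best[np.argmax(spec[best])]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        operating_threshold=float(thresholds[best_idx]),
        operating_sensitivity=float(sens[best_idx]),
        operating_specificity=float(spec[best_idx]),
    )


def mutual_exclusivity(expr: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Pairwise Spearman correlations of feature expression across samples.

    Mutually exclusive features come out negatively correlated.  Constant
    features are flagged and excluded from the matrix.
    """
    if len(features) < 2:
        raise ValueError("need >=2 features")
    if expr.shape[1] < 3:
        raise ValueError("need >=3 samples")
    sub = expr.loc[features]
    constant = sub.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"constant feature(s) excluded: {list(sub.index[constant])}"
        )
        sub = sub.loc[~constant]
    if len(sub) < 2:
        raise ValueError("fewer than 2 non-constant features")
    rho, _ = stats.spearmanr(sub.to_numpy().T)
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=sub.index, columns=sub.index)
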