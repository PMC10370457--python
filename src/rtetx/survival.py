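"""Expression-stratified survival screening and the dual-cohort
prognostic filter.

For each feature, samples are split into low/high expression tertiles;
the groups are compared with a log-rank test and a univariate Cox
proportional-hazards fit on the binary group indicator (Efron tie
handling, via lifelines).  A feature is prognostic when it passes p and
hazard-ratio thresholds in every cohort with concordant direction; the
summary hazard ratio is the geometric mean across cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


@dataclass
class PrognosticFilter:
    """Dual-cohort prognostic thresholds: Cox p < p_max in every cohort
    separately, concordant direction, and geometric-mean HR >= hr_high
    (adverse) or <= hr_low (protective)."""

    p_max: float = 0.05
    hr_high: float = 2.0
    hr_low: float = 0.5
    use_logrank_p: bool = False  # filter on log-rank p instead of Cox Wald p
    per_cohort_hr: bool = False  # require the HR bound in every cohort

    def __post_init__(self):
        if not 0 < self.hr_low < 1 < self.hr_high:
            raise ValueError("need 0 < hr_low < 1 < hr_high")


def survival_from_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Extract (time, event) per sample from metadata; positive times only."""
    surv = meta[["survival_days", "event"]].dropna()
    surv = surv.rename(columns={"survival_days": "time"})
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return surv.astype({"time": float, "event": int})


def stratify_tertiles(
    values: pd.Series, fraction: float = 1 / 3
) -> tuple[list[str], list[str]]:
    """Bottom- and top-tertile samples by expression.

    Samples are ranked by value with ties broken by sample id; the bottom
    floor(n*fraction) form the low group and the top floor(n*fraction) the
    high group; the middle is excluded.
    """
    n = len(values)
    if n < 6:
        raise ValueError("need >=6 samples to stratify")
    arr = values.to_numpy(dtype=float)
    if np.all(arr == arr[0]):
        raise ValueError("no stratification possible: constant values")
    k = int(np.floor(n * fraction))
    order = sorted(values.index, key=lambda s: (values[s], s))
    return order[:k], order[-k:]


@dataclass
class SurvivalRecord:
    feature: str
    cohort: str
    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    cox_p: float
    n_low: int
    n_high: int
    estimable: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def fit_survival(
    low: list[str],
    high: list[str],
    survival: pd.DataFrame,
    feature: str = "",
    cohort: str = "",
) -> SurvivalRecord:
    """Log-rank test and Cox HR (high vs low) for one stratification.

    Records with a zero-event group are flagged non-estimable and excluded
    from downstream filters.
    """
    low = [s for s in low if s in survival.index]
    high = [s for s in high if s in survival.index]
    t_low = survival.loc[low, "time"].to_numpy()
    e_low = survival.loc[low, "event"].to_numpy()
    t_high = survival.loc[high, "time"].to_numpy()
    e_high = survival.loc[high, "event"].to_numpy()
    record = SurvivalRecord(
        feature=feature, cohort=cohort, hr=np.nan, ci_low=np.nan,
        ci_high=np.nan, logrank_p=np.nan, cox_p=np.nan,
        n_low=len(low), n_high=len(high), estimable=False,
    )
    if e_low.sum() == 0 or e_high.sum() == 0:
        return record

    lr = logrank_test(t_high, t_low, event_observed_A=e_high, event_observed_B=e_low)
    record.logrank_p = float(lr.p_value)

    df = pd.DataFrame(
        {
            "time": np.concatenate([t_low, t_high]),
            "event": np.concatenate([e_low, e_high]),
            "high": np.concatenate([np.zeros(len(low)), np.ones(len(high))]),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone-likelihood / separation failures
        logger.debug("Cox fit failed for %s/%s: %s", feature, cohort, exc)
        return record
    record.hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    record.ci_low = float(np.exp(ci.iloc[0, 0]))
    record.ci_high = float(np.exp(ci.iloc[0, 1]))
    record.cox_p = float(cph.summary["p"].iloc[0])
    record.estimable = np.isfinite(record.hr) and record.hr > 0
    return record


def cohort_survival_screen(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    cohort: str = "",
    features: list[str] | None = None,
    fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Tertile-stratified survival screen of every feature in one cohort."""
    samples = [s for s in expr.columns if s in survival.index]
    records = []
    for feature in features if features is not None else expr.index:
        values = expr.loc[feature, samples]
        try:
            low, high = stratify_tertiles(values, fraction)
        except ValueError:
            records.append(
                SurvivalRecord(feature, cohort, np.nan, np.nan, np.nan,
                               np.nan, np.nan, 0, 0, False).to_dict()
            )
            continue
        records.append(
            fit_survival(low, high, survival, feature=feature, cohort=cohort).to_dict()
        )
    return pd.DataFrame(records).set_index("feature")


def dual_cohort_filter(
    records: dict[str, pd.DataFrame],
    filt: PrognosticFilter | None = None,
) -> pd.DataFrame:
    """Features prognostic in every cohort.

    ``records`` maps cohort name -> screen table (index feature; columns hr,
    cox_p, logrank_p, estimable).  A feature is kept iff it is estimable
    with p < p_max in each cohort, hazard directions agree, and the
    geometric-mean HR is >= hr_high or <= hr_low.  Output columns:
    summary_hr, direction ('adverse'/'protective'), per-cohort HRs and ps.
    """
    if filt is None:
        filt = PrognosticFilter()
    cohorts = sorted(records)
    if not cohorts:
        raise ValueError("no cohorts supplied")
    common = set(records[cohorts[0]].index)
    union = set()
    for c in cohorts:
        union |= set(records[c].index)
        common &= set(records[c].index)
    dropped = union - common
    if dropped:
        logger.info("dual_cohort_filter: %d feature(s) missing in a cohort", len(dropped))

    p_col = "logrank_p" if filt.use_logrank_p else "cox_p"
    rows = []
    for feature in sorted(common):
        recs = [records[c].loc[feature] for c in cohorts]
        if not all(bool(r["estimable"]) for r in recs):
            continue
        if not all(r[p_col] < filt.p_max for r in recs):
            continue
        log_hrs = np.log([r["hr"] for r in recs])
        if np.any(log_hrs == 0) or not (np.all(log_hrs > 0) or np.all(log_hrs < 0)):
            continue  # discordant direction across cohorts
        summary_hr = float(np.exp(log_hrs.mean()))
        if filt.per_cohort_hr:
            hr_ok = all(
                r["hr"] >= filt.hr_high or r["hr"] <= filt.hr_low for r in recs
            )
        else:
            hr_ok = summary_hr >= filt.hr_high or summary_hr <= filt.hr_low
        if not hr_ok:
            continue
        row = {
            "feature": feature,
            "summary_hr": summary_hr,
            "direction": "adverse" if summary_hr > 1 else "protective",
        }
        for c, r in zip(cohorts, recs):
            row[f"hr_{c}"] = float(r["hr"])
            row[f"p_{c}"] = float(r[p_col])
        rows.append(row)
    cols = ["feature", "summary_hr", "direction"] + [
        f"{k}_{c}" for c in cohorts for k in ("hr", "p")
    ]
    return pd.DataFrame(rows, columns=cols).set_index("feature")


def gene_level_prognostics(
    split,
    survival_by_cohort: dict[str, pd.DataFrame],
    samples_by_cohort: dict[str, list[str]],
    filt: PrognosticFilter | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Prognostic screen on exon and intron layers separately, plus the
    intersection with concordance flags.

    Returns (exon prognostic table, intron prognostic table, concordance
    table).  A gene in both layers' prognostic sets is concordant when its
    exon and intron summary hazard ratios point the same way.
    """
    if filt is None:
        filt = PrognosticFilter()
    layer_results = {}
    for layer_name, layer in (("exon", split.exon), ("intron", split.intron)):
        records = {}
        for cohort, samples in samples_by_cohort.items():
            cols = [s for s in samples if s in layer.columns]
            records[cohort] = cohort_survival_screen(
                layer.loc[:, cols], survival_by_cohort[cohort], cohort=cohort
            )
        layer_results[layer_name] = dual_cohort_filter(records, filt)
    exon_res, intron_res = layer_results["exon"], layer_results["intron"]
    both = sorted(set(exon_res.index) & set(intron_res.index))
    concordance = pd.DataFrame(
        {
            "exon_hr": exon_res.loc[both, "summary_hr"].to_numpy(),
            "intron_hr": intron_res.loc[both, "summary_hr"].to_numpy(),
        },
        index=pd.Index(both, name="gene_id"),
    )
    concordance["concordant"] = np.sign(np.log(concordance["exon_hr"])) == np.sign(
        np.log(concordance["intron_hr"])
    )
    return exon_res, intron_res, concordance
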