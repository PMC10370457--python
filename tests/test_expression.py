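"""Selection filter, differential expression, enrichment and complexity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtetx.expression import (
    SelectionThresholds,
    copy_number_bias,
    differential_repeat_expression,
    intersect_selections,
    select_overexpressed,
    subfamily_enrichment,
    transcriptome_complexity,
)


def make_meta(cancer, healthy_by_tissue, matched="esophagus"):
    rows = []
    for s in cancer:
        rows.append({"sample_id": s, "cohort": "C", "condition": "EAC",
                     "matched_tissue": matched})
    for tissue, samples in healthy_by_tissue.items():
        for s in samples:
            rows.append({"sample_id": s, "cohort": "N", "condition": tissue,
                         "matched_tissue": ""})
    return pd.DataFrame(rows).set_index("sample_id")


class TestComplexity:
    def test_all_zero_sample(self):
        expr = pd.DataFrame({"s1": [0.0, 0.0], "s2": [1.0, 0.4]},
                            index=["f1", "f2"])
        counts = transcriptome_complexity(expr)
        assert counts["s1"] == 0 and counts["s2"] == 1

    def test_boundary_inclusive(self):
        expr = pd.DataFrame({"s1": [0.5]}, index=["f1"])
        assert transcriptome_complexity(expr, 0.5)["s1"] == 1

    def test_matches_double_loop(self, rng):
        expr = pd.DataFrame(rng.exponential(1, size=(100, 10)))
        expr.index = expr.index.astype(str)
        expr.columns = expr.columns.astype(str)
        counts = transcriptome_complexity(expr, 0.5)
        for s in expr.columns:
            naive = sum(1 for f in expr.index if expr.loc[f, s] >= 0.5)
            assert counts[s] == naive


class TestSelection:
    def _run(self, cancer_vals, healthy_vals, **kw):
        cancer = [f"c{i}" for i in range(len(cancer_vals))]
        healthy = [f"h{i}" for i in range(len(healthy_vals))]
        expr = pd.DataFrame(
            [cancer_vals + healthy_vals], index=["f1"], columns=cancer + healthy
        )
        meta = make_meta(cancer, {"esophagus": healthy})
        return select_overexpressed(expr, meta, "EAC", **kw)

    def test_healthy_zero_cancer_expressed_selected(self):
        selected, _ = self._run([1.0] * 6, [0.0] * 6)
        assert selected == ["f1"]

    def test_cancer_median_boundary_strict(self):
        selected, table = self._run([0.4] * 6, [0.0] * 6)
        assert selected == []
        selected, _ = self._run([0.5] * 6, [0.0] * 6)
        assert selected == []  # strict > 0.5
        selected, _ = self._run([0.51] * 6, [0.0] * 6)
        assert selected == ["f1"]

    def test_fold_condition_arithmetic(self):
        # H = 0.2 (constant healthy): 3*0.2=0.6 > q75C=0.5 -> rejected
        selected, t = self._run([0.5] * 3 + [0.6] * 3, [0.2] * 6)
        assert selected == []
        # q75C = 0.7 >= 0.6 -> selected
        selected, t = self._run([0.6] * 2 + [0.7] * 4, [0.2] * 6)
        assert selected == ["f1"]

    def test_percentiles_match_sorting_oracle(self, rng):
        # statistics table must agree with direct order-statistic arithmetic
        cancer_vals = list(rng.exponential(2, 9).round(3))
        healthy_vals = list(rng.exponential(0.3, 7).round(3))
        _, table = self._run(cancer_vals, healthy_vals)
        mC = float(np.median(cancer_vals))
        q75 = float(np.percentile(cancer_vals, 75))
        h = max(
            float(np.percentile(healthy_vals, 90)),
            float(np.median(healthy_vals)),
        )
        assert table.loc["f1", "median_cancer"] == pytest.approx(mC)
        assert table.loc["f1", "q_cancer"] == pytest.approx(q75)
        assert table.loc["f1", "healthy_summary"] == pytest.approx(h)

    def test_missing_matched_tissue_errors(self):
        expr = pd.DataFrame([[1.0]], index=["f1"], columns=["c0"])
        meta = pd.DataFrame(
            [{"sample_id": "c0", "cohort": "C", "condition": "EAC",
              "matched_tissue": ""}]
        ).set_index("sample_id")
        with pytest.raises(ValueError, match="matched"):
            select_overexpressed(expr, meta, "EAC")

    def test_monotone_in_perturbations(self, rng):
        # raising cancer values or lowering healthy values never de-selects
        cancer = [f"c{i}" for i in range(8)]
        healthy = [f"h{i}" for i in range(8)]
        expr = pd.DataFrame(
            rng.exponential(1.0, size=(20, 16)),
            index=[f"f{i}" for i in range(20)],
            columns=cancer + healthy,
        )
        meta = make_meta(cancer, {"esophagus": healthy})
        base_sel, _ = select_overexpressed(expr, meta, "EAC")
        base = set(base_sel)
        for _ in range(200):
            pert = expr.copy()
            f = pert.index[int(rng.integers(20))]
            if rng.random() < 0.5:
                s = cancer[int(rng.integers(8))]
                pert.loc[f, s] += float(rng.exponential(1.0))
            else:
                s = healthy[int(rng.integers(8))]
                pert.loc[f, s] *= float(rng.random())
            new_sel, _ = select_overexpressed(pert, meta, "EAC")
            assert base <= set(new_sel) | (base - {f})
            # only the perturbed feature may change, and only by joining
            assert base - {f} <= set(new_sel) | {f}
            if f in base:
                assert f in new_sel

    def test_recovery_on_synthetic_truth(self, dataset):
        sel, _ = select_overexpressed(dataset.expr, dataset.meta, "EAC")
        planted = set(dataset.truth.planted_overexpressed)
        specials = set(dataset.truth.exclusive_pair)
        assert planted <= set(sel)  # sensitivity 1.0
        assert set(sel) - planted - specials == set()  # no false positives

    def test_intersection_utility(self):
        assert intersect_selections(["a", "b", "c"], ["c", "a"]) == ["a", "c"]


class TestDifferentialExpression:
    def test_identical_groups_zero_passes(self, rng):
        vals = rng.exponential(1, size=(30, 6))
        expr = pd.DataFrame(np.hstack([vals, vals]),
                            columns=[f"s{i}" for i in range(12)])
        expr.index = expr.index.astype(str)
        res = differential_repeat_expression(
            expr, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        )
        assert res["pass"].sum() == 0

    def test_fold_exactly_six_fails(self):
        # construct means so that (meanA+0.1)/(meanB+0.1) == 6 exactly
        a = np.full(20, 6 * 1.1 - 0.1)
        b = np.full(20, 1.0)
        a += np.linspace(-1e-9, 1e-9, 20)  # negligible variance, p ~ 0
        b += np.linspace(-1e-9, 1e-9, 20)
        expr = pd.DataFrame([np.concatenate([a, b])],
                            index=["f1"],
                            columns=[f"s{i}" for i in range(40)])
        res = differential_repeat_expression(
            expr, [f"s{i}" for i in range(20)], [f"s{i}" for i in range(20, 40)]
        )
        assert abs(res.loc["f1", "log2_fold_change"] - math.log2(6)) < 1e-6
        assert not res.loc["f1", "pass"]

    def test_planted_eightfold_shift_detected(self):
        rng = np.random.default_rng(7)
        detected = 0
        n_rep = 50
        for _ in range(n_rep):
            log_b = rng.normal(1.0, 0.3, 20)
            log_a = rng.normal(1.0 + 3.0, 0.3, 20)  # 8-fold in log2
            expr = pd.DataFrame(
                [np.concatenate([2.0**log_a, 2.0**log_b])],
                index=["f1"], columns=[f"s{i}" for i in range(40)],
            )
            res = differential_repeat_expression(
                expr, [f"s{i}" for i in range(20)],
                [f"s{i}" for i in range(20, 40)],
            )
            detected += int(res.loc["f1", "pass"])
        assert detected >= 0.99 * n_rep

    def test_zero_variance_flagged(self):
        expr = pd.DataFrame(
            [[1.0] * 8], index=["f1"], columns=[f"s{i}" for i in range(8)]
        )
        res = differential_repeat_expression(
            expr, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        )
        assert res.loc["f1", "zero_variance"]
        assert res.loc["f1", "p"] == 1.0


def exact_fisher_two_sided(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact integer arithmetic."""
    m, r, n = a + c, a + b, a + b + c + d
    denom = math.comb(n, m)
    n_obs = math.comb(r, a) * math.comb(n - r, m - a)
    total = 0
    for k in range(max(0, m - (n - r)), min(r, m) + 1):
        n_k = math.comb(r, k) * math.comb(n - r, m - k)
        if n_k <= n_obs:
            total += n_k
    return total / denom


class TestEnrichment:
    def test_equal_proportions_give_null(self):
        selected = [f"s{i}" for i in range(10)]
        rest = [f"r{i}" for i in range(20)]
        membership = {"AluSx": set(selected[:5] + rest[:10])}
        res = subfamily_enrichment(selected, selected + rest, membership)
        assert res.loc["AluSx", "odds_ratio"] == pytest.approx(1.0)
        assert res.loc["AluSx", "p"] == pytest.approx(1.0)

    def test_hand_table_matches_hypergeometric_oracle(self):
        selected = [f"s{i}" for i in range(10)]
        rest = [f"r{i}" for i in range(100)]
        membership = {"L1HS": set(selected[:8] + rest[:10])}
        res = subfamily_enrichment(selected, selected + rest, membership)
        assert res.loc["L1HS", ["a", "b", "c", "d"]].tolist() == [8, 2, 10, 90]
        assert res.loc["L1HS", "p"] == pytest.approx(
            exact_fisher_two_sided(8, 2, 10, 90), abs=1e-12
        )

    def test_depletion_gives_or_below_one(self):
        selected = [f"s{i}" for i in range(10)]
        rest = [f"r{i}" for i in range(20)]
        membership = {"SVA_D": set(rest[:10])}
        res = subfamily_enrichment(selected, selected + rest, membership)
        assert res.loc["SVA_D", "odds_ratio"] < 1

    def test_selected_not_subset_errors(self):
        with pytest.raises(ValueError):
            subfamily_enrichment(["x"], ["y"], {"a": {"x"}})

    def test_absent_subfamily_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = subfamily_enrichment(
                ["s1"], ["s1", "s2"], {"ghost": {"zz"}, "ok": {"s1"}}
            )
        assert list(res.index) == ["ok"]

    def test_bh_q_monotone_and_bounded(self, rng):
        selected = [f"s{i}" for i in range(15)]
        rest = [f"r{i}" for i in range(60)]
        membership = {
            f"fam{j}": set(
                np.array(selected + rest)[
                    rng.random(75) < rng.uniform(0.05, 0.6)
                ]
            )
            for j in range(8)
        }
        membership = {k: v for k, v in membership.items() if v}
        res = subfamily_enrichment(selected, selected + rest, membership)
        assert (res["q"] <= 1).all()
        ordered = res.sort_values("p")
        assert ordered["q"].is_monotonic_increasing


class TestCopyNumberBias:
    def _enrich(self, ors):
        return pd.DataFrame({"odds_ratio": ors},
                            index=[f"f{i}" for i in range(len(ors))])

    def test_perfect_monotone_gives_rho_one(self):
        cn = pd.Series([10, 100, 1000, 5000], index=[f"f{i}" for i in range(4)])
        rho, _ = copy_number_bias(self._enrich([1.1, 1.5, 2.5, 4.0]), cn)
        assert rho == pytest.approx(1.0)

    def test_five_point_table_matches_rank_formula(self):
        ors = [0.5, 2.0, 1.2, 3.0, 0.8]
        cn = pd.Series([50, 300, 120, 800, 20],
                       index=[f"f{i}" for i in range(5)])
        rho, _ = copy_number_bias(self._enrich(ors), cn)
        expected = stats.spearmanr(cn.to_numpy(), np.log(ors))[0]
        # direct rank-difference formula (no ties)
        rx = stats.rankdata(cn.to_numpy())
        ry = stats.rankdata(np.log(ors))
        d2 = ((rx - ry) ** 2).sum()
        formula = 1 - 6 * d2 / (5 * 24)
        assert rho == pytest.approx(expected) == pytest.approx(formula)

    def test_too_few_subfamilies_errors(self):
        cn = pd.Series([10, 20], index=["f0", "f1"])
        with pytest.raises(ValueError):
            copy_number_bias(self._enrich([1.0, 2.0]), cn)

    def test_constant_vector_errors(self):
        cn = pd.Series([10, 10, 10], index=["f0", "f1", "f2"])
        with pytest.raises(ValueError, match="undefined"):
            copy_number_bias(self._enrich([1.0, 2.0, 3.0]), cn)
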