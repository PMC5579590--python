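"""Split, adjusted AUC (DeLong), comparator choice, pattern evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polypattern.association import CorrelationTable
from polypattern.evaluation import (
    EvaluationError,
    EvaluationRow,
    adjusted_auc,
    best_single_biomarker,
    build_report,
    delong_auc_variance,
    delong_ci,
    evaluate_pattern,
    split_two_fold,
)
from polypattern.pipeline import PipelineConfig, preprocess_cohort
from polypattern.selection import SelectionResult
from polypattern.synthetic import generate_cohort, loading_for_target_correlation

from conftest import make_config


class TestSplit:
    def test_floor_rule(self):
        s = split_two_fold(475, seed=0)
        assert len(s.test_idx) == 237
        assert len(s.train_idx) == 238
        assert len(set(s.test_idx) | set(s.train_idx)) == 475

    def test_determinism_and_seed_sensitivity(self):
        a = split_two_fold(100, seed=5)
        b = split_two_fold(100, seed=5)
        c = split_two_fold(100, seed=6)
        assert np.array_equal(a.test_idx, b.test_idx)
        assert not np.array_equal(a.test_idx, c.test_idx)
        assert len(c.test_idx) == len(c.train_idx) == 50

    def test_too_small_raises(self):
        with pytest.raises(EvaluationError):
            split_two_fold(3, seed=0)


# Frozen independent oracle: R pROC (method = "delong") on this dataset
# gives auc = 0.7625, 95% CI (0.6123978300, 0.9126021700),
# var = 0.005865131579.
_ORACLE_SCORES = [
    1.028857, 1.64192, 1.14672, -0.97318, -1.3928, 0.067196, 0.861351,
    0.509187, 1.810286, 0.750843, 0.63976, -0.731323, -1.107717, 1.484406,
    0.048912, 0.81152, -1.376423, -0.436371, -1.291092, -0.775679, 2.103063,
    -0.280581, 0.665907, 1.363789, 0.53153, 0.94771, 0.978138, 1.618139,
    0.768745, 1.472261, 1.256819, 1.624569, 1.424943, 2.857684, 0.536324,
    2.399187, 0.797388, 0.242074, 2.411194, 0.760494,
]
_ORACLE_LABELS = [0] * 20 + [1] * 20


class TestDeLong:
    def test_proc_oracle(self):
        auc, var = delong_auc_variance(
            np.array(_ORACLE_SCORES), np.array(_ORACLE_LABELS)
        )
        assert auc == pytest.approx(0.7625, abs=1e-10)
        assert var == pytest.approx(0.005865131579, rel=1e-6)
        auc2, (lo, hi) = delong_ci(_ORACLE_SCORES, _ORACLE_LABELS)
        assert lo == pytest.approx(0.61239783, abs=1e-6)
        assert hi == pytest.approx(0.91260217, abs=1e-6)

    def test_perfect_and_ties(self):
        auc, _ = delong_auc_variance(np.array([0, 0, 1, 1.0]), np.array([0, 0, 1, 1]))
        assert auc == 1.0
        auc, _ = delong_auc_variance(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))
        assert auc == 0.5

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            delong_auc_variance(np.arange(5.0), np.ones(5, dtype=int))


class TestAdjustedAUC:
    def _cov(self, rng, n):
        return np.column_stack([
            rng.integers(0, 2, n),
            rng.normal(26, 4, n),
            rng.normal(54, 8, n),
        ])

    def test_perfect_score(self, rng):
        n = 200
        lab = rng.integers(0, 2, n)
        out = adjusted_auc(lab.astype(float), lab, self._cov(rng, n))
        assert out.auc > 0.99
        assert not np.isnan(out.baseline_auc)

    def test_null_centers_on_half(self, rng):
        aucs = [
            adjusted_auc(rng.normal(0, 1, 150), rng.integers(0, 2, 150),
                         self._cov(rng, 150)).auc
            for _ in range(30)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.04)

    def test_binormal_closed_form(self, rng):
        """Binormal shift d with uninformative covariates: AUC -> Phi(d/sqrt(2))."""
        d = 1.0
        target = stats.norm.cdf(d / np.sqrt(2))
        aucs = []
        for _ in range(40):
            n = 300
            lab = rng.integers(0, 2, n)
            scorev = rng.normal(0, 1, n) + d * lab
            aucs.append(adjusted_auc(scorev, lab, self._cov(rng, n)).auc)
        assert np.mean(aucs) == pytest.approx(target, abs=0.02)

    def test_monotone_invariance_with_uninformative_covariates(self, rng):
        """AUC driven by the score ranking is invariant to strictly monotone
        transforms of the score."""
        n = 400
        lab = rng.integers(0, 2, n)
        s = rng.normal(0, 1, n) + 1.5 * lab
        Z = self._cov(rng, n)
        a1 = adjusted_auc(s, lab, Z).auc
        a2 = adjusted_auc(np.exp(s / 2.0), lab, Z).auc
        assert a1 == pytest.approx(a2, abs=0.02)

    def test_separation_still_returns(self, rng):
        n = 60
        lab = np.array([0] * 30 + [1] * 30)
        s = lab * 10.0  # complete separation
        out = adjusted_auc(s, lab, self._cov(rng, n))
        assert out.auc == pytest.approx(1.0, abs=1e-9)


def _corr_table(r_vals, foods=("f",)):
    mets = [f"m{j}" for j in range(len(r_vals[0]))]
    r = pd.DataFrame(list(r_vals), index=list(foods), columns=mets)
    return CorrelationTable(r=r, p=r.abs() * 0 + 0.01, n=100,
                            covariate_names=["sex", "bmi", "age"])


class TestBestSingleBiomarker:
    def test_highest_positive_wins(self):
        tab = _corr_table([[0.2, 0.5, -0.9]])
        assert best_single_biomarker(tab, "f") == "m1"

    def test_tie_goes_to_lower_index(self):
        tab = _corr_table([[0.4, 0.4, 0.1]])
        assert best_single_biomarker(tab, "f") == "m0"

    def test_single_metabolite(self):
        tab = _corr_table([[0.3]])
        assert best_single_biomarker(tab, "f") == "m0"

    def test_no_positive_raises(self):
        tab = _corr_table([[-0.3, -0.1]])
        with pytest.raises(EvaluationError):
            best_single_biomarker(tab, "f")

    def test_unknown_food_raises(self):
        with pytest.raises(EvaluationError):
            best_single_biomarker(_corr_table([[0.3]]), "nope")


class TestEvaluatePattern:
    def _processed(self, seed=7, rho=0.6, n=300):
        lam = np.zeros((4, 10))
        lam[0, 0] = loading_for_target_correlation(rho, 1.0)
        cohort = generate_cohort(make_config(n_subjects=n, loading_matrix=lam,
                                             seed=seed))
        return preprocess_cohort(cohort, PipelineConfig())

    def test_size_one_selection_equals_single_biomarker(self):
        """A one-metabolite pattern is a monotone transform of that
        metabolite: r and AUC match the single-biomarker comparator."""
        proc = self._processed()
        split = split_two_fold(300, seed=1)
        sel_pattern = SelectionResult(
            food="food1", method="RRR-VIP", selected=["met1"],
            statistic=pd.Series([2.0], index=["met1"]),
        )
        sel_single = SelectionResult(
            food="food1", method="single-PP", selected=["met1"],
            statistic=pd.Series([1.0], index=["met1"]),
        )
        a = evaluate_pattern(proc, "food1", sel_pattern, split)
        b = evaluate_pattern(proc, "food1", sel_single, split, method="single-PP")
        assert a.r == pytest.approx(b.r, abs=1e-10)
        assert a.auc == pytest.approx(b.auc, abs=1e-10)

    def test_null_generator_centers_on_zero_and_half(self):
        rs, aucs = [], []
        sel = SelectionResult(
            food="food1", method="RRR-VIP", selected=["met1", "met2", "met3"],
            statistic=pd.Series([1.0, 1.0, 1.0], index=["met1", "met2", "met3"]),
        )
        for seed in range(15):
            lam = np.zeros((4, 10))
            cohort = generate_cohort(make_config(n_subjects=200,
                                                 loading_matrix=lam, seed=seed))
            proc = preprocess_cohort(cohort, PipelineConfig())
            row = evaluate_pattern(proc, "food1", sel, split_two_fold(200, seed))
            rs.append(row.r)
            aucs.append(row.auc)
        assert np.mean(rs) == pytest.approx(0.0, abs=0.05)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_strong_loading_gives_high_auc(self):
        proc = self._processed(rho=0.65, n=400, seed=3)
        sel = SelectionResult(
            food="food1", method="RRR-VIP", selected=["met1"],
            statistic=pd.Series([2.0], index=["met1"]),
        )
        row = evaluate_pattern(proc, "food1", sel, split_two_fold(400, seed=2))
        assert row.r > 0.45
        assert row.auc > 0.75

    def test_empty_selection_raises(self):
        proc = self._processed()
        sel = SelectionResult(food="food1", method="RRR-VIP", selected=[],
                              statistic=pd.Series(dtype=float))
        with pytest.raises(EvaluationError):
            evaluate_pattern(proc, "food1", sel, split_two_fold(300, seed=0))

    def test_no_test_leakage(self):
        """Training weights and comparator do not change when test-fold
        metabolite rows are permuted."""
        proc = self._processed()
        split = split_two_fold(300, seed=4)
        sel = SelectionResult(
            food="food1", method="RRR-VIP", selected=["met1", "met2"],
            statistic=pd.Series([2.0, 1.0], index=["met1", "met2"]),
        )
        from polypattern.rrr import fit_rrr

        X = proc.metabolites.values[sel.selected]
        y = proc.intake_24hdr.values["food1"]
        m1 = fit_rrr(X.iloc[split.train_idx], y.iloc[split.train_idx], rank=1)
        X_shuffled = X.copy()
        X_shuffled.iloc[split.test_idx] = X.iloc[
            np.random.default_rng(0).permutation(split.test_idx)
        ].to_numpy()
        m2 = fit_rrr(X_shuffled.iloc[split.train_idx],
                     y.iloc[split.train_idx], rank=1)
        assert np.allclose(m1.weights, m2.weights)


class TestBuildReport:
    def _row(self, food="f", method="single-PP", instrument="24-HDR"):
        return EvaluationRow(
            food=food, instrument=instrument, method=method,
            comparator_name=None, n_selected=1, consumer_pct=0.4,
            r=0.5, p=0.01, auc=0.8, auc_ci=(0.7, 0.9),
            baseline_auc=0.55, converged=True,
        )

    def test_empty_report_has_header(self):
        rep = build_report([])
        assert rep.empty
        assert "auc_pct" in rep.columns

    def test_one_row(self):
        rep = build_report([self._row()])
        assert len(rep) == 1
        assert rep.loc[0, "auc_pct"] == 80.0
        assert rep.loc[0, "consumer_pct"] == 40.0

    def test_duplicate_key_raises(self):
        with pytest.raises(EvaluationError, match="duplicate"):
            build_report([self._row(), self._row()])

    def test_ci_must_contain_auc(self):
        with pytest.raises(EvaluationError):
            EvaluationRow(
                food="f", instrument="24-HDR", method="single-PP",
                comparator_name=None, n_selected=1, consumer_pct=0.4,
                r=0.5, p=0.01, auc=0.95, auc_ci=(0.7, 0.9),
                baseline_auc=0.5, converged=True,
            )
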