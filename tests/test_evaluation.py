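"""Cross-validation harness, corrected phenotypes, metrics and model
comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gpsel import (
    SimConfig,
    TraitArchitecture,
    accuracy,
    bias,
    compare_models,
    corrected_phenotype,
    make_chip_subset,
    make_folds,
    run_cv,
    simulate_genotypes,
    simulate_traits,
)
from gpsel.evaluation import (
    CVReport,
    MetricError,
    StudyData,
    _SelectionCache,
    ols_residuals,
    trait_design,
)


class TestFolds:
    def test_published_cohort_size_splits_into_51_52(self):
        plan = make_folds(np.arange(513), k=10, seed=1)
        sizes = np.bincount(plan.assignments)
        assert set(sizes) <= {51, 52}
        assert sizes.sum() == 513

    def test_leave_one_out_limit(self):
        plan = make_folds(np.arange(10), k=10, seed=2)
        assert np.bincount(plan.assignments).tolist() == [1] * 10

    def test_deterministic_under_seed(self):
        a = make_folds(np.arange(100), k=10, seed=3)
        b = make_folds(np.arange(100), k=10, seed=3)
        assert np.array_equal(a.assignments, b.assignments)

    def test_partition_exhaustive_and_disjoint(self):
        plan = make_folds(np.arange(97), k=10, seed=4)
        all_rows = np.concatenate([plan.validation_rows(f) for f in range(10)])
        assert sorted(all_rows) == list(range(97))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.arange(5), k=10, seed=0)


class TestCorrectedPhenotype:
    def test_no_fixed_effects_gives_centered_phenotype(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        resid = ols_residuals(y, np.zeros((4, 0)))
        assert np.allclose(resid, y - y.mean())

    def test_phenotype_linear_in_cw_leaves_zero_residuals(self):
        rng = np.random.default_rng(5)
        n = 80
        pheno = pd.DataFrame({
            "id": [str(i) for i in range(n)],
            "sex": rng.integers(0, 2, n),
            "batch": rng.integers(1, 6, n),
            "cw": rng.normal(90, 5, n),
        })
        pheno["cw_type"] = np.where(pheno["batch"] <= 4, 1, 2)
        pheno["trait2"] = 3.0 + 0.25 * pheno["cw"]
        pheno["trait1"] = 0.0
        resid = corrected_phenotype(pheno, 1)
        assert np.abs(resid).max() < 1e-9

    def test_split_group_equals_separate_fits(self):
        """The two-record-type adjustment must equal independently fitted
        per-group regressions, concatenated back in order."""
        rng = np.random.default_rng(6)
        n = 120
        pheno = pd.DataFrame({
            "id": [str(i) for i in range(n)],
            "sex": rng.integers(0, 2, n),
            "batch": rng.integers(1, 6, n),
            "cw": rng.normal(90, 5, n),
        })
        pheno["cw_type"] = np.where(pheno["batch"] <= 4, 1, 2)
        pheno["trait2"] = rng.normal(size=n) + 0.1 * pheno["cw"] + 0.3 * pheno["sex"]
        pheno["trait1"] = 0.0
        resid = corrected_phenotype(pheno, 1)
        for grp in (1, 2):
            mask = (pheno["cw_type"] == grp).to_numpy()
            sub = pheno[mask]
            X = np.column_stack([
                np.ones(mask.sum()),
                sub["sex"].to_numpy(float),
                pd.get_dummies(sub["batch"], drop_first=True).to_numpy(float),
                sub["cw"].to_numpy(float) - sub["cw"].mean(),
            ])
            beta, *_ = np.linalg.lstsq(X, sub["trait2"].to_numpy(), rcond=None)
            oracle = sub["trait2"].to_numpy() - X @ beta
            assert np.allclose(resid[mask], oracle, atol=1e-9)

    def test_rank_deficiency_names_aliased_column(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(MetricError, match="aliased"):
            ols_residuals(y, X, names=["c1", "c2"])


class TestMetrics:
    def test_perfect_prediction(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        assert accuracy(g, g) == pytest.approx(1.0)
        assert bias(g, g) == pytest.approx(1.0)

    def test_halved_gebv_doubles_slope(self):
        c = np.array([1.0, 2.0, 3.0, 5.0])
        assert bias(c / 2, c) == pytest.approx(2.0)
        assert accuracy(c / 2, c) == pytest.approx(1.0)

    def test_anticorrelated(self):
        g = np.array([1.0, 2.0, 3.0])
        assert accuracy(g, -g) == pytest.approx(-1.0)

    def test_constant_gebv_undefined(self):
        with pytest.raises(MetricError):
            accuracy(np.ones(5), np.arange(5.0))
        with pytest.raises(MetricError):
            bias(np.ones(5), np.arange(5.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance_and_inverse_scaling(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        g = rng.standard_normal(30)
        c = g + rng.standard_normal(30)
        assert accuracy(scale * g + shift, c) == pytest.approx(accuracy(g, c), abs=1e-9)
        assert bias(scale * g, c) == pytest.approx(bias(g, c) / scale, rel=1e-9)


class TestCompareModels:
    @staticmethod
    def _report(acc_by_model, biases=None):
        rows = []
        for m, accs in acc_by_model.items():
            for f, a in enumerate(accs):
                rows.append({
                    "model": m, "dataset": 1, "trait": 0, "fold": f,
                    "accuracy": a,
                    "bias": 1.0 if biases is None else biases[m][f],
                    "failed": False, "message": "",
                })
        return CVReport(cells=pd.DataFrame(rows))

    def test_identical_accuracies_give_p_one(self):
        rep = self._report({"A": [0.3, 0.4, 0.35, 0.32], "B": [0.3, 0.4, 0.35, 0.32]})
        compare_models(rep)
        pair = rep.tukey["trait1"]["pairs"]["A:d1 vs B:d1"]
        assert pair == pytest.approx(1.0)

    def test_tukey_matches_hand_computed_studentized_range(self):
        """Independent oracle: group means, pooled MSE and the studentized
        range distribution, computed from first principles."""
        groups = {
            "A": [0.30, 0.35, 0.25, 0.40],
            "B": [0.50, 0.55, 0.45, 0.60],
            "C": [0.32, 0.38, 0.30, 0.36],
        }
        rep = self._report(groups)
        compare_models(rep)
        k, n = 3, 4
        df = k * (n - 1)
        means = {m: np.mean(v) for m, v in groups.items()}
        mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
        for pair_name, (a, b) in [("A:d1 vs B:d1", ("A", "B")),
                                  ("A:d1 vs C:d1", ("A", "C")),
                                  ("B:d1 vs C:d1", ("B", "C"))]:
            q = abs(means[a] - means[b]) / np.sqrt(mse / n)
            p_hand = stats.studentized_range.sf(q, k, df)
            assert rep.tukey["trait1"]["pairs"][pair_name] == pytest.approx(p_hand, abs=1e-6)

    def test_unit_biases_give_t_test_p_one(self):
        rep = self._report(
            {"A": [0.3, 0.4, 0.35, 0.32], "B": [0.5, 0.55, 0.45, 0.6]},
            biases={"A": [1.0] * 4, "B": [1.2, 0.9, 1.1, 1.05]},
        )
        compare_models(rep)
        assert rep.bias_tests["A:d1:trait1"]["p"] == pytest.approx(1.0)
        assert rep.bias_tests["B:d1:trait1"]["p"] < 1.0

    def test_single_model_comparison_skipped(self):
        rep = self._report({"A": [0.3, 0.4, 0.35, 0.32]})
        compare_models(rep)
        assert "note" in rep.tukey["trait1"]


@pytest.fixture(scope="module")
def cv_study():
    cfg = SimConfig(n_individuals=250, n_chromosomes=2, snps_per_chromosome=200,
                    chip_fraction=0.25, seed=88)
    wgs = simulate_genotypes(cfg)
    pheno, truth = simulate_traits(wgs, TraitArchitecture(), seed=89)
    chip = make_chip_subset(wgs, 0.25)
    return StudyData(chip=chip, wgs=wgs, pheno=pheno), truth


class TestRunCV:
    def test_grid_bookkeeping_and_recomputable_aggregates(self, cv_study):
        data, _ = cv_study
        folds = make_folds(data.pheno["id"].to_numpy(), k=4, seed=7)
        rep = run_cv([("ST-GBLUP", 1), ("ST-MABLUP", 1)], data, folds,
                     target_trait=0, k_pcs=0)
        ok = rep.cells[~rep.cells["failed"]]
        assert len(ok) == 2 * 4
        assert not rep.cells["failed"].any()
        agg = rep.aggregates
        row = agg[(agg["model"] == "ST-GBLUP")].iloc[0]
        manual = ok[ok["model"] == "ST-GBLUP"]["accuracy"]
        assert row["accuracy_mean"] == pytest.approx(manual.mean())
        assert row["accuracy_se"] == pytest.approx(manual.std(ddof=1) / 2.0)

    def test_identical_fold_plans_across_models(self, cv_study):
        data, _ = cv_study
        folds = make_folds(data.pheno["id"].to_numpy(), k=4, seed=7)
        rep = run_cv([("ST-GBLUP", 1), ("ST-GBLUP", 3)], data, folds,
                     target_trait=0, k_pcs=0)
        a = rep.cells[rep.cells["dataset"] == 1].sort_values("fold")["fold"]
        b = rep.cells[rep.cells["dataset"] == 3].sort_values("fold")["fold"]
        assert list(a) == list(b)

    def test_validation_phenotypes_never_reach_training_selection(self, cv_study):
        """Corrupting validation-fold phenotypes must not change which SNPs
        the training-fold scan selects."""
        data, _ = cv_study
        folds = make_folds(data.pheno["id"].to_numpy(), k=4, seed=9)
        designs = {t: trait_design(data.pheno, t) for t in (0, 1)}
        thresholds = {"chip": 1.0 / data.chip.n_snps, "wgs": 1.0 / 200}
        n_eff = {"chip": data.chip.n_snps, "wgs": 200}
        cache1 = _SelectionCache(data, folds, designs, thresholds, n_eff, k_pcs=0)
        sel1 = cache1.get("wgs", 0, 0)

        corrupted = StudyData(chip=data.chip, wgs=data.wgs, pheno=data.pheno.copy())
        val = folds.validation_rows(0)
        corrupted.pheno.loc[val, "trait1"] = 1e6
        cache2 = _SelectionCache(corrupted, folds, designs, thresholds, n_eff, k_pcs=0)
        sel2 = cache2.get("wgs", 0, 0)
        assert sel1.significant_ids == sel2.significant_ids
        assert sel1.top_snp == sel2.top_snp

    def test_failed_cells_recorded_not_fatal(self, cv_study):
        data, _ = cv_study
        broken = StudyData(chip=data.chip, wgs=data.wgs, pheno=data.pheno.copy())
        broken.pheno["trait1"] = 0.0  # constant phenotype breaks the scan
        folds = make_folds(data.pheno["id"].to_numpy(), k=3, seed=11)
        rep = run_cv([("ST-MABLUP", 1)], broken, folds, target_trait=0, k_pcs=0)
        assert rep.cells["failed"].all()
        assert (rep.cells["message"] != "").all()
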