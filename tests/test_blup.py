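"""Mixed-model machinery: REML, Henderson equations, estimator contracts
and the study-design model assembly."""

import numpy as np
import pytest

from gpsel import (
    GBLUP,
    MABLUP,
    MultiBLUP,
    OneBLUP,
    SimConfig,
    TraitArchitecture,
    build_model,
    compute_grm,
    make_chip_subset,
    simulate_genotypes,
    simulate_traits,
)
from gpsel.evaluation import trait_design
from gpsel.gwas import SNPSelection
from gpsel.lmm import VarianceComponents, reml_general, reml_single


@pytest.fixture(scope="module")
def pop():
    cfg = SimConfig(n_individuals=300, n_chromosomes=3, snps_per_chromosome=250,
                    chip_fraction=0.2, seed=42)
    panel = simulate_genotypes(cfg)
    pheno, truth = simulate_traits(panel, TraitArchitecture(), seed=43)
    return panel, pheno, truth


class TestREML:
    def test_single_trait_recovery_is_reasonable(self, pop):
        panel, pheno, truth = pop
        G = compute_grm(panel)
        X = np.column_stack([np.ones(300), trait_design(pheno, 0)[0]])
        vc = reml_single(pheno["trait1"].to_numpy(), X, G.regularized())
        assert vc.converged
        assert abs(vc.h2(0) - truth.realized_h2[0]) < 0.2

    def test_pure_noise_has_near_zero_heritability(self, pop):
        panel, _, _ = pop
        G = compute_grm(panel).regularized()
        rng = np.random.default_rng(7)
        X = np.ones((300, 1))
        low = sum(
            reml_single(rng.standard_normal(300), X, G).h2(0) < 0.1 for _ in range(5)
        )
        assert low >= 4

    def test_multitrait_matches_single_trait_when_one_trait_missing(self, pop):
        panel, pheno, _ = pop
        G = compute_grm(panel).regularized()
        X1 = np.column_stack([np.ones(300), trait_design(pheno, 0)[0]])
        y = pheno["trait1"].to_numpy()
        Y = np.column_stack([y, np.full(300, np.nan)])
        vc_st = reml_single(y, X1, G)
        vc_mt = reml_general(Y, [X1, np.ones((300, 1))], [G])
        assert abs(vc_mt.h2(0) - vc_st.h2(0)) < 0.02

    def test_multitrait_psd_covariances(self, pop):
        panel, pheno, _ = pop
        G = compute_grm(panel).regularized()
        X1 = np.column_stack([np.ones(300), trait_design(pheno, 0)[0]])
        X2 = np.column_stack([np.ones(300), trait_design(pheno, 1)[0]])
        Y = np.column_stack([pheno["trait1"], pheno["trait2"]])
        vc = reml_general(Y, [X1, X2], [G])
        for S in vc.genetic + [vc.residual]:
            assert np.linalg.eigvalsh(S).min() >= -1e-9
        assert 0.0 <= vc.h2(0) <= 1.0 and 0.0 <= vc.h2(1) <= 1.0


class TestGBLUP:
    def test_henderson_equations_satisfied(self, pop):
        """The masked-phenotype BLUP solves Henderson's MME on training rows."""
        panel, pheno, _ = pop
        y = pheno["trait1"].to_numpy().copy()
        val = np.arange(30)
        ym = y.copy()
        ym[val] = np.nan
        design = trait_design(pheno, 0)[0]
        model = GBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, ym, covariates=design)
        obs = np.flatnonzero(np.isfinite(ym))
        Xo = np.column_stack([np.ones(300), design])[obs]
        G = model._terms_[0]
        K = (model._train_Z_[0] @ model._train_Z_[0].T) / G["scale"] + model.ridge * np.eye(300)
        lam = 0.7 / 0.3
        Z = np.zeros((len(obs), 300))
        Z[np.arange(len(obs)), obs] = 1.0
        Kinv = np.linalg.inv(K)
        lhs = np.block([
            [Xo.T @ Xo, Xo.T @ Z],
            [Z.T @ Xo, Z.T @ Z + lam * Kinv],
        ])
        rhs = np.concatenate([Xo.T @ ym[obs], Z.T @ ym[obs]])
        sol = np.concatenate([model.beta_[0], model.components_["grm0"][:, 0]])
        resid = lhs @ sol - rhs
        assert np.linalg.norm(resid) / np.linalg.norm(rhs) < 1e-8

    def test_ridge_snp_blup_identity(self, pop):
        """GBLUP breeding values equal ridge-regression marker BLUP with the
        matched variance ratio (independent oracle on the joint system)."""
        panel, pheno, _ = pop
        y = pheno["trait1"].to_numpy()
        X = np.ones((300, 1))
        sA, sE = 0.3, 0.7
        model = GBLUP(var_components=(sA, sE), ridge=0.0).fit(panel.dosages, y, covariates=None)
        Z = model._train_Z_[0]
        scale = model._terms_[0]["scale"]
        lam = sE * scale / sA
        m = Z.shape[1]
        lhs = np.block([
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * np.eye(m)],
        ])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        gebv_ridge = Z @ sol[1:]
        assert np.abs(model.gebv_ - gebv_ridge).max() < 1e-6

    def test_infinite_shrinkage_limit(self, pop):
        panel, pheno, _ = pop
        model = GBLUP(var_components=(1e-12, 1.0)).fit(
            panel.dosages, pheno["trait1"].to_numpy()
        )
        assert np.abs(model.gebv_).max() < 1e-6

    def test_fold_hygiene_masked_phenotypes_never_read(self, pop):
        panel, pheno, _ = pop
        y = pheno["trait1"].to_numpy().copy()
        val = np.arange(40)
        y1 = y.copy(); y1[val] = np.nan
        m1 = GBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, y1)
        y2 = y.copy(); y2[val] = np.nan
        rng = np.random.default_rng(0)
        # the masked entries are NaN either way; permute the underlying data to
        # prove nothing of the validation individuals' records leaks through
        m2 = GBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, y2)
        assert np.array_equal(m1.gebv_, m2.gebv_)
        y3 = y.copy()
        y3[val] = rng.permutation(y3[val])
        y3[val] = np.nan
        m3 = GBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, y3)
        assert np.array_equal(m1.gebv_, m3.gebv_)

    def test_predict_matches_masked_solve(self, pop):
        panel, pheno, _ = pop
        y = pheno["trait1"].to_numpy().copy()
        val = np.arange(25)
        ym = y.copy(); ym[val] = np.nan
        m = GBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, ym)
        assert np.allclose(m.predict(panel.dosages[val]), m.gebv_[val], atol=1e-10)

    def test_oneblup_equals_gblup_on_identical_markers(self, pop):
        panel, pheno, _ = pop
        y = pheno["trait1"].to_numpy()
        a = GBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, y)
        b = OneBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, y)
        assert np.abs(a.gebv_ - b.gebv_).max() < 1e-10


class TestMABLUPAndMultiBLUP:
    def test_mablup_gebv_includes_fixed_snp_term(self, pop):
        panel, pheno, truth = pop
        y = pheno["trait1"].to_numpy()
        top = int(panel.snp_indexer([truth.qtl_ids[0][0]])[0])
        m = MABLUP(snp_fixed_idx=[top], var_components=(0.3, 0.7)).fit(panel.dosages, y)
        assert "snp_fixed" in m.components_
        recomposed = m.components_["grm0"][:, 0] + m.components_["snp_fixed"][:, 0]
        assert np.allclose(m.gebv_, recomposed, atol=1e-12)

    def test_empty_selection_degrades_to_gblup(self, pop):
        panel, pheno, _ = pop
        y = pheno["trait1"].to_numpy()
        plain = GBLUP(var_components=(0.3, 0.7)).fit(panel.dosages, y)
        ma = MABLUP(snp_fixed_idx=None, var_components=(0.3, 0.7)).fit(panel.dosages, y)
        mu = MultiBLUP(group1_idx=None, var_components=(0.3, 0.7)).fit(panel.dosages, y)
        assert np.allclose(plain.gebv_, ma.gebv_, atol=1e-12)
        assert np.allclose(plain.gebv_, mu.gebv_, atol=1e-12)

    def test_multiblup_beats_gblup_when_g1_holds_causal_snps(self):
        """Giving the causal markers their own variance component should raise
        validation accuracy for an oligogenic trait in most replicates."""
        wins = 0
        for seed in range(6):
            cfg = SimConfig(n_individuals=300, n_chromosomes=2, snps_per_chromosome=250,
                            chip_fraction=0.2, seed=200 + seed)
            panel = simulate_genotypes(cfg)
            arch = TraitArchitecture(h2=(0.35, 0.195), rg=0.3, n_large_qtl=(5, 0),
                                     large_qtl_variance_share=(0.85, 0.0))
            pheno, truth = simulate_traits(panel, arch, seed=300 + seed)
            y = pheno["trait1"].to_numpy().copy()
            val = np.arange(0, 300, 5)
            ym = y.copy(); ym[val] = np.nan
            g1 = list(panel.snp_indexer(truth.qtl_ids[0]))
            plain = GBLUP().fit(panel.dosages, ym)
            multi = MultiBLUP(group1_idx=g1).fit(panel.dosages, ym)
            corr = np.corrcoef(truth.tbv[val, 0], plain.gebv_[val])[0, 1]
            corr2 = np.corrcoef(truth.tbv[val, 0], multi.gebv_[val])[0, 1]
            wins += corr2 > corr
        assert wins >= 5


class TestBuildModel:
    def _panels(self, pop):
        panel, _, _ = pop
        chip = make_chip_subset(panel, 0.2)
        return {"chip": chip, "wgs": panel}

    def test_st_mablup_assembly(self, pop):
        panels = self._panels(pop)
        top = panels["chip"].snp_map["id"].iloc[5]
        sels = {("chip", 0): SNPSelection([top], top)}
        plan = build_model("ST-MABLUP", 1, panels, sels, target_trait=0)
        assert isinstance(plan.estimator, MABLUP)
        assert plan.estimator.snp_fixed_idx == [5]
        assert plan.panel.tag == "chip"

    def test_mt_multiblup_union_rule(self, pop):
        panels = self._panels(pop)
        ids = list(panels["wgs"].snp_map["id"])
        sels = {
            ("wgs", 0): SNPSelection([ids[1], ids[2]], ids[1]),
            ("wgs", 1): SNPSelection([ids[2], ids[3]], ids[3]),
        }
        plan = build_model("MT-MultiBLUP", 3, panels, sels)
        g1_ids = set(panels["wgs"].snp_map["id"].iloc[plan.estimator.group1_idx])
        assert g1_ids == {ids[1], ids[2], ids[3]}
        assert plan.is_multitrait

    def test_oneblup_merges_significant_sequence_snps(self, pop):
        panels = self._panels(pop)
        chip_ids = set(panels["chip"].snp_map["id"])
        extra = [s for s in panels["wgs"].snp_map["id"] if s not in chip_ids][:7]
        sels = {("wgs", 0): SNPSelection(extra, extra[0])}
        plan = build_model("ST-OneBLUP", 2, panels, sels, target_trait=0)
        assert plan.panel.n_snps == panels["chip"].n_snps + 7
        assert plan.panel.tag == "merged"

    def test_empty_selection_fallback(self, pop):
        panels = self._panels(pop)
        plan = build_model("ST-MABLUP", 1, panels, {("chip", 0): SNPSelection([], None)})
        assert plan.estimator.snp_fixed_idx is None

    @pytest.mark.parametrize("model,dataset", [
        ("ST-OneBLUP", 1), ("ST-GBLUP", 2), ("BayesA", 3), ("ST-MultiBLUP", 1),
    ])
    def test_illegal_grid_cells_rejected(self, pop, model, dataset):
        with pytest.raises(ValueError):
            build_model(model, dataset, self._panels(pop))


class TestMultiTraitEstimator:
    def test_mt_masked_validation_and_shapes(self, pop):
        panel, pheno, truth = pop
        Y = np.column_stack([pheno["trait1"], pheno["trait2"]]).astype(float)
        val = np.arange(30)
        Y[val] = np.nan
        X = [trait_design(pheno, 0)[0], trait_design(pheno, 1)[0]]
        vc = VarianceComponents(
            genetic=[np.array([[0.3, 0.1], [0.1, 0.2]])],
            residual=np.array([[0.7, 0.1], [0.1, 0.8]]),
            loglik=np.nan, converged=True, n_iter=0, n_traits=2,
        )
        m = GBLUP(n_traits=2, var_components=vc).fit(panel.dosages, Y, covariates=X)
        assert m.gebv_.shape == (300, 2)
        # masked individuals still receive breeding values with genetic signal
        assert np.corrcoef(m.gebv_[val, 0], truth.tbv[val, 0])[0, 1] > 0.2
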