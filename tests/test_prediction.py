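import numpy as np
import pytest

from rootherit.genotypes import TraitTable
from rootherit.prediction import (
    GeneticPredictionModel,
    GeneticPredictionResults,
    GibbsConfig,
    build_design,
    conditional_effect_mean,
    fit_per_region,
    heritability_summary,
)
from rootherit.relatedness import relatedness_matrix
from rootherit.simulate import SimulationConfig, simulate_population

FAST = GibbsConfig(iterations=1_200, burn_in=600, seed=0)


def ridge_closed_form(X, y, mu, sigma_b2, sigma_e2):
    lam = sigma_e2 / sigma_b2
    return np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ (y - mu))


class TestBuildDesign:
    def test_relatedness_rows_are_analyzable_columns_all_genotyped(
        self, study_like_population
    ):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        import pandas as pd

        values = traits.values.copy()
        values.iloc[40:, values.columns.get_loc("t04")] = np.nan  # 40 phenotyped
        partial = TraitTable(
            samples=traits.samples,
            orchard=traits.orchard,
            region=traits.region,
            values=values,
        )
        design, y = build_design(m, partial, "t04", mode="relatedness")
        assert design.shape == (40, panel.n_samples)
        assert len(y) == 40
        # rows are the matching relatedness-matrix rows
        np.testing.assert_array_equal(design.values[0], m.values[0])

    def test_marker_mode_dosage_columns(self, study_like_population):
        _, panel, traits, _ = study_like_population
        design, _ = build_design(panel, traits, "t04", mode="marker")
        expected_cols = sum(
            len(np.unique(np.concatenate([panel.allele1[:, j], panel.allele2[:, j]])))
            for j in range(panel.n_loci)
        )
        assert design.shape == (panel.n_samples, expected_cols)
        # per locus, dosages of a fully genotyped sample sum to 2
        locus0_cols = [k for k, c in enumerate(design.columns) if c.startswith("SSR01:")]
        assert design.values[:, locus0_cols].sum(axis=1) == pytest.approx(2.0)

    def test_too_few_samples_refused(self, study_like_population):
        _, panel, traits, _ = study_like_population
        import pandas as pd

        values = traits.values.copy()
        values.iloc[5:, :] = np.nan
        sparse = TraitTable(
            samples=traits.samples,
            orchard=traits.orchard,
            region=traits.region,
            values=values,
        )
        m = relatedness_matrix(panel)
        with pytest.raises(ValueError, match="need >= 10"):
            build_design(m, sparse, "t04")

    def test_unknown_trait_refused(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        with pytest.raises(ValueError, match="unknown trait"):
            build_design(m, traits, "nope")


class TestGibbsSampler:
    def test_conditional_mean_equals_ridge_solution(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 4))
        y = rng.standard_normal(6)
        got = conditional_effect_mean(X, y, mu=0.3, sigma_b2=0.7, sigma_e2=1.3)
        want = ridge_closed_form(X, y, 0.3, 0.7, 1.3)
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_fixed_variance_chain_matches_ridge(self):
        # with both variances clamped, the long-run posterior mean of beta
        # is the ridge solution (flat-mu model: compare on centered y)
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 5))
        y = X @ rng.standard_normal(5) + 0.5 * rng.standard_normal(10)
        yc = y - y.mean()
        cfg = GibbsConfig(
            iterations=22_000,
            burn_in=2_000,
            seed=3,
            fixed_sigma_b2=0.8,
            fixed_sigma_e2=0.5,
        )
        from rootherit.prediction import DesignMatrix

        design = DesignMatrix(
            values=X, row_samples=[f"S{i}" for i in range(10)], columns=list("abcde"),
            mode="marker",
        )
        res = GeneticPredictionModel(design, y).fit(cfg)
        # oracle: with the flat prior on mu integrated out, the marginal
        # posterior mean of beta is ridge on the doubly centered problem
        Xc = X - X.mean(axis=0)
        want = ridge_closed_form(Xc, yc, 0.0, 0.8, 0.5)
        np.testing.assert_allclose(res.beta_mean, want, atol=0.02)

    def test_chain_reproducible_under_seed(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        model = GeneticPredictionModel.from_tables(m, traits, "t04")
        r1 = model.fit(FAST)
        r2 = model.fit(FAST)
        np.testing.assert_array_equal(r1.h2_draws, r2.h2_draws)
        np.testing.assert_array_equal(r1.gebv.to_numpy(), r2.gebv.to_numpy())

    def test_scale_equivariance(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        model = GeneticPredictionModel.from_tables(m, traits, "t04")
        res = model.fit(FAST)
        scaled_traits = TraitTable(
            samples=traits.samples,
            orchard=traits.orchard,
            region=traits.region,
            values=traits.values * 3.0,
        )
        model3 = GeneticPredictionModel.from_tables(m, scaled_traits, "t04")
        res3 = model3.fit(FAST)
        np.testing.assert_allclose(res3.h2_draws, res.h2_draws, atol=1e-8)
        assert res3.r == pytest.approx(res.r, abs=1e-8)
        np.testing.assert_allclose(
            res3.gebv.to_numpy(), 3.0 * res.gebv.to_numpy(), atol=1e-7
        )

    def test_shrinkage_limit_kills_gebv_and_h2(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        cfg = GibbsConfig(
            iterations=800, burn_in=400, seed=4,
            fixed_sigma_b2=1e-12, fixed_sigma_e2=1.0,
        )
        res = GeneticPredictionModel.from_tables(m, traits, "t04").fit(cfg)
        assert res.h2_mean < 1e-6
        assert np.ptp(res.gebv.to_numpy()) < 1e-4

    def test_h2_draws_bounded_and_variances_nonnegative(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        res = GeneticPredictionModel.from_tables(m, traits, "t04").fit(FAST)
        assert np.all((res.h2_draws >= 0) & (res.h2_draws <= 1))
        assert np.all(res.sigma_a2_draws >= 0)
        assert np.all(res.sigma_e2_draws >= 0)
        assert -1 <= res.r <= 1
        assert res.n_draws == FAST.n_retained

    def test_pure_noise_trait_h2_small(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        res = GeneticPredictionModel.from_tables(m, traits, "t00").fit(FAST)
        assert res.h2_mean < 0.15

    def test_degenerate_phenotype_rejected(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        flat = TraitTable(
            samples=traits.samples,
            orchard=traits.orchard,
            region=traits.region,
            values=traits.values.assign(const=1.0),
        )
        with pytest.raises(ValueError, match="variance"):
            GeneticPredictionModel.from_tables(m, flat, "const")


def _manual_results(h2_draws, sa2, se2, y=None, gebv=None):
    from rootherit.prediction import DesignMatrix

    n = 12
    rng = np.random.default_rng(0)
    X = rng.standard_normal((n, 3))
    y = y if y is not None else rng.standard_normal(n)
    design = DesignMatrix(values=X, row_samples=[f"S{i}" for i in range(n)],
                          columns=list("abc"), mode="marker")
    model = GeneticPredictionModel(design, y)
    T = len(h2_draws)
    raw = {
        "h2": np.asarray(h2_draws, float)[:, None],
        "sigma_a2": np.asarray(sa2, float)[:, None],
        "sigma_e2": np.asarray(se2, float)[:, None],
        "mu": np.zeros((T, 1)),
        "sigma_b2": np.ones((T, 1)),
        "gebv": (gebv if gebv is not None else rng.standard_normal(n))[:, None],
        "beta_mean": np.zeros((3, 1)),
    }
    cfg = GibbsConfig(iterations=2 * T, burn_in=T, seed=0)
    return GeneticPredictionResults(model=model, config=cfg, y_mean=0.0, raw=raw), y


class TestHeritabilitySummary:
    def test_all_zero_additive_variance(self):
        T = 120
        res, _ = _manual_results(np.zeros(T), np.zeros(T), np.ones(T))
        h2, (lo, hi), _ = heritability_summary(res)
        assert h2 == 0.0
        assert (lo, hi) == (0.0, 0.0)

    def test_equal_variances_give_half(self):
        T = 120
        res, _ = _manual_results(np.full(T, 0.5), np.ones(T), np.ones(T))
        h2, _, _ = heritability_summary(res)
        assert h2 == pytest.approx(0.5)

    def test_mean_of_draws(self):
        draws = np.tile([0.2, 0.4], 60)
        res, _ = _manual_results(draws, draws, 1 - draws)
        h2, _, _ = heritability_summary(res)
        assert h2 == pytest.approx(0.3)

    def test_perfect_gebv_gives_r_one(self):
        T = 120
        rng = np.random.default_rng(5)
        y = rng.standard_normal(12)
        res, _ = _manual_results(np.zeros(T), np.zeros(T), np.ones(T), y=y, gebv=y)
        assert res.r == pytest.approx(1.0)

    def test_too_few_draws_rejected(self):
        res, _ = _manual_results(np.zeros(50), np.zeros(50), np.ones(50))
        with pytest.raises(ValueError, match="100"):
            heritability_summary(res)


class TestPerRegion:
    def test_region_counts_partition_global(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        global_res = fit_per_region(m, traits, "t04", None, FAST)
        n_total = 0
        for region in sorted(set(traits.region)):
            res = fit_per_region(m, traits, "t04", region, FAST)
            n_total += res.model.design.shape[0]
        assert n_total == global_res.model.design.shape[0]

    def test_unknown_region_refused(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        with pytest.raises(ValueError, match="not present"):
            fit_per_region(m, traits, "t04", "R9", FAST)

    def test_region_effects_inflate_per_region_h2(self):
        # with strong region shifts, removing the between-region variance
        # from the fit raises h2 relative to the global estimate
        diffs = []
        for seed in range(3):
            cfg = SimulationConfig(
                seed=seed, trait_h2={"t": 0.4}, region_effect_sd=1.0
            )
            panel, traits, _ = simulate_population(cfg)
            m = relatedness_matrix(panel)
            fast = GibbsConfig(iterations=1_200, burn_in=600, seed=seed)
            g = fit_per_region(m, traits, "t", None, fast).h2_mean
            per = [
                fit_per_region(m, traits, "t", r, fast).h2_mean
                for r in sorted(set(traits.region))
            ]
            diffs.append(np.mean(per) - g)
        assert np.mean(diffs) > 0


class TestResultsSurface:
    def test_summary_mentions_key_quantities(self, study_like_population):
        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        res = GeneticPredictionModel.from_tables(m, traits, "t04").fit(FAST)
        text = res.summary()
        assert "h2 (posterior mean)" in text
        assert "credible interval" in text
        assert "model fit r" in text

    def test_trace_and_gebv_export(self, tmp_path, study_like_population):
        import pandas as pd

        _, panel, traits, _ = study_like_population
        m = relatedness_matrix(panel)
        res = GeneticPredictionModel.from_tables(m, traits, "t04").fit(FAST)
        res.to_trace_csv(tmp_path / "trace.csv")
        res.gebv_to_csv(tmp_path / "gebv.csv")
        trace = pd.read_csv(tmp_path / "trace.csv")
        assert list(trace.columns) == ["draw", "mu", "sigma_a2", "sigma_e2", "h2"]
        assert len(trace) == res.n_draws
        gebv = pd.read_csv(tmp_path / "gebv.csv")
        assert len(gebv) == res.model.design.shape[0]
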