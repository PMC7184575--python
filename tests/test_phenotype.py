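"""Derived traits, REML mixed models, LSmeans, heritability, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mkgblup import (
    accumulate_gdd,
    compute_lsmeans,
    derive_traits,
    fit_ndvi_decay,
    heritability,
    membrane_thermostability,
    reml_fit,
    simulate_markers,
    simulate_trial,
    stay_green,
    trait_yield_correlations,
    SimulationConfig,
)
from mkgblup.phenotype import PhenotypeDataError


class TestMembraneThermostability:
    @pytest.mark.parametrize(
        "t1,t2,expected",
        [(20.0, 80.0, 75.0), (50.0, 50.0, 0.0), (0.0, 33.0, 100.0)],
    )
    def test_direct_arithmetic(self, t1, t2, expected):
        assert membrane_thermostability(t1, t2) == pytest.approx(expected)

    def test_nonpositive_t2_rejected(self):
        with pytest.raises(PhenotypeDataError):
            membrane_thermostability(10.0, 0.0)

    def test_t1_above_t2_warns(self):
        with pytest.warns(UserWarning):
            assert membrane_thermostability(90.0, 80.0) < 0

    @given(
        t1=st.floats(0.0, 200.0),
        t2=st.floats(0.1, 200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_100(self, t1, t2):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert membrane_thermostability(t1, t2) <= 100.0


class TestAgdd:
    def test_constant_series(self):
        agdd = accumulate_gdd([10.0] * 10, [20.0] * 10, t_base=0.0)
        assert agdd[-1] == pytest.approx(150.0)

    def test_below_base_clamped_to_zero(self):
        agdd = accumulate_gdd([-10.0] * 5, [-2.0] * 5, t_base=0.0)
        np.testing.assert_array_equal(agdd, np.zeros(5))

    def test_matches_manual_loop(self, rng):
        tmin = rng.uniform(-5, 15, 60)
        tmax = tmin + rng.uniform(0, 15, 60)
        agdd = accumulate_gdd(tmin, tmax, t_base=4.0)
        total = 0.0
        for lo, hi, a in zip(tmin, tmax, agdd):
            total += max(0.0, (lo + hi) / 2.0 - 4.0)
            assert a == pytest.approx(total)

    def test_misaligned_series_rejected(self):
        with pytest.raises(PhenotypeDataError):
            accumulate_gdd([1.0, 2.0], [3.0])


class TestNdviDecay:
    def test_exact_line_recovered(self):
        agdd = np.array([100.0, 250.0, 400.0, 550.0, 700.0, 850.0])
        ndvi = 0.8 - 0.0005 * agdd
        m, b = fit_ndvi_decay(ndvi, agdd)
        assert m == pytest.approx(-0.0005, abs=1e-15)
        assert b == pytest.approx(0.8, abs=1e-12)

    def test_two_point_line(self):
        m, b = fit_ndvi_decay([0.8, 0.6], [100.0, 300.0])
        assert m == pytest.approx(-0.001)
        assert b == pytest.approx(0.9)

    def test_matches_normal_equations(self, rng):
        agdd = np.sort(rng.uniform(0, 1000, 6))
        ndvi = 0.9 - 0.0004 * agdd + rng.normal(0, 0.02, 6)
        m, b = fit_ndvi_decay(ndvi, agdd)
        A = np.column_stack([agdd, np.ones(6)])
        m_o, b_o = np.linalg.solve(A.T @ A, A.T @ ndvi)
        assert m == pytest.approx(m_o, abs=1e-12)
        assert b == pytest.approx(b_o, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(PhenotypeDataError):
            fit_ndvi_decay([0.5], [100.0])
        with pytest.raises(PhenotypeDataError):
            fit_ndvi_decay([0.5, 0.6], [100.0, 100.0])

    def test_slope_scale_equivariance(self, rng):
        agdd = np.sort(rng.uniform(0, 1000, 6))
        ndvi = 0.9 - 0.0004 * agdd + rng.normal(0, 0.01, 6)
        m1, b1 = fit_ndvi_decay(ndvi, agdd)
        m2, b2 = fit_ndvi_decay(ndvi, agdd * 3.0)
        assert m2 == pytest.approx(m1 / 3.0)
        # constant AGDD shift moves only the intercept
        m3, b3 = fit_ndvi_decay(ndvi, agdd + 500.0)
        assert m3 == pytest.approx(m1)
        assert b3 == pytest.approx(b1 - m1 * 500.0)


class TestStayGreen:
    def test_arithmetic(self):
        assert stay_green(-0.0005, 0.8, 1000.0) == pytest.approx(0.3)

    def test_flat_decay(self):
        assert stay_green(0.0, 0.42, 5000.0) == pytest.approx(0.42)

    def test_outside_unit_interval_warns_or_clips(self):
        with pytest.warns(UserWarning):
            assert stay_green(-0.002, 0.5, 1000.0) == pytest.approx(-1.5)
        assert stay_green(-0.002, 0.5, 1000.0, clip=True) == 0.0

    def test_planted_values_recovered_through_derive_traits(self):
        agdd = [100.0, 250.0, 400.0, 550.0, 700.0, 850.0]
        m_true, b_true, pm = -0.0004, 0.85, 1200.0
        row = {"T1": 20.0, "T2": 80.0, "AGDD_PM": pm}
        for t, a in enumerate(agdd, 1):
            row[f"NDVI_{t}"] = b_true + m_true * a
            row[f"AGDD_{t}"] = a
        df = derive_traits(pd.DataFrame([row]))
        assert df.loc[0, "RS"] == pytest.approx(m_true, abs=1e-12)
        assert df.loc[0, "SG"] == pytest.approx(b_true + m_true * pm, abs=1e-10)
        assert df.loc[0, "MT"] == pytest.approx(75.0)


class TestReml:
    def test_balanced_oneway_matches_anova(self, rng):
        # balanced one-way random effects: REML == ANOVA estimators
        g, r = 15, 6
        u = rng.normal(0, 3.0, g)
        y = (u[:, None] + rng.normal(0, 2.0, (g, r))).ravel()
        Z = np.kron(np.eye(g), np.ones((r, 1)))
        fit = reml_fit(y, np.ones((g * r, 1)), [Z])
        ybar = y.reshape(g, r).mean(1)
        msb = r * ybar.var(ddof=1)
        msw = y.reshape(g, r).var(1, ddof=1).mean()
        np.testing.assert_allclose(fit.var_error, msw, rtol=1e-3)
        np.testing.assert_allclose(fit.var_components[0], (msb - msw) / r, rtol=1e-3)

    def test_zero_genetic_variance_gives_near_zero_h2(self, rng):
        # replicated trial with no genotypic signal at all
        rows = []
        for b in range(4):
            for i in range(40):
                rows.append(
                    {"environment": "E1", "block": b + 1, "genotype": f"g{i}",
                     "GY": 50.0 + rng.normal(0, np.sqrt(30.0))}
                )
        est = heritability(pd.DataFrame(rows), "GY", "E1")
        assert est.H2 < 0.1

    def test_equal_variances_give_half(self):
        h2s = []
        for seed in range(6):
            cfg = SimulationConfig(
                n_lines=250, n_markers=200, n_envs=1, n_qtl=100, env_means=[50.0],
                var_genetic=40.0, var_ge=0.0, var_error=40.0, block_sd=2.0,
                seed=seed + 50,
            )
            m = simulate_markers(cfg)
            plots, _ = simulate_trial(m, cfg)
            h2s.append(heritability(plots, "GY", "E1").H2)
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.08)

    def test_h2_in_unit_interval(self, small_dataset):
        _, plots, _ = small_dataset
        for env in plots["environment"].unique():
            h2 = heritability(plots, "GY", env).H2
            assert 0.0 <= h2 <= 1.0

    def test_unreplicated_single_block_rejected(self):
        plots = pd.DataFrame(
            {
                "environment": ["E1"] * 4,
                "block": [1, 1, 1, 1],
                "genotype": ["a", "b", "c", "d"],
                "GY": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(PhenotypeDataError):
            heritability(plots, "GY", "E1")


class TestLsmeans:
    def test_balanced_design_equals_raw_means(self, rng):
        genos = [f"g{i}" for i in range(10)]
        rows = []
        for b in range(3):
            for g in genos:
                rows.append({"environment": "E1", "block": b + 1, "genotype": g,
                             "GY": rng.normal(10, 2)})
        plots = pd.DataFrame(rows)
        lsm = compute_lsmeans(plots, "GY").set_index("genotype")["lsmean"]
        raw = plots.groupby("genotype")["GY"].mean()
        np.testing.assert_allclose(lsm.reindex(raw.index), raw, rtol=1e-6)

    def test_single_block_equals_genotype_values(self):
        plots = pd.DataFrame(
            {
                "environment": "E1",
                "block": 1,
                "genotype": ["a", "b", "c"],
                "GY": [5.0, 7.0, 9.0],
            }
        )
        lsm = compute_lsmeans(plots, "GY").set_index("genotype")["lsmean"]
        np.testing.assert_allclose(lsm[["a", "b", "c"]], [5.0, 7.0, 9.0])

    def test_lsmeans_beat_raw_means_under_block_effects(self):
        # augmented design with strong planted block effects: the mixed
        # model partially recovers them through the replicated checks
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_lines=80, n_markers=200, n_envs=1, n_qtl=60, env_means=[100.0],
                var_genetic=40.0, var_ge=0.0, var_error=10.0, block_sd=15.0,
                n_blocks_per_env=8, seed=seed + 10,
            )
            m = simulate_markers(cfg)
            plots, truth = simulate_trial(m, cfg)
            g = pd.Series(truth.g, index=truth.line_ids)
            lsm = compute_lsmeans(plots, "GY").set_index("genotype")["lsmean"]
            raw = plots.groupby("genotype")["GY"].mean()
            common = sorted(set(lsm.index) & set(g.index))
            rmse_lsm = np.sqrt(np.mean((lsm[common] - lsm[common].mean() - g[common]) ** 2))
            rmse_raw = np.sqrt(np.mean((raw[common] - raw[common].mean() - g[common]) ** 2))
            wins += rmse_lsm < rmse_raw
        assert wins >= 7

    def test_orthogonal_dth_covariate_changes_little(self):
        cfg = SimulationConfig(
            n_lines=100, n_markers=200, n_envs=1, n_qtl=60, env_means=[100.0],
            var_genetic=40.0, var_ge=0.0, var_error=20.0, block_sd=2.0,
            dth_loading=0.0, seed=77,
        )
        m = simulate_markers(cfg)
        plots, truth = simulate_trial(m, cfg)
        plots = __import__("mkgblup").simulate_physiology(plots, truth, cfg)
        lsm0 = compute_lsmeans(plots, "GY", dth_covariate=False).set_index("genotype")["lsmean"]
        lsm1 = compute_lsmeans(plots, "GY", dth_covariate=True).set_index("genotype")["lsmean"]
        assert np.corrcoef(lsm0, lsm1.reindex(lsm0.index))[0, 1] > 0.99


class TestCorrelations:
    def _lsm_frame(self, values: dict) -> pd.DataFrame:
        rows = []
        for trait, vals in values.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"genotype": f"g{i}", "environment": "E1", "trait": trait,
                     "lsmean": v, "se": 0.0, "dth_corrected": False}
                )
        return pd.DataFrame(rows)

    def test_identical_trait_r_one(self, rng):
        gy = rng.normal(size=20)
        lsm = self._lsm_frame({"GY": gy, "copy": gy, "neg": -gy})
        out = trait_yield_correlations(lsm, "E1").set_index("trait")
        assert out.loc["copy", "r"] == pytest.approx(1.0)
        assert out.loc["neg", "r"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self, rng):
        lsm = self._lsm_frame({"GY": rng.normal(size=10), "flat": np.ones(10)})
        out = trait_yield_correlations(lsm, "E1").set_index("trait")
        assert np.isnan(out.loc["flat", "r"])

    def test_planted_correlation_recovered(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 242
            gy = rng.normal(size=n)
            trait = 0.38 * gy + np.sqrt(1 - 0.38**2) * rng.normal(size=n)
            lsm = self._lsm_frame({"GY": gy, "SPAD": trait})
            out = trait_yield_correlations(lsm, "E1").set_index("trait")
            rs.append(out.loc["SPAD", "r"])
        assert np.mean(rs) == pytest.approx(0.38, abs=0.12)

    def test_significance_stars(self, rng):
        gy = np.linspace(0, 1, 50)
        lsm = self._lsm_frame({"GY": gy, "t": gy + rng.normal(0, 0.05, 50)})
        out = trait_yield_correlations(lsm, "E1").set_index("trait")
        assert out.loc["t", "stars"] == "***"


class TestRemlAgainstLme4:
    def test_heritability_components_match_lme4(self, tmp_path):
        """The in-package REML agrees with lme4 on an augmented-design trial."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cfg = SimulationConfig(
            n_lines=120, n_markers=200, n_envs=1, n_qtl=80, env_means=[100.0],
            var_genetic=40.0, var_ge=0.0, var_error=60.0, block_sd=5.0,
            n_blocks_per_env=8, seed=321,
        )
        m = simulate_markers(cfg)
        plots, _ = simulate_trial(m, cfg)
        est = heritability(plots, "GY", "E1")
        csv = tmp_path / "plots.csv"
        plots.to_csv(csv, index=False)
        script = tmp_path / "reml.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f'd <- read.csv("{csv}")\n'
            "d$genotype <- factor(d$genotype); d$block <- factor(d$block)\n"
            "fit <- lmer(GY ~ 1 + (1|genotype) + (1|block), data=d, REML=TRUE)\n"
            "vc <- as.data.frame(VarCorr(fit))\n"
            'cat(vc$vcov[vc$grp=="genotype"], vc$vcov[vc$grp=="Residual"], sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        var_g_r, var_e_r = (float(x) for x in out.stdout.split())
        assert est.var_G == pytest.approx(var_g_r, rel=1e-3, abs=1e-6)
        assert est.var_e == pytest.approx(var_e_r, rel=1e-3)
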