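"""Linearized noise propagation, correlation surfaces, Monte Carlo, Simpson."""

import dataclasses

import numpy as np
import pytest

from ribocomp import (
    ConditionSeries,
    CorrelationSurfaceSpec,
    KineticParams,
    PopulationMoments,
    UndefinedCorrelationError,
    ValidationError,
    correlation_surface,
    covariance_full,
    covariance_reduced,
    default_condition_series,
    monte_carlo_population,
    protein_correlation,
    sensitivity_matrix,
    simpson_scenario,
    steady_state,
)


def random_moments(rng):
    rho = rng.uniform(-0.4, 0.4, 3)  # modest correlations stay PSD
    return PopulationMoments(
        mean_M1T=10 ** rng.uniform(1, 3),
        mean_M2T=10 ** rng.uniform(1, 3),
        mean_RibT=10 ** rng.uniform(3.3, 4.2),
        cv2_M1T=rng.uniform(0, 0.5),
        cv2_M2T=rng.uniform(0, 0.5),
        cv2_RibT=rng.uniform(0, 0.5),
        rho_M1M2=rho[0], rho_M1Rib=rho[1], rho_M2Rib=rho[2],
    )


class TestCovariancePropagation:
    def test_no_input_variation_no_covariance(self, kinetics, base_moments):
        sens = sensitivity_matrix(kinetics, base_moments.mean_cell())
        pop = dataclasses.replace(base_moments, cv2_M1T=0.0, cv2_M2T=0.0, cv2_RibT=0.0)
        assert covariance_full(sens, pop) == 0.0

    def test_full_equals_matrix_product_oracle(self, kinetics, rng):
        for _ in range(30):
            pop = random_moments(rng)
            sens = sensitivity_matrix(kinetics, pop.mean_cell())
            expected = (sens.J @ pop.covariance_matrix() @ sens.J.T)[0, 1]
            assert covariance_full(sens, pop) == pytest.approx(expected, rel=1e-12)

    def test_full_collapses_to_reduced(self, kinetics, rng):
        for _ in range(10):
            pop = dataclasses.replace(
                random_moments(rng), cv2_M2T=0.0,
                rho_M1M2=0.0, rho_M1Rib=0.0, rho_M2Rib=0.0,
            )
            sens = sensitivity_matrix(kinetics, pop.mean_cell())
            assert covariance_full(sens, pop) == pytest.approx(
                covariance_reduced(sens, pop).total, rel=1e-12
            )

    def test_reduced_term_signs(self, kinetics, base_moments):
        sens = sensitivity_matrix(kinetics, base_moments.mean_cell())
        red = covariance_reduced(sens, base_moments)
        assert red.term_rib >= 0.0
        assert red.term_m1 <= 0.0
        assert red.total == pytest.approx(red.term_rib + red.term_m1)

    def test_pure_resource_variation_positive(self, kinetics, base_moments):
        pop = dataclasses.replace(base_moments, cv2_M1T=0.0)
        sens = sensitivity_matrix(kinetics, pop.mean_cell())
        assert covariance_reduced(sens, pop).total > 0.0

    def test_pure_burden_variation_negative(self, kinetics, base_moments):
        pop = dataclasses.replace(base_moments, cv2_RibT=0.0)
        sens = sensitivity_matrix(kinetics, pop.mean_cell())
        assert covariance_reduced(sens, pop).total < 0.0

    def test_non_psd_moments_rejected(self):
        with pytest.raises(ValidationError):
            PopulationMoments(rho_M1M2=0.9, rho_M1Rib=0.9, rho_M2Rib=-0.9)


class TestProteinCorrelation:
    def test_single_resource_source_gives_plus_one(self, kinetics, base_moments):
        pop = dataclasses.replace(base_moments, cv2_M1T=0.0)
        assert protein_correlation(kinetics, pop) == pytest.approx(1.0)

    def test_single_burden_source_gives_minus_one(self, kinetics, base_moments):
        pop = dataclasses.replace(base_moments, cv2_RibT=0.0)
        assert protein_correlation(kinetics, pop) == pytest.approx(-1.0)

    def test_zero_variance_raises(self, kinetics, base_moments):
        pop = dataclasses.replace(base_moments, cv2_M1T=0.0, cv2_RibT=0.0)
        with pytest.raises(UndefinedCorrelationError):
            protein_correlation(kinetics, pop)

    def test_crossover_in_burden_variability(self, kinetics, base_moments):
        """r crosses zero at some cv2_M1T*, strictly decreasing through it."""
        def r_at(c):
            return protein_correlation(
                kinetics, dataclasses.replace(base_moments, cv2_M1T=c)
            )

        lo, hi = 1e-4, 10.0
        assert r_at(lo) > 0 > r_at(hi)
        for _ in range(60):  # bisection oracle for the crossover
            mid = np.sqrt(lo * hi)
            if r_at(mid) > 0:
                lo = mid
            else:
                hi = mid
        cstar = np.sqrt(lo * hi)
        assert abs(r_at(cstar)) < 1e-6
        grid = cstar * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        rs = [r_at(c) for c in grid]
        assert np.all(np.diff(rs) < 0)

    def test_gain_invariance(self, base_moments):
        r1 = protein_correlation(KineticParams(), base_moments)
        r2 = protein_correlation(KineticParams(c1=50.0, c2=0.02), base_moments)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_bounded(self, kinetics, rng):
        for _ in range(30):
            pop = random_moments(rng)
            if pop.cv2_M1T + pop.cv2_RibT == 0:
                continue
            assert abs(protein_correlation(kinetics, pop, "full")) <= 1.0


class TestCorrelationSurface:
    def test_single_point_grid_matches_point_evaluation(self, kinetics, base_moments):
        spec = CorrelationSurfaceSpec(
            x_axis="mean_M1T", x_grid=[300.0],
            y_axis="cv2_M1T", y_grid=[0.1], base=base_moments,
        )
        surf = correlation_surface(kinetics, spec)
        assert len(surf) == 1
        assert surf["r"].iloc[0] == pytest.approx(
            protein_correlation(kinetics, base_moments)
        )

    def test_r_rises_with_mean_burden(self, kinetics, base_moments):
        spec = CorrelationSurfaceSpec(
            x_axis="mean_M1T", x_grid=np.geomspace(120, 1000, 8),
            y_axis="cv2_M1T", y_grid=[0.05, 0.1], base=base_moments,
        )
        surf = correlation_surface(kinetics, spec)
        for _, block in surf.groupby("cv2_M1T"):
            assert np.all(np.diff(block["r"].to_numpy()) >= 0)

    def test_r_falls_with_mean_resource(self, kinetics, base_moments):
        spec = CorrelationSurfaceSpec(
            x_axis="mean_RibT", x_grid=np.linspace(5000, 10_000, 6),
            y_axis="cv2_RibT", y_grid=[0.1], base=base_moments,
        )
        surf = correlation_surface(kinetics, spec)
        assert np.all(np.diff(surf["r"].to_numpy()) <= 0)

    def test_variability_monotonicity(self, kinetics, base_moments):
        rs_rib = [
            protein_correlation(
                kinetics, dataclasses.replace(base_moments, cv2_RibT=c)
            )
            for c in (0.02, 0.05, 0.1, 0.2, 0.4)
        ]
        assert np.all(np.diff(rs_rib) > 0)
        rs_m1 = [
            protein_correlation(
                kinetics, dataclasses.replace(base_moments, cv2_M1T=c)
            )
            for c in (0.02, 0.05, 0.1, 0.2, 0.4)
        ]
        assert np.all(np.diff(rs_m1) < 0)

    def test_bad_axis_rejected(self, base_moments):
        with pytest.raises(ValidationError):
            CorrelationSurfaceSpec(
                x_axis="mean_M1T", x_grid=[1, 2],
                y_axis="mean_M1T", y_grid=[1, 2], base=base_moments,
            )


class TestMonteCarlo:
    def test_degenerate_population_is_deterministic(self, kinetics, base_moments):
        pop = dataclasses.replace(base_moments, cv2_M1T=0.0, cv2_RibT=0.0)
        df = monte_carlo_population(kinetics, pop, 50, seed=3)
        ss = steady_state(kinetics, pop.mean_cell())
        assert np.allclose(df["P1"], ss.P1, rtol=1e-9)
        assert np.allclose(df["P2"], ss.P2, rtol=1e-9)

    def test_input_moment_recovery(self, kinetics, base_moments):
        n = 40_000
        df = monte_carlo_population(kinetics, base_moments, n, seed=5)
        for col, mean, cv2 in (
            ("M1T", base_moments.mean_M1T, base_moments.cv2_M1T),
            ("RibT", base_moments.mean_RibT, base_moments.cv2_RibT),
        ):
            x = df[col].to_numpy()
            se_mean = x.std(ddof=1) / np.sqrt(n)
            assert abs(x.mean() - mean) < 3 * se_mean
            est_cv2 = x.var(ddof=1) / x.mean() ** 2
            # rough SE of the CV^2 estimate via chunked replicates
            chunks = x.reshape(20, -1)
            cv2s = chunks.var(axis=1, ddof=1) / chunks.mean(axis=1) ** 2
            se_cv2 = cv2s.std(ddof=1) / np.sqrt(20)
            assert abs(est_cv2 - cv2) < 4 * se_cv2

    def test_target_cross_correlation_realized(self, kinetics, base_moments):
        pop = dataclasses.replace(base_moments, cv2_M2T=0.1, rho_M1M2=0.3)
        df = monte_carlo_population(kinetics, pop, 60_000, seed=6)
        r = np.corrcoef(df["M1T"], df["M2T"])[0, 1]
        assert r == pytest.approx(0.3, abs=0.02)

    def test_small_noise_covariance_matches_linearization(self, kinetics):
        pop = PopulationMoments(cv2_M1T=0.0025, cv2_M2T=0.0, cv2_RibT=0.0025)
        df = monte_carlo_population(kinetics, pop, 50_000, seed=7)
        sens = sensitivity_matrix(kinetics, pop.mean_cell())
        predicted = covariance_full(sens, pop)
        p = df[["P1", "P2"]].to_numpy()
        mc = np.cov(p.T)[0, 1]
        boot_rng = np.random.default_rng(8)
        boots = [
            np.cov(p[boot_rng.integers(0, len(p), len(p))].T)[0, 1]
            for _ in range(200)
        ]
        assert abs(mc - predicted) < 3 * np.std(boots, ddof=1)

    def test_seed_determinism(self, kinetics, base_moments):
        a = monte_carlo_population(kinetics, base_moments, 100, seed=11)
        b = monte_carlo_population(kinetics, base_moments, 100, seed=11)
        assert a.equals(b)


class TestSimpsonScenario:
    def test_single_condition_merged_equals_within(self, kinetics, base_moments):
        series = ConditionSeries((("only", base_moments),))
        res = simpson_scenario(kinetics, series, 500, seed=2)
        assert res.merged_r == pytest.approx(res.within_r[0])

    def test_sign_reversal_on_default_series(self, kinetics):
        res = simpson_scenario(kinetics, default_condition_series(), 3000, seed=2)
        assert all(r > 0 for r in res.within_r)
        assert res.merged_r < 0

    def test_pooled_covariance_identity(self, kinetics):
        """Pooled Cov = mean within-Cov + Cov of condition means (equal n)."""
        res = simpson_scenario(kinetics, default_condition_series(3), 400, seed=4)
        t = res.table
        groups = [g for _, g in t.groupby("condition", sort=False)]
        within = np.mean([np.cov(g["P1"], g["P2"], ddof=0)[0, 1] for g in groups])
        means = np.array([[g["P1"].mean(), g["P2"].mean()] for g in groups])
        between = np.cov(means.T, ddof=0)[0, 1]
        pooled = np.cov(t["P1"], t["P2"], ddof=0)[0, 1]
        assert pooled == pytest.approx(within + between, rel=1e-9)

    def test_two_condition_mixture_oracle(self, kinetics, base_moments):
        """A between-condition mean shift with opposite output trends drives
        the pooled covariance negative even when within-covariances are
        positive — closed-form mixture-covariance oracle."""
        low = dataclasses.replace(base_moments, mean_M1T=50.0)
        high = dataclasses.replace(base_moments, mean_M1T=1000.0)
        series = ConditionSeries((("low", low), ("high", high)))
        res = simpson_scenario(kinetics, series, 4000, seed=9)
        t = res.table
        groups = [g for _, g in t.groupby("condition", sort=False)]
        within_covs = [np.cov(g["P1"], g["P2"], ddof=0)[0, 1] for g in groups]
        means = np.array([[g["P1"].mean(), g["P2"].mean()] for g in groups])
        between = np.cov(means.T, ddof=0)[0, 1]
        assert all(c > 0 for c in within_covs)
        assert between < 0
        assert between + np.mean(within_covs) < 0
        assert all(r > 0 for r in res.within_r)
        assert res.merged_r < 0

    def test_adding_conditions_preserves_earlier_streams(self, kinetics):
        s3 = default_condition_series(3, m1t_range=(30, 1000))
        # same first three labels/moments, one extra condition appended
        extra = ConditionSeries(
            s3.conditions + (("extra", s3.conditions[0][1]),)
        )
        a = simpson_scenario(kinetics, s3, 200, seed=5)
        b = simpson_scenario(kinetics, extra, 200, seed=5)
        assert a.within_r == b.within_r[:3]
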