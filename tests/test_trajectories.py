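"""Spline bases, reference Z-scoring, the Bayesian trajectory model and
divergence-point logic."""

import numpy as np
import pandas as pd
import pytest

import gmnet as g
from gmnet.trajectories import (
    DivergenceEstimate,
    _design,
    _make_log_prob,
    difference_curve,
    divergence_point,
    fit_trajectory,
    rcs_basis,
    zscore_to_reference,
)


class TestZscoreToReference:
    def test_reference_subset_mean_zero_sd_one(self, cohort):
        table, _ = cohort
        out, ref = zscore_to_reference(table, ["small_world"])
        vals = out.loc[ref, "small_world"]
        assert vals.mean() == pytest.approx(0.0, abs=1e-10)
        assert vals.std(ddof=1) == pytest.approx(1.0)

    def test_value_at_reference_mean_maps_to_zero(self, cohort):
        table, _ = cohort
        ref = (table["mutation_status"] == "non-carrier") & (table["age"] < 40)
        m = table.loc[ref, "small_world"].mean()
        probe = table.copy()
        probe.loc[probe.index[0], "small_world"] = m
        out, _ = zscore_to_reference(probe, ["small_world"])
        assert out["small_world"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_two_pass_oracle(self, cohort):
        table, _ = cohort
        out, ref = zscore_to_reference(table, ["nfl"])
        m = table.loc[ref, "nfl"].mean()
        s = table.loc[ref, "nfl"].std(ddof=1)
        np.testing.assert_allclose(
            out["nfl"].to_numpy(), ((table["nfl"] - m) / s).to_numpy()
        )

    def test_empty_reference_rejected(self, cohort):
        table, _ = cohort
        old = table[table["age"] >= 40]
        with pytest.raises(ValueError, match="reference"):
            zscore_to_reference(old, ["nfl"])


def _oracle_rcs(x, t):
    """Independent closed-form restricted cubic spline (3 knots)."""
    def p3(v):
        return np.maximum(v, 0.0) ** 3
    t1, t2, t3 = t
    col2 = (
        p3(x - t1)
        - p3(x - t2) * (t3 - t1) / (t3 - t2)
        + p3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.stack([x, col2], axis=1)


class TestRcsBasis:
    def test_three_knots_two_columns(self):
        rng = np.random.default_rng(0)
        basis = rcs_basis(rng.uniform(-25, 10, 200))
        assert basis.n_columns == 2
        assert basis.evaluate(np.zeros(5)).shape == (5, 2)

    def test_linear_outside_boundary_knots(self):
        basis = rcs_basis(np.linspace(-20, 8, 100))
        for grid in (np.linspace(-80, -40, 50), np.linspace(30, 70, 50)):
            b = basis.evaluate(grid)
            second = np.diff(b, n=2, axis=0)
            np.testing.assert_allclose(second, 0.0, atol=1e-8)

    def test_matches_truncated_power_oracle(self):
        rng = np.random.default_rng(1)
        eyo = rng.uniform(-25, 10, 300)
        basis = rcs_basis(eyo)
        x = rng.uniform(-30, 15, 50)
        np.testing.assert_allclose(
            basis.evaluate(x), _oracle_rcs(x, basis.knots), atol=1e-12
        )

    def test_knots_at_requested_quantiles(self):
        eyo = np.linspace(-25, 10, 1001)
        basis = rcs_basis(eyo, quantiles=(0.1, 0.5, 0.9))
        np.testing.assert_allclose(basis.knots, np.quantile(eyo, [0.1, 0.5, 0.9]))

    def test_coincident_knots_rejected(self):
        with pytest.raises(ValueError, match="knots"):
            g.RcsBasis(knots=np.array([0.0, 0.0, 1.0]))

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rcs_basis(np.repeat([1.0, 2.0], 20))


def _prepared_trajectory_table(cohort):
    table, truth = cohort
    table = table.copy()
    for a in g.LOG_ANALYTES:
        table[a] = np.log(table[a])
    out, _ = zscore_to_reference(table, ["nfl", "small_world", "total_gm_volume"])
    return out, truth


@pytest.fixture(scope="module")
def nfl_fit(cohort):
    table, truth = _prepared_trajectory_table(cohort)
    settings = g.McmcSettings(chains=32, iterations=6000, thinning=10, seed=5)
    fit = fit_trajectory(table, "nfl", settings=settings)
    return fit, truth


class TestFitTrajectory:
    def test_draw_bookkeeping_invariant(self, nfl_fit):
        fit, _ = nfl_fit
        expected = fit.chains * (fit.iterations - fit.warmup) // fit.thinning
        assert fit.n_draws == expected
        assert set(fit.rhat) == set(fit.param_names)

    def test_determinism_same_seed(self, cohort):
        table, _ = _prepared_trajectory_table(cohort)
        settings = g.McmcSettings(chains=8, iterations=400, thinning=4, seed=9)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            f1 = fit_trajectory(table, "nfl", settings=settings)
            f2 = fit_trajectory(table, "nfl", settings=settings)
        assert np.array_equal(f1.draws, f2.draws)

    def test_log_prob_invariant_to_family_relabeling(self, cohort):
        table, _ = _prepared_trajectory_table(cohort)
        basis = rcs_basis(table["eyo"].to_numpy())
        x, y, fam, _ = _design(table, "nfl", basis, ("sex",))
        lp = _make_log_prob(x, y, fam)
        relabeled = table.copy()
        mapping = {f: f"Z{i:03d}" for i, f in
                   enumerate(reversed(sorted(table["family_id"].unique())))}
        relabeled["family_id"] = relabeled["family_id"].map(mapping)
        x2, y2, fam2, _ = _design(relabeled, "nfl", basis, ("sex",))
        lp2 = _make_log_prob(x2, y2, fam2)
        theta = np.concatenate([np.full(x.shape[1], 0.1), [0.0, -1.0]])
        assert lp(theta)[0] == pytest.approx(lp2(theta)[0], rel=1e-12)

    def test_sex_covariate_required(self, cohort):
        table, _ = _prepared_trajectory_table(cohort)
        with pytest.raises(ValueError, match="sex"):
            fit_trajectory(table, "nfl", covariates=())

    def test_mutation_terms_detect_simulated_departure(self, nfl_fit):
        # the generating model has a real carrier departure after EYO -7, so
        # at least one mutation-related posterior interval must exclude 0
        fit, _ = nfl_fit
        summary = fit.posterior_summary()
        mut_rows = summary.loc[["mutation", "eyo_1:mutation", "eyo_2:mutation"]]
        excludes = (mut_rows["q2.5"] > 0) | (mut_rows["q97.5"] < 0)
        assert excludes.any()


class TestParameterRecovery:
    def test_fixed_effects_recovered_from_known_model(self):
        # simulate directly from the fitted model family with known betas
        rng = np.random.default_rng(21)
        n, n_fam = 350, 40
        eyo = rng.uniform(-25, 10, n)
        basis = rcs_basis(eyo)
        b = basis.evaluate(eyo)
        carrier = rng.random(n) < 0.6
        sex = rng.random(n) < 0.45
        fam = rng.integers(0, n_fam, n)
        true = {
            "intercept": 0.2, "eyo_1": 0.01, "eyo_2": -0.02, "mutation": 1.0,
            "eyo_1:mutation": 0.08, "eyo_2:mutation": 0.15, "sex": -0.3,
            "sigma": 0.8, "tau": 0.5,
        }
        u = rng.normal(0, true["tau"], n_fam)
        y = (
            true["intercept"] + true["eyo_1"] * b[:, 0] + true["eyo_2"] * b[:, 1]
            + carrier * (true["mutation"] + true["eyo_1:mutation"] * b[:, 0]
                         + true["eyo_2:mutation"] * b[:, 1])
            + true["sex"] * sex + u[fam] + rng.normal(0, true["sigma"], n)
        )
        table = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "family_id": [f"F{f:03d}" for f in fam],
            "mutation_status": np.where(carrier, "carrier", "non-carrier"),
            "sex": np.where(sex, "M", "F"),
            "eyo": eyo, "nfl": y,
        })
        fit = fit_trajectory(
            table, "nfl", basis=basis,
            settings=g.McmcSettings(chains=32, iterations=6000, thinning=10, seed=2),
        )
        summary = fit.posterior_summary()
        covered = sum(
            summary.loc[p, "q2.5"] <= true[p] <= summary.loc[p, "q97.5"]
            for p in true
        )
        assert covered >= 8  # all 9 in expectation; allow one miss
        # variance components land in the right region
        assert summary.loc["tau", "median"] == pytest.approx(0.5, abs=0.25)
        assert summary.loc["sigma", "median"] == pytest.approx(0.8, abs=0.15)


class TestDifferenceCurve:
    def test_matches_draw_by_draw_oracle(self, nfl_fit):
        fit, _ = nfl_fit
        grid = np.array([-20.0, -10.0, 0.0, 5.0])
        est = difference_curve(fit, grid=grid)
        b = fit.basis.evaluate(grid)
        names = fit.param_names
        for gi in range(len(grid)):
            draws = np.array([
                d[names.index("mutation")]
                + d[names.index("eyo_1:mutation")] * b[gi, 0]
                + d[names.index("eyo_2:mutation")] * b[gi, 1]
                for d in fit.draws
            ])
            assert est.mean[gi] == pytest.approx(draws.mean())
            lo, hi = est.bands[0.99]
            assert lo[gi] == pytest.approx(np.quantile(draws, 0.005))
            assert hi[gi] == pytest.approx(np.quantile(draws, 0.995))

    def test_zero_mutation_draws_give_zero_difference(self, nfl_fit):
        fit, _ = nfl_fit
        import copy
        silenced = copy.copy(fit)
        silenced.draws = fit.draws.copy()
        for p in ("mutation", "eyo_1:mutation", "eyo_2:mutation"):
            silenced.draws[:, fit.param_names.index(p)] = 0.0
        est = difference_curve(silenced)
        np.testing.assert_allclose(est.mean, 0.0)
        for lo, hi in est.bands.values():
            np.testing.assert_allclose(lo, 0.0)
            np.testing.assert_allclose(hi, 0.0)

    def test_bands_nested_pointwise(self, nfl_fit):
        fit, _ = nfl_fit
        est = difference_curve(fit)
        lo95, hi95 = est.bands[0.95]
        lo99, hi99 = est.bands[0.99]
        lo995, hi995 = est.bands[0.995]
        assert (lo995 <= lo99).all() and (lo99 <= lo95).all()
        assert (hi995 >= hi99).all() and (hi99 >= hi95).all()

    def test_empty_grid_rejected(self, nfl_fit):
        fit, _ = nfl_fit
        with pytest.raises(ValueError, match="grid"):
            difference_curve(fit, grid=np.array([]))

    def test_divergence_levels_monotone(self, nfl_fit):
        fit, truth = nfl_fit
        est = difference_curve(fit)
        d95, d99, d995 = (est.divergence[l] for l in (0.95, 0.99, 0.995))
        present = [d for d in (d95, d99, d995) if d is not None]
        assert len(present) >= 1
        if d95 is not None and d99 is not None:
            assert d99 >= d95
        if d99 is not None and d995 is not None:
            assert d995 >= d99


def _manual_estimate(grid, lo, hi):
    return DivergenceEstimate(
        outcome="x", grid=np.asarray(grid, float), mean=(np.asarray(lo) + hi) / 2,
        bands={0.99: (np.asarray(lo, float), np.asarray(hi, float))},
    )


class TestDivergencePoint:
    def test_sustained_rule_skips_transient_exclusion(self):
        # excluded at index 1 only, then again from index 3 onward
        lo = np.array([-1.0, 0.5, -1.0, 0.5, 0.5])
        hi = np.array([1.0, 2.0, 1.0, 2.0, 2.0])
        est = _manual_estimate([0, 1, 2, 3, 4], lo, hi)
        assert divergence_point(est, 0.99) == 3.0
        assert divergence_point(est, 0.99, sustained=False) == 1.0

    def test_no_exclusion_returns_none(self):
        est = _manual_estimate([0, 1, 2], [-1, -1, -1], [1, 1, 1])
        assert divergence_point(est, 0.99) is None

    def test_exclusion_not_sustained_to_end_returns_none(self):
        est = _manual_estimate([0, 1, 2], [0.5, 0.5, -1.0], [2, 2, 1])
        assert divergence_point(est, 0.99) is None

    def test_negative_departures_count_too(self):
        est = _manual_estimate([0, 1], [-2.0, -2.0], [-0.5, -0.5])
        assert divergence_point(est, 0.99) == 0.0

    def test_missing_level_rejected(self):
        est = _manual_estimate([0], [1.0], [2.0])
        with pytest.raises(ValueError, match="level"):
            divergence_point(est, 0.5)
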