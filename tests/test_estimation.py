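"""Estimator contracts: OLS/LPM, probit, inverse Mills ratio,
random-intercept ML, the stacked-IMR two-step, first differences and the
exclusion-restriction check."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from gpmobility.estimation import (
    CollinearityError,
    ModelSpec,
    SeparationError,
    exclusion_restriction_check,
    first_difference_fit,
    heckman_selection_fit,
    inverse_mills,
    ols_fit,
    probit_fit,
    random_intercept_fit,
)
from gpmobility.synthetic_panel import (
    simulate_fd_benchmark,
    simulate_random_intercept_benchmark,
    simulate_selection_benchmark,
)


def with_ids(df, practice="practice_id", doctor="doctor_id"):
    out = df.copy()
    if doctor not in out:
        out[doctor] = np.arange(len(out))
    if practice not in out:
        out[practice] = 0
    if "year" not in out:
        out["year"] = 2004
    return out


class TestOLS:
    def test_exact_fit_without_noise(self):
        x = np.arange(20.0)
        df = with_ids(pd.DataFrame({"y": 2.0 + 3.0 * x, "x": x}))
        res = ols_fit(ModelSpec("y", ["x"]), df)
        assert res.params["const"] == pytest.approx(2.0, abs=1e-10)
        assert res.params["x"] == pytest.approx(3.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        beta = np.array([0.5, -1.0, 2.0, 0.3])
        y = X @ beta + rng.standard_normal(n)
        df = with_ids(pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2], "x3": X[:, 3]}))
        res = ols_fit(ModelSpec("y", ["x1", "x2", "x3"]), df)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.params.to_numpy(), oracle, atol=1e-8)

    def test_duplicated_column_raises_naming_it(self, rng):
        x = rng.standard_normal(50)
        df = with_ids(pd.DataFrame({"y": rng.standard_normal(50), "x": x, "x_dup": 2 * x}))
        with pytest.raises(CollinearityError, match="x"):
            ols_fit(ModelSpec("y", ["x", "x_dup"]), df)

    def test_lpm_reports_out_of_range_share_unclipped(self, rng):
        x = np.linspace(-3, 3, 400)
        y = (x + 0.3 * rng.standard_normal(400) > 0).astype(float)
        df = with_ids(pd.DataFrame({"y": y, "x": x}))
        res = ols_fit(ModelSpec("y", ["x"]), df)
        assert 0.0 < res.extra["lpm_out_of_range_share"] < 1.0

    def test_row_order_invariance(self, rng):
        df = with_ids(
            pd.DataFrame({"y": rng.standard_normal(100), "x": rng.standard_normal(100)})
        )
        a = ols_fit(ModelSpec("y", ["x"]), df)
        b = ols_fit(ModelSpec("y", ["x"]), df.sample(frac=1.0, random_state=1))
        pd.testing.assert_series_equal(a.params, b.params, atol=1e-12, rtol=0)

    def test_affine_rescaling_rescales_coefficient(self, rng):
        df = with_ids(
            pd.DataFrame({"y": rng.standard_normal(100), "x": rng.standard_normal(100)})
        )
        a = ols_fit(ModelSpec("y", ["x"]), df)
        df2 = df.assign(x=10.0 * df["x"])
        b = ols_fit(ModelSpec("y", ["x"]), df2)
        assert b.params["x"] == pytest.approx(a.params["x"] / 10.0)
        assert b.bse["x"] == pytest.approx(a.bse["x"] / 10.0)


class TestProbit:
    def test_symmetric_fixture_zero_intercept(self, rng):
        x = rng.standard_normal(4000)
        y = (x + rng.standard_normal(4000) > 0).astype(float)
        df = with_ids(pd.DataFrame({"y": y, "x": x}))
        res = probit_fit(ModelSpec("y", ["x"]), df)
        assert abs(res.params["const"]) < 3 * res.bse["const"]

    def test_parameter_recovery(self):
        rng = np.random.default_rng(31)
        n, b0, b1 = 5000, -0.3, 0.8
        x = rng.standard_normal(n)
        y = (b0 + b1 * x + rng.standard_normal(n) > 0).astype(float)
        df = with_ids(pd.DataFrame({"y": y, "x": x}))
        res = probit_fit(ModelSpec("y", ["x"]), df)
        assert abs(res.params["x"] - b1) < 3 * res.bse["x"]
        assert abs(res.params["const"] - b0) < 3 * res.bse["const"]

    def test_one_class_outcome_rejected(self, rng):
        df = with_ids(pd.DataFrame({"y": np.ones(60), "x": rng.standard_normal(60)}))
        with pytest.raises(ValueError, match="single value"):
            probit_fit(ModelSpec("y", ["x"]), df)

    def test_perfect_separation_surfaced(self, rng):
        x = rng.standard_normal(200)
        df = with_ids(pd.DataFrame({"y": (x > 0).astype(float), "x": x}))
        with pytest.raises(SeparationError):
            probit_fit(ModelSpec("y", ["x"]), df)

    def test_affine_rescaling(self, rng):
        x = rng.standard_normal(2000)
        y = (0.5 * x + rng.standard_normal(2000) > 0).astype(float)
        df = with_ids(pd.DataFrame({"y": y, "x": x}))
        a = probit_fit(ModelSpec("y", ["x"]), df)
        b = probit_fit(ModelSpec("y", ["x"]), df.assign(x=4.0 * df["x"]))
        assert b.params["x"] == pytest.approx(a.params["x"] / 4.0, rel=1e-6)


class TestInverseMills:
    # 30-digit reference values computed with sympy's erfc
    SYMPY_REFERENCE = {
        -40.0: 40.0249688472072637,
        -30.0: 30.0332596674336770,
        -8.0: 8.12136811223611268,
        -3.0: 3.28309865493043651,
        -1.0: 1.52513527616098121,
        -0.5: 1.14107777036806448,
        0.0: 0.797884560802865356,
        0.5: 0.509160433837033486,
        1.0: 0.287599970939178361,
        3.0: 0.00443783904212566379,
    }

    def test_zero_index_closed_form(self):
        assert abs(inverse_mills(0.0) - np.sqrt(2.0 / np.pi)) <= 1e-10

    @pytest.mark.parametrize("x, expected", sorted(SYMPY_REFERENCE.items()))
    def test_high_precision_reference(self, x, expected):
        assert inverse_mills(x) == pytest.approx(expected, abs=1e-10, rel=1e-12)

    def test_deep_tail(self):
        assert 0.0 < inverse_mills(8.0) < 1e-10

    def test_strictly_decreasing_and_positive(self):
        grid = np.linspace(-60.0, 10.0, 2000)
        vals = inverse_mills(grid)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) < 0)


def _profile_gls_oracle(y, X, groups):
    """Independent ML fit of the random-intercept model: profile the
    likelihood over the variance ratio theta = sigma_u^2/sigma_e^2 with
    closed-form GLS at each theta."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n = len(y)
    Z = pd.get_dummies(pd.Series(groups)).to_numpy(dtype=float)

    def neg_profile_ll(theta):
        V = np.eye(n) + theta * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = (r @ Vi @ r) / n
        sign, logdet = np.linalg.slogdet(V)
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    opt = minimize_scalar(neg_profile_ll, bounds=(1e-8, 50.0), method="bounded",
                          options={"xatol": 1e-10})
    theta = opt.x
    V = np.eye(n) + theta * Z @ Z.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = (r @ Vi @ r) / n
    return beta, theta * s2, s2, -neg_profile_ll(theta)


class TestRandomIntercept:
    def test_matches_profile_likelihood_oracle(self):
        df = simulate_random_intercept_benchmark(n_groups=15, group_size=6, seed=4)
        df = with_ids(df)
        df["practice_id"] = df["group"]
        res = random_intercept_fit(ModelSpec("y", ["x"], group_level="practice"), df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta, su2, se2, ll = _profile_gls_oracle(df["y"], X, df["group"])
        np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-5)
        assert res.sigma_u2 == pytest.approx(su2, rel=1e-4)
        assert res.sigma_e2 == pytest.approx(se2, rel=1e-4)
        assert res.loglike == pytest.approx(ll, abs=1e-5)

    def test_degenerate_variance_matches_ols(self):
        df = simulate_random_intercept_benchmark(
            n_groups=40, group_size=6, sigma_u=0.0, seed=8
        )
        df = with_ids(df)
        df["practice_id"] = df["group"]
        ri = random_intercept_fit(ModelSpec("y", ["x"], group_level="practice"), df)
        ols = ols_fit(ModelSpec("y", ["x"]), df)
        assert ri.params["x"] == pytest.approx(ols.params["x"], abs=1e-6)
        assert ri.sigma_u2 == pytest.approx(0.0, abs=1e-2)

    def test_loglik_nests_pooled_model(self):
        df = with_ids(simulate_random_intercept_benchmark(n_groups=30, group_size=5, seed=9))
        df["practice_id"] = df["group"]
        ri = random_intercept_fit(ModelSpec("y", ["x"], group_level="practice"), df)
        ols = ols_fit(ModelSpec("y", ["x"]), df)
        assert ri.loglike >= ols.loglike - 1e-8

    def test_row_order_invariance(self):
        df = with_ids(simulate_random_intercept_benchmark(n_groups=20, group_size=5, seed=3))
        df["practice_id"] = df["group"]
        spec = ModelSpec("y", ["x"], group_level="practice")
        a = random_intercept_fit(spec, df)
        b = random_intercept_fit(spec, df.sample(frac=1.0, random_state=0))
        pd.testing.assert_series_equal(a.params, b.params, atol=1e-8, rtol=1e-6)


class TestHeckman:
    STAY = ModelSpec("stay", ["x", "years_to_retirement"])
    OUT = ModelSpec("y", ["x"])

    def test_imr_series_invariants(self):
        panel = simulate_selection_benchmark(rho=0.5, seed=6)
        res = heckman_selection_fit(self.STAY, self.OUT, panel)
        assert len(res.imr) == int(panel["stay"].sum())
        assert (res.imr > 0).all()
        assert set(res.first_stages) == {2003, 2004, 2005}

    def test_correction_moves_estimate_towards_truth(self):
        panel = simulate_selection_benchmark(rho=0.5, n_per_year=2000, seed=10)
        res = heckman_selection_fit(self.STAY, self.OUT, panel)
        naive = ols_fit(self.OUT, panel.dropna(subset=["y"]))
        truth = 1.0
        assert abs(res.second_stage.params["x"] - truth) < abs(naive.params["x"] - truth)

    def test_exclusion_variable_placement_enforced(self):
        panel = simulate_selection_benchmark(seed=0)
        with pytest.raises(ValueError, match="exclusion"):
            heckman_selection_fit(ModelSpec("stay", ["x"]), self.OUT, panel)
        with pytest.raises(ValueError, match="must not"):
            heckman_selection_fit(
                self.STAY, ModelSpec("y", ["x", "years_to_retirement"]), panel
            )

    def test_single_class_year_skipped_with_warning(self):
        panel = simulate_selection_benchmark(seed=1)
        panel.loc[panel["year"] == 2003, "stay"] = 1
        with pytest.warns(UserWarning, match="2003"):
            res = heckman_selection_fit(self.STAY, self.OUT, panel)
        assert res.skipped_years == [2003]
        assert 2003 not in res.first_stages


class TestFirstDifference:
    def test_time_invariant_covariates_dropped(self):
        panel = simulate_fd_benchmark(seed=12)
        with pytest.warns(UserWarning, match="female"):
            res = first_difference_fit(ModelSpec("y", ["x", "female"]), panel)
        assert "d_female" not in res.params.index
        assert "female" in res.extra["dropped"]

    def test_equals_within_estimator_on_two_periods(self):
        """Algebraic identity: with T = 2 the FD slope equals the within
        (doctor-demeaned) estimator slope."""
        panel = simulate_fd_benchmark(seed=13)
        fd = first_difference_fit(ModelSpec("y", ["x"]), panel)
        demeaned = panel.copy()
        demeaned["period"] = (demeaned["year"] == 2006).astype(float)
        for c in ("y", "x", "period"):
            demeaned[c] = demeaned[c] - demeaned.groupby("doctor_id")[c].transform("mean")
        # the FD constant absorbs the common period effect, so the within
        # regression needs the demeaned period indicator alongside x
        within = np.linalg.lstsq(
            demeaned[["x", "period"]].to_numpy(), demeaned["y"].to_numpy(), rcond=None
        )[0][0]
        assert fd.params["d_x"] == pytest.approx(within, abs=1e-10)

    def test_removes_fixed_effect_bias(self):
        panel = with_ids(simulate_fd_benchmark(n=4000, beta=1.0, seed=14))
        pooled = ols_fit(ModelSpec("y", ["x"]), panel)
        fd = first_difference_fit(ModelSpec("y", ["x"]), panel)
        assert abs(pooled.params["x"] - 1.0) > 5 * pooled.bse["x"]  # clearly biased
        assert abs(fd.params["d_x"] - 1.0) < 3 * fd.bse["d_x"]

    def test_shock_enters_in_levels(self):
        panel = simulate_fd_benchmark(seed=15)
        rng = np.random.default_rng(0)
        shock = pd.Series(rng.normal(size=panel["doctor_id"].nunique()),
                          index=np.arange(panel["doctor_id"].nunique()))
        panel["price_shock"] = shock.reindex(panel["doctor_id"]).to_numpy()
        res = first_difference_fit(ModelSpec("y", ["x"]), panel, shock_var="price_shock")
        assert "price_shock" in res.params.index


class TestExclusionCheck:
    @staticmethod
    def _mobility_frame(rng, n=800, retirement_effect=0.0):
        age = rng.integers(28, 62, n)
        ytr = rng.integers(62, 69, n) - age
        moved = (
            0.05 + retirement_effect * ytr + 0.25 * rng.standard_normal(n) > 0.5 * 0.25
        ).astype(float)
        return pd.DataFrame(
            {
                "moved": moved,
                "age": age,
                "female": rng.integers(0, 2, n),
                "years_to_retirement": ytr,
                "doctor_id": np.arange(n),
                "practice_id": rng.integers(0, 40, n),
                "year": 2005,
            }
        )

    def test_valid_exclusion_rarely_significant(self):
        rng = np.random.default_rng(0)
        spec = ModelSpec("moved", ["age", "female"])
        hits = 0
        for _ in range(100):
            res = exclusion_restriction_check(self._mobility_frame(rng), spec)
            hits += res.extra["exclusion_pvalue"] < 0.05
        assert hits <= 10  # non-significant in >= 90% of replications

    def test_misspecified_retirement_effect_detected(self):
        rng = np.random.default_rng(1)
        spec = ModelSpec("moved", ["age", "female"])
        hits = 0
        for _ in range(60):
            frame = self._mobility_frame(rng, retirement_effect=0.015)
            res = exclusion_restriction_check(frame, spec)
            hits += res.extra["exclusion_pvalue"] < 0.05
        assert hits >= 30  # power of at least one half

    def test_constant_exclusion_variable_warns(self):
        rng = np.random.default_rng(2)
        frame = self._mobility_frame(rng)
        frame["years_to_retirement"] = 20
        with pytest.warns(UserWarning, match="constant"):
            res = exclusion_restriction_check(frame, ModelSpec("moved", ["age", "female"]))
        assert np.isnan(res.extra["exclusion_coef"])
        assert res.extra["exclusion_dropped"]
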