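import math

import numpy as np
import pandas as pd
import pytest

from memstep.ssf_fit import (
    FitResult,
    Stratum,
    Term,
    build_design,
    clogit_loglik,
    fit_clogit,
    rss,
    tslv_optimum,
)


def simulate_design(S, J, beta, seed, cov_scale=1.0):
    """Simulate strata directly from the stratified-softmax model.

    Candidate covariates are iid normal; the used candidate is drawn with
    probability proportional to exp(beta'x). Returns the flat design table.
    """
    rng = np.random.default_rng(seed)
    p = len(beta)
    rows = []
    for s in range(S):
        X = rng.normal(scale=cov_scale, size=(J + 1, p))
        eta = X @ np.asarray(beta)
        w = np.exp(eta - eta.max())
        chosen = rng.choice(J + 1, p=w / w.sum())
        for j in range(J + 1):
            rows.append([s, j, int(j == chosen)] + list(X[j]))
    cols = ["stratum_id", "candidate_id", "used"] + [f"x{k}" for k in range(p)]
    return pd.DataFrame(rows, columns=cols)


def _strata_from_matrix(cov_by_stratum, used_index=0):
    out = []
    for i, cov in enumerate(cov_by_stratum):
        out.append(Stratum(stratum_id=i, t=float(i), covariates=cov, used_index=used_index))
    return out


class TestBuildDesign:
    def test_shape_one_term(self):
        strata = _strata_from_matrix(
            [{"habitat": np.array([0.1, 0.2, 0.3])}, {"habitat": np.array([1.0, 2.0, 3.0])}]
        )
        df = build_design(strata, ["habitat"])
        assert len(df) == 6
        assert list(df.columns) == ["stratum_id", "candidate_id", "used", "habitat"]
        assert df.groupby("stratum_id")["used"].sum().tolist() == [1, 1]

    def test_quadratic_expansion(self):
        strata = _strata_from_matrix([{"tslv": np.array([1.0, 2.0, 5.0])}])
        df = build_design(strata, [Term("tslv", quadratic=True)])
        assert "tslv_sq" in df.columns
        assert np.allclose(df["tslv_sq"], df["tslv"] ** 2)

    def test_missing_covariate_names_stratum_and_term(self):
        strata = _strata_from_matrix([{"habitat": np.array([0.1, 0.2])}])
        with pytest.raises(ValueError, match="tslv"):
            build_design(strata, ["tslv"])

    def test_stratum_constant_term_inestimable(self):
        strata = _strata_from_matrix(
            [{"c": np.array([3.0, 3.0, 3.0])}, {"c": np.array([5.0, 5.0, 5.0])}]
        )
        with pytest.raises(ValueError, match="constant within every stratum"):
            build_design(strata, ["c"])


class TestLoglik:
    def test_null_model_closed_form(self):
        for S, J in [(1, 1), (10, 5), (37, 20)]:
            df = simulate_design(S, J, [0.4, -0.2], seed=S)
            assert clogit_loglik([0.0, 0.0], df) == pytest.approx(-S * math.log(J + 1), abs=1e-10)

    def test_matches_bruteforce_softmax_enumeration(self):
        rng = np.random.default_rng(5)
        df = simulate_design(10, 4, [0.5, -1.0], seed=2)
        for _ in range(5):
            beta = rng.normal(size=2)
            brute = 0.0
            for _, grp in df.groupby("stratum_id"):
                etas = [float(beta @ row) for row in grp[["x0", "x1"]].to_numpy()]
                denom = sum(math.exp(e) for e in etas)
                e_used = etas[int(np.flatnonzero(grp["used"].to_numpy())[0])]
                brute += e_used - math.log(denom)
            assert clogit_loglik(beta, df) == pytest.approx(brute, abs=1e-12)

    def test_stratum_constant_shift_invariance(self):
        df = simulate_design(8, 5, [0.7], seed=3)
        base = clogit_loglik([0.7], df)
        shifted = df.copy()
        # add a different constant to every stratum's covariate column
        shifted["x0"] = shifted["x0"] + shifted["stratum_id"] * 13.5
        assert clogit_loglik([0.7], shifted) == pytest.approx(base, abs=1e-10)

    def test_nonfinite_covariates_rejected(self):
        df = simulate_design(3, 3, [0.1], seed=4)
        df.loc[0, "x0"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            clogit_loglik([0.1], df)


class TestFitClogit:
    def test_parameter_recovery_within_three_se(self):
        beta_true = [0.8, -0.5]
        df = simulate_design(2000, 20, beta_true, seed=10)
        fit = fit_clogit(df)
        assert fit.converged
        for name, b in zip(["x0", "x1"], beta_true):
            assert abs(fit.beta[name] - b) < 3 * fit.se[name]

    def test_matches_dense_grid_search(self):
        df = simulate_design(300, 10, [0.6], seed=11)
        fit = fit_clogit(df)
        coarse = np.arange(-2.0, 2.0, 0.01)
        best = coarse[int(np.argmax([clogit_loglik([b], df) for b in coarse]))]
        fine = np.arange(best - 0.02, best + 0.02, 1e-4)
        best = fine[int(np.argmax([clogit_loglik([b], df) for b in fine]))]
        assert abs(fit.beta["x0"] - best) < 1e-4

    def test_matches_statsmodels_conditional_logit(self):
        """Independent oracle: statsmodels' ConditionalLogit on the same data."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = simulate_design(400, 10, [0.8, -0.5], seed=12)
        ours = fit_clogit(df)
        ref = ConditionalLogit(
            df["used"].to_numpy(), df[["x0", "x1"]].to_numpy(), groups=df["stratum_id"].to_numpy()
        ).fit(disp=False)
        # agreement is limited by the oracle's own optimizer tolerance
        assert np.allclose(ours.beta.values, ref.params, atol=5e-4)
        assert np.allclose(ours.se.values, ref.bse, atol=5e-4)
        assert clogit_loglik(ours.beta.values, df) >= ref.llf - 1e-8
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_separation_flagged(self):
        rows = []
        for s in range(20):
            rows += [[s, 0, 1, 1.0], [s, 1, 0, 0.0], [s, 2, 0, 0.0]]
        df = pd.DataFrame(rows, columns=["stratum_id", "candidate_id", "used", "x0"])
        fit = fit_clogit(df)
        assert not fit.converged
        assert "separation" in fit.diagnostic

    def test_deterministic_given_start(self):
        df = simulate_design(100, 5, [0.3, 0.1], seed=14)
        a, b = fit_clogit(df), fit_clogit(df)
        assert np.array_equal(a.beta.values, b.beta.values)

    def test_concavity_endpoint(self):
        """At the optimum the observed information is positive definite."""
        df = simulate_design(500, 8, [0.5, -0.7], seed=15)
        fit = fit_clogit(df)
        assert fit.converged
        eigvals = np.linalg.eigvalsh(np.linalg.inv(fit.vcov.values))
        assert np.all(eigvals > 0)

    def test_memory_free_reduction(self):
        """Dropping zero-coefficient familiarity columns from the design leaves
        the remaining coefficients' fit identical."""
        df = simulate_design(500, 10, [0.6, 0.0], seed=16)
        full = fit_clogit(df)
        reduced = fit_clogit(df.drop(columns=["x1"]))
        # x1 truly has no effect in the generating model: the x0 estimate and
        # loglik from the reduced fit agree closely with a refit of x0 alone
        assert reduced.converged
        assert abs(full.beta["x0"] - reduced.beta["x0"]) < 2 * full.se["x0"] / 10

    def test_wald_coverage_calibration(self):
        """95% Wald intervals cover the truth at close to nominal rate."""
        beta_true = [0.5, -0.3]
        hits = np.zeros(2, dtype=int)
        n_rep = 60
        for rep in range(n_rep):
            df = simulate_design(300, 10, beta_true, seed=1000 + rep)
            fit = fit_clogit(df)
            for k, name in enumerate(["x0", "x1"]):
                lo, hi = fit.wald_interval(name)
                hits[k] += lo <= beta_true[k] <= hi
        for k in range(2):
            assert 0.85 * n_rep <= hits[k] <= n_rep


class TestPostprocessing:
    def _fit(self, beta, names=None, vcov_scale=0.01):
        names = names or [f"b{i}" for i in range(len(beta))]
        return FitResult(
            beta=pd.Series(beta, index=names),
            vcov=pd.DataFrame(np.eye(len(beta)) * vcov_scale, index=names, columns=names),
            loglik=-1.0,
            converged=True,
            n_strata=10,
        )

    def test_rss_identity(self):
        fit = self._fit([0.5, -1.0])
        assert rss([1.0, 2.0], [1.0, 2.0], fit) == 1.0

    def test_rss_closed_form(self):
        fit = self._fit([math.log(2.0)])
        assert rss([1.0], [0.0], fit) == pytest.approx(2.0, rel=1e-12)

    def test_rss_multiplicative(self):
        fit = self._fit([0.3, -0.7])
        x1, x2, x3 = [1.0, 0.0], [0.2, 0.5], [-1.0, 2.0]
        assert rss(x1, x2, fit) * rss(x2, x3, fit) == pytest.approx(rss(x1, x3, fit), rel=1e-12)

    def test_rss_interval_contains_point(self):
        fit = self._fit([0.5])
        r, lo, hi = rss([1.0], [0.0], fit, interval=True)
        assert lo < r < hi

    def test_rss_dimension_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            rss([1.0], [0.0, 0.0], self._fit([0.5, 0.2]))

    def test_tslv_vertex_formula(self):
        fit = self._fit([0.02, -5e-5], names=["tslv", "tslv_sq"])
        assert tslv_optimum(fit) == pytest.approx(200.0)

    def test_tslv_vertex_zero_linear(self):
        fit = self._fit([0.0, -5e-5], names=["tslv", "tslv_sq"])
        assert tslv_optimum(fit) == 0.0

    def test_tslv_no_interior_maximum(self):
        fit = self._fit([0.02, 1e-5], names=["tslv", "tslv_sq"])
        with pytest.raises(ValueError, match="no interior maximum"):
            tslv_optimum(fit)

    def test_fitresult_json_roundtrip(self, tmp_path):
        fit = self._fit([0.1, 0.2])
        p = tmp_path / "fit.json"
        fit.to_json(p)
        back = FitResult.from_json(p)
        assert np.array_equal(back.beta.values, fit.beta.values)
        assert np.array_equal(back.vcov.values, fit.vcov.values)
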