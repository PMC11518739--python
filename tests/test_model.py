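import numpy as np
import pandas as pd
import pytest

from rrscore.model import (
    PriorConfig,
    RRRPosterior,
    build_model,
    composite_score,
    hpd_interval,
    hpd_significance,
    posterior_predictive,
    sample_posterior,
    spacing_summary,
)
from rrscore.preprocessing import DesignMatrix, Standardizer
from rrscore.synthetic import PredictorSpec


def tiny_design(j=40, seed=0, with_ordinal=True):
    rng = np.random.default_rng(seed)
    values = pd.DataFrame({
        "x_cont": rng.standard_normal(j),
        "x_bin": rng.integers(0, 2, j).astype(float),
    })
    encodings = {"x_cont": "standardized-continuous", "x_bin": "binary"}
    n_levels = {}
    if with_ordinal:
        values["x_ord"] = rng.integers(0, 4, j)
        encodings["x_ord"] = "ordinal-raw-code"
        n_levels["x_ord"] = 4
    return DesignMatrix(values=values, encodings=encodings, n_levels=n_levels,
                        standardizer=Standardizer())


def tiny_outcomes(design, A, B, noise_sd=0.1, seed=1, zeta=None):
    rng = np.random.default_rng(seed)
    X = design.values.to_numpy(dtype=float).copy()
    if "x_ord" in design.values.columns:
        z = zeta if zeta is not None else np.array([0.2, 0.3, 0.5])
        X[:, 2] = np.concatenate([[0.0], np.cumsum(z)])[X[:, 2].astype(int)]
    Y = (X @ A) @ B.T + rng.normal(0, noise_sd, (X.shape[0], B.shape[0]))
    return pd.DataFrame(Y, index=design.values.index,
                        columns=[f"y{i}" for i in range(B.shape[0])])


class TestBuildModel:
    def test_gradient_matches_finite_differences(self):
        design = tiny_design(j=25)
        A = np.array([[1.0], [-0.5], [0.8]])
        B = np.array([[1.1], [0.9]])
        Y = tiny_outcomes(design, A, B)
        Y.iloc[::5, 0] = np.nan  # exercise the mask
        m = build_model(design, Y, PriorConfig())
        rng = np.random.default_rng(2)
        w = rng.normal(0, 0.7, m.dim)
        _, g = m.logp_grad(w)
        eps = 1e-6
        for i in range(m.dim):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            fd = (m.logp_grad(wp)[0] - m.logp_grad(wm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_deterministic_B_collapses_to_shared_predictor(self):
        design = tiny_design(j=30)
        m = build_model(design, tiny_outcomes(design, np.ones((3, 1)),
                                              np.ones((2, 1))),
                        PriorConfig(deterministic_B=True))
        w = np.random.default_rng(0).normal(size=m.dim)
        A, B, zetas = m.unpack(w)
        np.testing.assert_array_equal(B, 1.0)
        # every outcome shares the single linear predictor X @ A
        X = m.encode_X(zetas)
        pred = (X @ A) @ B.T
        for o in range(pred.shape[1]):
            np.testing.assert_allclose(pred[:, o], (X @ A)[:, 0])

    def test_deterministic_B_requires_rank_one(self):
        with pytest.raises(ValueError):
            PriorConfig(rank=2, deterministic_B=True)

    def test_fully_masked_outcomes_rejected(self):
        design = tiny_design(j=10)
        Y = tiny_outcomes(design, np.zeros((3, 1)), np.ones((2, 1)))
        Y[:] = np.nan
        with pytest.raises(ValueError, match="fully missing"):
            build_model(design, Y, PriorConfig())

    def test_shape_mismatch_rejected(self):
        design = tiny_design(j=10)
        Y = tiny_outcomes(tiny_design(j=11, seed=3), np.zeros((3, 1)),
                          np.ones((2, 1)))
        with pytest.raises(ValueError, match="row count"):
            build_model(design, Y, PriorConfig())

    def test_rows_without_observed_outcomes_excluded_with_warning(self):
        design = tiny_design(j=12)
        Y = tiny_outcomes(design, np.ones((3, 1)), np.ones((2, 1)))
        Y.iloc[3] = np.nan
        with pytest.warns(UserWarning, match="no observed outcome"):
            m = build_model(design, Y, PriorConfig())
        assert m.j == 11

    def test_univariate_limit_approaches_least_squares(self):
        # m = n = k = 1 without ordinals: Bayesian linear regression whose
        # posterior-mean slope A*B approaches the OLS slope as data grows
        rng = np.random.default_rng(4)
        j = 400
        x = rng.standard_normal(j)
        y = 0.8 * x + rng.normal(0, 0.3, j)
        design = DesignMatrix(
            values=pd.DataFrame({"x": x}),
            encodings={"x": "standardized-continuous"}, n_levels={},
            standardizer=Standardizer())
        Y = pd.DataFrame({"y": y})
        m = build_model(design, Y, PriorConfig())
        post = sample_posterior(m, chains=2, burn_in=200, retained=200, seed=5)
        xc = x - x.mean()
        slope_ols = float(np.dot(xc, y) / np.dot(xc, xc))
        slope_bayes = float((post.A[:, 0, 0] * post.B[:, 0, 0]).mean())
        assert slope_bayes == pytest.approx(slope_ols, abs=0.05)


@pytest.fixture(scope="module")
def fitted():
    design = tiny_design(j=60)
    A = np.array([[1.2], [-0.8], [0.9]])
    B = np.array([[1.0], [1.3]])
    Y = tiny_outcomes(design, A, B, noise_sd=0.3)
    m = build_model(design, Y, PriorConfig(observation_sd=0.3))
    post = sample_posterior(m, chains=2, burn_in=200, retained=150, seed=3)
    return design, A, B, m, post


class TestSampling:

    def test_draw_count_is_chains_times_retained(self, fitted):
        *_, post = fitted
        assert post.n_draws == 2 * 150
        assert post.A.shape == (300, 3, 1)
        assert post.B.shape == (300, 2, 1)

    def test_B_draws_strictly_positive(self, fitted):
        *_, post = fitted
        assert np.all(post.B > 0)

    def test_zeta_draws_are_simplexes(self, fitted):
        *_, post = fitted
        z = post.zetas["x_ord"]
        assert np.all(z >= 0)
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-10)

    def test_theta_recomputable_from_draws(self, fitted):
        design, _, _, m, post = fitted
        s = 17
        z = {name: post.zetas[name][s] for name in post.zetas}
        np.testing.assert_allclose(post.theta[s], m.encode_X(z) @ post.A[s],
                                   atol=1e-10)

    def test_same_seed_same_draws(self):
        design = tiny_design(j=20)
        Y = tiny_outcomes(design, np.ones((3, 1)), np.ones((2, 1)))
        m = build_model(design, Y, PriorConfig())
        a = sample_posterior(m, chains=1, burn_in=50, retained=50, seed=11)
        b = sample_posterior(m, chains=1, burn_in=50, retained=50, seed=11)
        np.testing.assert_array_equal(a.A, b.A)

    def test_all_missing_row_leaves_posterior_unchanged(self):
        design = tiny_design(j=20)
        Y = tiny_outcomes(design, np.ones((3, 1)), np.ones((2, 1)))
        m1 = build_model(design, Y, PriorConfig())
        Y2 = Y.copy()
        Y2.iloc[7] = np.nan  # this row now contributes nothing
        with pytest.warns(UserWarning):
            m2 = build_model(design, Y2, PriorConfig())
        # not bitwise (row sets differ) but the likelihood only loses one row;
        # with identical seeds the posteriors agree within Monte-Carlo error
        p1 = sample_posterior(m1, chains=1, burn_in=150, retained=150, seed=2)
        p2 = sample_posterior(m2, chains=1, burn_in=150, retained=150, seed=2)
        np.testing.assert_allclose(p1.A.mean(axis=0), p2.A.mean(axis=0),
                                   atol=0.2)


class TestPosteriorPredictive:
    def make_posterior(self, design, A_draws, B_draws, zeta_draws=None):
        m = build_model(design,
                        tiny_outcomes(design, A_draws[0], B_draws[0]),
                        PriorConfig())
        S = A_draws.shape[0]
        zetas = {}
        for name, _, _, D in m.ordinals:
            if zeta_draws is None:
                zetas[name] = np.tile(np.full(D, 1.0 / D), (S, 1))
            else:
                zetas[name] = zeta_draws
        theta = np.stack([
            m.encode_X({k: v[s] for k, v in zetas.items()}) @ A_draws[s]
            for s in range(S)])
        return RRRPosterior(A=A_draws, B=B_draws, zetas=zetas, theta=theta,
                            column_names=list(design.values.columns),
                            outcome_names=["y0", "y1"], model=m)

    def test_zero_loadings_predict_centered_mean(self):
        design = tiny_design(j=15)
        S = 5
        post = self.make_posterior(design, np.zeros((S, 3, 1)), np.ones((S, 2, 1)))
        preds = posterior_predictive(post, design)
        np.testing.assert_allclose(preds, 0.0)

    def test_single_draw_equals_its_linear_map(self):
        design = tiny_design(j=10, with_ordinal=False)
        A = np.array([[[0.5], [-1.0]]])
        B = np.array([[[1.0], [2.0]]])
        post = self.make_posterior(design, A, B)
        preds = posterior_predictive(post, design)
        X = design.values.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)  # likelihood uses the centered predictor
        np.testing.assert_allclose(preds[0], (Xc @ A[0]) @ B[0].T, atol=1e-12)

    def test_mean_matches_explicit_loop(self):
        design = tiny_design(j=12)
        rng = np.random.default_rng(8)
        S = 7
        A = rng.normal(size=(S, 3, 1))
        B = np.exp(rng.normal(size=(S, 2, 1)))
        zeta = rng.dirichlet(np.ones(3), size=S)
        post = self.make_posterior(design, A, B, zeta_draws=zeta)
        preds = posterior_predictive(post, design)
        # brute-force loop oracle (training rows, so centering uses them too)
        acc = np.zeros_like(preds[0])
        for s in range(S):
            X = design.values.to_numpy(dtype=float).copy()
            table = np.concatenate([[0.0], np.cumsum(zeta[s])])
            X[:, 2] = table[design.values["x_ord"].to_numpy()]
            Xc = X - X.mean(axis=0)
            acc += (Xc @ A[s]) @ B[s].T
        np.testing.assert_allclose(preds.mean(axis=0), acc / S, atol=1e-10)

    def test_column_mismatch_rejected(self):
        design = tiny_design(j=10)
        post = self.make_posterior(design, np.zeros((2, 3, 1)), np.ones((2, 2, 1)))
        other = tiny_design(j=5, with_ordinal=False)
        with pytest.raises(ValueError, match="columns"):
            posterior_predictive(post, other)


class TestCompositeScore:
    def test_zero_row_scores_zero(self):
        design = tiny_design(j=6, with_ordinal=False)
        design.values.iloc[0] = 0.0
        post = TestPosteriorPredictive().make_posterior(
            design, np.random.default_rng(0).normal(size=(4, 2, 1)),
            np.ones((4, 2, 1)))
        theta, summary = composite_score(post, design)
        np.testing.assert_allclose(theta[:, 0, 0], 0.0, atol=1e-12)

    def test_duplicated_row_duplicates_summaries(self):
        design = tiny_design(j=5, with_ordinal=False)
        design.values.iloc[1] = design.values.iloc[0]
        post = TestPosteriorPredictive().make_posterior(
            design, np.random.default_rng(1).normal(size=(4, 2, 1)),
            np.ones((4, 2, 1)))
        _, summary = composite_score(post, design)
        a, b = summary.iloc[0], summary.iloc[1]
        assert a["mean"] == pytest.approx(b["mean"])
        assert a["hpd_low"] == pytest.approx(b["hpd_low"])

    def test_positive_B_preserves_ranking_against_predictions(self):
        # ranking visits by posterior-mean theta equals ranking by any
        # outcome's posterior-mean prediction (B > 0 is order preserving)
        design = tiny_design(j=25)
        rng = np.random.default_rng(2)
        S = 9
        A = rng.normal(size=(S, 3, 1))
        B = np.exp(rng.normal(size=(S, 2, 1)))
        helper = TestPosteriorPredictive()
        post = helper.make_posterior(design, A, B)
        theta, _ = composite_score(post, design)
        preds = posterior_predictive(post, design)
        # per-draw equality of orderings (positivity acts draw-wise)
        for s in range(S):
            rank_theta = np.argsort(theta[s, :, 0])
            rank_pred = np.argsort(preds[s, :, 0])
            np.testing.assert_array_equal(rank_theta, rank_pred)


def brute_force_hpd(draws, level=0.95):
    """Oracle: enumerate every window of ceil(level*S) sorted draws."""
    s = np.sort(draws)
    n = len(s)
    w = int(np.ceil(level * n))
    best = None
    for i in range(n - w + 1):
        width = s[i + w - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + w - 1])
    return best[1], best[2]


class TestHPD:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for draws in (rng.standard_normal(101), rng.exponential(size=200),
                      rng.normal(5, 0.1, 57)):
            lo, hi = hpd_interval(draws)
            blo, bhi = brute_force_hpd(draws)
            assert (lo, hi) == pytest.approx((blo, bhi))

    def test_consistent_with_arviz_reference(self):
        # arviz's hdi keeps floor(level*S)+1 order statistics, ours the
        # narrowest window holding ceil(level*S); intervals agree up to
        # one order statistic at the boundary
        import arviz as az
        draws = np.random.default_rng(3).standard_normal(1000)
        lo, hi = hpd_interval(draws, 0.95)
        ref_lo, ref_hi = az.hdi(draws, hdi_prob=0.95)
        assert ref_lo - 1e-12 <= lo and hi <= ref_hi + 1e-12
        assert np.mean((draws >= lo) & (draws <= hi)) >= 0.95
        assert (hi - lo) <= (ref_hi - ref_lo) + 1e-12

    def test_narrower_than_equal_tailed(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            draws = rng.exponential(size=300)
            lo, hi = hpd_interval(draws)
            eq = np.quantile(draws, [0.025, 0.975])
            assert (hi - lo) <= (eq[1] - eq[0]) + 1e-12

    def test_tight_normal_is_significant_risk(self):
        draws = np.random.default_rng(2).normal(5, 0.1, 1000)
        lo, hi = hpd_interval(draws)
        # matches normal-quantile expectations
        assert lo == pytest.approx(5 - 1.96 * 0.1, abs=0.05)
        assert hi == pytest.approx(5 + 1.96 * 0.1, abs=0.05)

    def test_degenerate_draws(self):
        lo, hi = hpd_interval(np.zeros(100))
        assert lo == hi == 0.0
        lo, hi = hpd_interval(np.full(100, 3.0))
        assert lo == hi == 3.0


class TestSignificance:
    def make_post(self, A_draws):
        design = tiny_design(j=8, with_ordinal=False)
        m = build_model(design, tiny_outcomes(design, A_draws[0],
                                              np.ones((2, 1))), PriorConfig())
        S = A_draws.shape[0]
        return RRRPosterior(A=A_draws, B=np.ones((S, 2, 1)), zetas={},
                            theta=np.zeros((S, 8, 1)),
                            column_names=["x_cont", "x_bin"],
                            outcome_names=["y0", "y1"], model=m)

    def test_all_zero_draws_not_significant(self):
        table = hpd_significance(self.make_post(np.zeros((100, 2, 1))))
        assert not table["significant"].any()

    def test_tight_positive_draws_significant_risk(self):
        rng = np.random.default_rng(4)
        A = np.zeros((1000, 2, 1))
        A[:, 0, 0] = rng.normal(5, 0.1, 1000)
        table = hpd_significance(self.make_post(A))
        row = table[table["predictor"] == "x_cont"].iloc[0]
        assert row["significant"]
        assert row["direction"] == "risk"

    def test_constant_nonzero_draws_significant(self):
        A = np.full((50, 2, 1), -2.0)
        table = hpd_significance(self.make_post(A))
        assert table["significant"].all()
        assert (table["direction"] == "protective").all()


class TestSpacing:
    def test_summary_lists_every_transition(self):
        design = tiny_design(j=20)
        helper = TestPosteriorPredictive()
        post = helper.make_posterior(
            design, np.random.default_rng(0).normal(size=(6, 3, 1)),
            np.ones((6, 2, 1)))
        table = spacing_summary(post)
        assert set(table["transition"]) == {"0->1", "1->2", "2->3"}
        assert len(table) == 3
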