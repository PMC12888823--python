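import numpy as np
import pandas as pd
import pytest

from splicecontrol.netinfer import (
    ColumnSpec,
    RegressionProblem,
    bayesian_lasso_fit,
    build_problem,
    call_edges,
    estimate_derivative,
    infer_network,
    kernel_weights,
    smooth_curves,
)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        s = np.linspace(0, 1, 30)
        out = smooth_curves(np.full((1, 30), 2.5), s, h=0.05)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_tiny_bandwidth_returns_input(self):
        rng = np.random.default_rng(0)
        s = np.linspace(0, 1, 25)
        v = rng.standard_normal((2, 25))
        out = smooth_curves(v, s, h=1e-4)
        np.testing.assert_allclose(out, v, atol=1e-10)

    def test_linear_series_interior_near_line(self):
        s = np.linspace(0, 1, 101)
        v = (3.0 * s)[None, :]
        out = smooth_curves(v, s, h=0.05)
        interior = slice(15, -15)
        np.testing.assert_allclose(out[0, interior], v[0, interior], atol=1e-3)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kernel_weights(np.linspace(0, 1, 5), 0.0)


class TestDerivative:
    def test_linear_function_exact(self):
        s = np.linspace(0, 1, 40)
        d = estimate_derivative(3.0 * s, s)
        np.testing.assert_allclose(d, 3.0, atol=1e-10)

    def test_quadratic_exact_on_irregular_grid(self):
        rng = np.random.default_rng(1)
        s = np.sort(rng.random(30))
        d = estimate_derivative(s**2, s)
        np.testing.assert_allclose(d, 2 * s, atol=1e-10)

    def test_constant_is_zero(self):
        s = np.linspace(0, 1, 10)
        np.testing.assert_allclose(estimate_derivative(np.ones(10), s), 0.0, atol=1e-12)

    def test_duplicate_pseudotime_rejected(self):
        s = np.array([0.0, 0.5, 0.5, 1.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            estimate_derivative(np.arange(4.0), s)


def _curves_dicts(rng, n_as=5, n_rbp=3, n_tf=2, n=30):
    s = np.linspace(0, 1, n)
    cols = [f"S{i}" for i in range(n)]
    d = {}
    der = {}
    for layer, cnt, prefix in (("AS", n_as, "AS"), ("RBP", n_rbp, "RBP"), ("TF", n_tf, "TF")):
        vals = rng.uniform(0.5, 2.0, size=(cnt, n))
        d[layer] = pd.DataFrame(vals, index=[f"{prefix}{i+1}" for i in range(cnt)], columns=cols)
        der[layer] = pd.DataFrame(
            estimate_derivative(vals, s), index=d[layer].index, columns=cols
        )
    return d, der, s


class TestBuildProblem:
    def test_as_node_column_count(self):
        rng = np.random.default_rng(2)
        curves, derivs, _ = _curves_dicts(rng)
        pr = build_problem("AS1", "AS", curves, derivs)
        assert pr.X.shape[1] == 4 + 3 + 1  # partners + upstream RBPs + degradation

    def test_tf_node_has_no_upstream_layer(self):
        rng = np.random.default_rng(3)
        curves, derivs, _ = _curves_dicts(rng)
        pr = build_problem("TF1", "TF", curves, derivs)
        assert pr.X.shape[1] == 1 + 1
        assert {c.family for c in pr.columns} == {"g", "d"}

    def test_columns_equal_bruteforce_products(self):
        rng = np.random.default_rng(4)
        curves, derivs, _ = _curves_dicts(rng)
        pr = build_problem("RBP2", "RBP", curves, derivs)
        own = curves["RBP"].loc["RBP2"].to_numpy()[1:-1]
        for j, spec in enumerate(pr.columns):
            if spec.kind == "degradation":
                expected = -curves["RBP"].loc["RBP2"].to_numpy()[1:-1]
            else:
                expected = own * curves[spec.source_layer].loc[spec.source].to_numpy()[1:-1]
            np.testing.assert_allclose(pr.X[:, j] * pr.scales[j], expected, rtol=1e-12)

    def test_forbidden_layer_pairs_never_appear(self):
        rng = np.random.default_rng(5)
        curves, derivs, _ = _curves_dicts(rng)
        forbidden = {("TF", "AS"), ("AS", "RBP"), ("RBP", "TF"), ("AS", "TF")}
        for layer in ("AS", "RBP", "TF"):
            for node in curves[layer].index:
                pr = build_problem(node, layer, curves, derivs)
                pairs = {
                    (c.source_layer, c.target_layer)
                    for c in pr.columns if c.kind == "edge"
                }
                assert not pairs & forbidden


def _toy_problem(rng, n=50, p=6, beta1=2.0, noise=0.05):
    X = rng.standard_normal((n, p))
    y = beta1 * X[:, 0] + noise * rng.standard_normal(n)
    cols = [
        ColumnSpec("edge", "a", f"N{j}", "T", "AS", "AS") for j in range(p)
    ]
    return RegressionProblem(node="T", layer="AS", y=y, X=X, columns=cols,
                             scales=np.ones(p))


class TestBayesianLasso:
    def test_null_response_shrinks_to_zero(self):
        rng = np.random.default_rng(0)
        pr = _toy_problem(rng, beta1=0.0, noise=0.0)
        pr.y = np.zeros_like(pr.y)
        post = bayesian_lasso_fit(pr, iters=2000, burn=500, seed=1)
        assert np.all(np.abs(post.post_mean) < 1e-2)

    def test_signal_recovered_spurious_suppressed(self):
        rng = np.random.default_rng(1)
        pr = _toy_problem(rng, beta1=2.0, noise=0.05)
        post = bayesian_lasso_fit(pr, iters=3000, burn=1000, seed=2)
        assert 1.8 < post.post_mean[0] < 2.2
        assert np.all(np.abs(post.post_mean[1:]) < 0.2)

    def test_shrinkage_below_ols_single_column(self):
        rng = np.random.default_rng(2)
        n = 30
        x = rng.standard_normal(n)
        y = 1.5 * x + 0.5 * rng.standard_normal(n)
        pr = RegressionProblem(
            node="T", layer="AS", y=y, X=x[:, None],
            columns=[ColumnSpec("edge", "a", "S", "T", "AS", "AS")],
            scales=np.ones(1),
        )
        post = bayesian_lasso_fit(pr, iters=4000, burn=1000, seed=3)
        ols = float(x @ y / (x @ x))
        assert abs(post.post_mean[0]) <= abs(ols) + 1e-6

    def test_bad_iteration_budget_rejected(self):
        rng = np.random.default_rng(3)
        pr = _toy_problem(rng)
        with pytest.raises(ValueError, match="iters > burn"):
            bayesian_lasso_fit(pr, iters=10, burn=10)


class TestEdgeCalling:
    def _posterior(self, draws_by_col):
        cols = []
        draws = []
        for i, (spec_kind, d) in enumerate(draws_by_col):
            cols.append(
                ColumnSpec(spec_kind, "a" if spec_kind == "edge" else "d",
                           f"S{i}", "T", "AS", "AS")
            )
            draws.append(d)
        import numpy as np

        post = pytest.importorskip("splicecontrol.netinfer").PosteriorSummary(
            node="T", layer="AS", columns=cols, draws=np.column_stack(draws)
        )
        return post

    def test_interval_spanning_zero_not_called(self):
        rng = np.random.default_rng(4)
        d_span = rng.uniform(-0.1, 0.4, 2000)
        d_pos = rng.uniform(0.2, 0.9, 2000)
        post = self._posterior([("edge", d_span), ("edge", d_pos), ("degradation", d_pos)])
        net = call_edges([post], level=0.9)
        assert net.edges["called"].tolist() == [0, 1]
        assert net.edges.loc[1, "sign"] == 1

    def test_called_set_matches_interval_rule_on_draws(self):
        rng = np.random.default_rng(5)
        draws = [("edge", rng.standard_normal(3000) + rng.uniform(-1, 1))
                 for _ in range(8)]
        post = self._posterior(draws)
        net = call_edges([post], level=0.9)
        for j, (_, d) in enumerate(draws):
            lo, hi = np.quantile(d, 0.05), np.quantile(d, 0.95)
            assert net.edges.loc[j, "called"] == int(lo > 0 or hi < 0)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            call_edges([], level=1.5)


class TestInferNetwork:
    def test_hierarchy_invariant_on_inferred_network(self, clean_sim):
        panel, truth = clean_sim
        net = infer_network(panel, truth.pseudotime, iters=600, burn=200, seed=0)
        allowed = {("AS", "AS"), ("RBP", "AS"), ("RBP", "RBP"), ("TF", "RBP"), ("TF", "TF")}
        pairs = set(zip(net.edges["source_layer"], net.edges["target_layer"]))
        assert pairs <= allowed
        assert not (net.edges["source"] == net.edges["target"]).any()
        assert (net.edges["score"] >= 0).all()

    def test_coefficient_recovery_against_truth(self, clean_sim):
        # noiseless panel, true pseudotime given: posterior means of the true
        # nonzero coefficients correlate strongly with the generating values
        panel, truth = clean_sim
        net = infer_network(panel, truth.pseudotime, iters=2000, burn=500, seed=0)
        fam_mats = {f: truth.coefficient_matrix(f) for f in "abceg"}
        names = {lay: truth.node_names(lay) for lay in ("AS", "RBP", "TF")}
        est, true_vals = [], []
        for row in net.edges.itertuples():
            mat = fam_mats[row.family]
            i = names[row.target_layer].index(row.target)
            j = names[row.source_layer].index(row.source)
            if mat[i, j] != 0.0:
                est.append(row.post_mean)
                true_vals.append(mat[i, j])
        r = np.corrcoef(est, true_vals)[0, 1]
        assert r >= 0.8
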