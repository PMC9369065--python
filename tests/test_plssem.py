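"""PLS path modeling: oracle equivalences, recovery, bootstrap, effects."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from chillsem import (
    PathModel,
    SimulationConfig,
    ave,
    bootstrap,
    composite_reliability,
    effects,
    fit_pls,
    hormone_mediation_model,
    simulate_dataset,
    to_dot,
    validate_model,
)
from chillsem.plssem import LowSampleWarning, PLSFit
from conftest import matrix_from_columns


def bivariate(n=200, r=0.6, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
    em = matrix_from_columns({"x": x, "y": y})
    model = PathModel({"X": ["x"], "Y": ["y"]}, [("X", "Y")])
    return em, model, x, y


class TestOracleEquivalence:
    def test_perfect_dependence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        em = matrix_from_columns({"x": x, "y": x.copy()})
        fit = fit_pls(em, PathModel({"X": ["x"], "Y": ["y"]}, [("X", "Y")]))
        assert fit.path_coefficients[("X", "Y")] == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared["Y"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.loadings, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_bivariate_path_is_pearson_correlation(self, seed):
        em, model, x, y = bivariate(n=60, r=0.4, seed=seed)
        fit = fit_pls(em, model)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.path_coefficients[("X", "Y")] == pytest.approx(r, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_multipredecessor_paths_are_standardized_ols(self, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.standard_normal((2, 80))
        y = 0.5 * x1 - 0.3 * x2 + rng.standard_normal(80)
        em = matrix_from_columns({"x1": x1, "x2": x2, "y": y})
        model = PathModel({"X1": ["x1"], "X2": ["x2"], "Y": ["y"]},
                          [("X1", "Y"), ("X2", "Y")])
        fit = fit_pls(em, model)
        # standardized OLS oracle
        Z = np.column_stack([(v - v.mean()) / v.std() for v in (x1, x2, y)])
        beta = np.linalg.lstsq(Z[:, :2], Z[:, 2], rcond=None)[0]
        assert fit.path_coefficients[("X1", "Y")] == pytest.approx(beta[0], abs=1e-10)
        assert fit.path_coefficients[("X2", "Y")] == pytest.approx(beta[1], abs=1e-10)


class TestFitProperties:
    def test_scores_standardized(self, fig9_dataset, fig9_model):
        fit = fit_pls(fig9_dataset.expression, fig9_model)
        assert np.allclose(fit.scores.mean(), 0.0, atol=1e-8)
        assert np.allclose(fit.scores.var(ddof=0), 1.0, atol=1e-8)

    def test_parameter_recovery_close_to_truth(self, fig9_dataset, fig9_model):
        fit = fit_pls(fig9_dataset.expression, fig9_model)
        errs = [abs(fit.path_coefficients[e] - fig9_dataset.true_paths[e])
                for e in fig9_model.edges]
        assert max(errs) < 0.08 and np.mean(errs) < 0.05

    def test_single_predecessor_path_is_score_correlation(self, fig9_dataset,
                                                          fig9_model):
        fit = fit_pls(fig9_dataset.expression, fig9_model)
        r = np.corrcoef(fit.scores["ABA"], fit.scores["ICE1"])[0, 1]
        assert fit.path_coefficients[("ABA", "ICE1")] == pytest.approx(r, abs=1e-10)

    def test_ave_identity_against_raw_data(self, fig9_dataset, fig9_model):
        fit = fit_pls(fig9_dataset.expression, fig9_model)
        X = fig9_dataset.expression.values
        for latent, inds in fig9_model.latents.items():
            lams = [np.corrcoef(X.loc[g], fit.scores[latent])[0, 1]
                    for g in inds]
            assert ave(fit, latent) == pytest.approx(
                np.mean(np.square(lams)), abs=1e-10)

    def test_scale_invariance_of_input(self, fig9_dataset, fig9_model):
        em = fig9_dataset.expression
        shifted = em.values * 7.3 + 11.0
        em2 = type(em)(shifted, em.design, kind="log")
        f1 = fit_pls(em, fig9_model)
        f2 = fit_pls(em2, fig9_model)
        for e in fig9_model.edges:
            assert f1.path_coefficients[e] == pytest.approx(
                f2.path_coefficients[e], abs=1e-9)

    def test_schemes_agree_on_well_conditioned_data(self):
        ds = simulate_dataset(SimulationConfig(n_samples=400, loadings=0.85,
                                               seed=21))
        ann = ds.annotation
        blocks = {b: list(ann.gene[ann.block == b]) for b in ann.block.unique()}
        edges = [(s, t) for s, t, _ in ds.config.structural_edges]
        results = {}
        for scheme in ["path", "centroid", "factorial"]:
            fit = fit_pls(ds.expression, PathModel(blocks, edges, scheme))
            results[scheme] = np.array([fit.path_coefficients[e] for e in edges])
        assert np.abs(results["path"] - results["centroid"]).max() < 0.02
        assert np.abs(results["path"] - results["factorial"]).max() < 0.02

    def test_low_sample_regime_warns_but_fits(self):
        ds = simulate_dataset(SimulationConfig(n_samples=12, seed=33))
        ann = ds.annotation
        blocks = {b: list(ann.gene[ann.block == b]) for b in ann.block.unique()}
        model = PathModel(blocks, [(s, t) for s, t, _ in ds.config.structural_edges])
        with pytest.warns(LowSampleWarning):
            fit = fit_pls(ds.expression, model)
        assert fit.converged

    def test_constant_indicator_rejected(self):
        em = matrix_from_columns({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            fit_pls(em, PathModel({"X": ["x"], "Y": ["y"]}, [("X", "Y")]))

    def test_model_validation_errors(self):
        with pytest.raises(ValueError, match="DAG"):
            PathModel({"A": ["a"], "B": ["b"]}, [("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="shared"):
            PathModel({"A": ["a"], "B": ["a"]}, [("A", "B")])
        with pytest.raises(ValueError, match="no indicators"):
            PathModel({"A": []}, [])

    def test_model_yaml_roundtrip(self, tmp_path, fig9_model):
        fig9_model.to_yaml(tmp_path / "m.yaml")
        back = PathModel.from_yaml(tmp_path / "m.yaml")
        assert back.latents == fig9_model.latents
        assert back.edges == fig9_model.edges
        assert back.scheme == fig9_model.scheme


class TestReliabilityMetrics:
    def fit_with_loadings(self, lams):
        model = PathModel({"L": [f"x{i}" for i in range(len(lams))]}, [])
        return PLSFit(model,
                      outer_weights=pd.Series(lams, index=model.latents["L"]),
                      loadings=pd.Series(lams, index=model.latents["L"]),
                      scores=pd.DataFrame(), path_coefficients={},
                      r_squared={}, n_iterations=1, converged=True)

    @pytest.mark.parametrize("lams, expected", [
        ([0.8, 0.6], 0.5),
        ([0.9, 0.9, 0.9], 0.81),
        ([1.0], 1.0),
    ])
    def test_ave_values(self, lams, expected):
        assert ave(self.fit_with_loadings(lams), "L") == pytest.approx(expected)

    @pytest.mark.parametrize("lams, expected", [
        ([1.0], 1.0),
        ([0.8, 0.8], (1.6 ** 2) / (1.6 ** 2 + 2 * 0.36)),
        ([0.0, 0.0], 0.0),
    ])
    def test_composite_reliability_values(self, lams, expected):
        assert composite_reliability(self.fit_with_loadings(lams), "L") == \
            pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("lams, passes", [
        ([0.9, 0.9], True),
        ([0.8, 0.6], True),     # AVE exactly 0.5: inclusive boundary
        ([0.5, 0.5], False),
    ])
    def test_validate_model_threshold(self, lams, passes):
        report = validate_model(self.fit_with_loadings(lams))
        assert bool(report.loc["L", "passes"]) is passes


class TestEffects:
    def fit_with_paths(self, latents, edges, coefs):
        model = PathModel({l: [l.lower()] for l in latents}, edges)
        return PLSFit(model, pd.Series(dtype=float), pd.Series(dtype=float),
                      pd.DataFrame(), dict(zip(edges, coefs)), {}, 1, True)

    def test_three_node_mediation(self):
        fit = self.fit_with_paths(
            ["H", "T", "A"], [("H", "T"), ("T", "A"), ("H", "A")],
            [0.5, 0.4, 0.2])
        table = effects(fit).set_index(["source", "target"])
        assert table.loc[("H", "A"), "indirect"] == pytest.approx(0.20)
        assert table.loc[("H", "A"), "total"] == pytest.approx(0.40)
        assert table.loc[("H", "T"), "indirect"] == 0.0

    def test_parallel_mediators_sum_of_products(self):
        a = [0.5, -0.4, 0.3]
        b = [0.25, 0.35, -0.15]
        c = 0.1
        edges = [("H", "T1"), ("H", "T2"), ("H", "T3"),
                 ("T1", "A"), ("T2", "A"), ("T3", "A"), ("H", "A")]
        fit = self.fit_with_paths(["H", "T1", "T2", "T3", "A"], edges,
                                  a + b + [c])
        table = effects(fit).set_index(["source", "target"])
        expected = sum(ai * bi for ai, bi in zip(a, b))
        assert table.loc[("H", "A"), "indirect"] == pytest.approx(expected)
        assert table.loc[("H", "A"), "total"] == pytest.approx(expected + c)

    def test_agrees_with_bruteforce_path_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            names = [f"L{i}" for i in range(n)]
            edges, coefs = [], {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        edges.append((names[i], names[j]))
                        coefs[(names[i], names[j])] = float(rng.uniform(-1, 1))
            if not edges:
                continue
            fit = self.fit_with_paths(names, edges, [coefs[e] for e in edges])
            table = effects(fit).set_index(["source", "target"])
            g = nx.DiGraph(edges)
            for src in names:
                for tgt in names:
                    if src == tgt:
                        continue
                    indirect = 0.0
                    if src in g and tgt in g:
                        for path in nx.all_simple_paths(g, src, tgt):
                            if len(path) > 2:
                                prod = np.prod([coefs[(path[k], path[k + 1])]
                                                for k in range(len(path) - 1)])
                                indirect += prod
                    assert table.loc[(src, tgt), "indirect"] == \
                        pytest.approx(indirect, abs=1e-12)


class TestBootstrap:
    def test_degenerate_perfect_dependence(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        em = matrix_from_columns({"x": x, "y": x.copy()})
        model = PathModel({"X": ["x"], "Y": ["y"]}, [("X", "Y")])
        summary = bootstrap(em, model, B=50, seed=1)
        paths = summary.table[summary.table["kind"] == "path"]
        assert paths["se"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert paths["boot_mean"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_se_close_to_analytic_correlation_se(self):
        em, model, x, y = bivariate(n=200, r=0.6, seed=42)
        summary = bootstrap(em, model, B=2000, seed=5)
        r = np.corrcoef(x, y)[0, 1]
        analytic = (1 - r ** 2) / np.sqrt(len(x) - 1)
        se = summary.table.query("kind == 'path'")["se"].iloc[0]
        assert abs(se - analytic) / analytic < 0.15

    def test_seed_determinism(self, fig9_dataset, fig9_model):
        a = bootstrap(fig9_dataset.expression, fig9_model, B=50, seed=9)
        b = bootstrap(fig9_dataset.expression, fig9_model, B=50, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_sign_alignment_keeps_loading_signs(self, fig9_dataset, fig9_model):
        summary = bootstrap(fig9_dataset.expression, fig9_model, B=100, seed=3)
        loads = summary.table[summary.table["kind"] == "loading"]
        # original loadings are strongly positive; aligned bootstrap means too
        assert (loads["boot_mean"] * np.sign(loads["original"]) > 0).all()

    def test_rejects_tiny_b(self, fig9_dataset, fig9_model):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap(fig9_dataset.expression, fig9_model, B=1)


class TestExport:
    def test_dot_edges_match_model(self, fig9_dataset, fig9_model):
        fit = fit_pls(fig9_dataset.expression, fig9_model)
        dot = to_dot(fit)
        assert dot.count("->") == len(fig9_model.edges)
        assert "red" in dot  # positive paths present
        assert "blue" in dot  # negative generating paths recovered as negative

    def test_default_mediation_topology(self):
        model = hormone_mediation_model(
            "ABA", ["a1", "a2"], {"ICE1": ["i1"], "CBF": ["c1"], "bZIP": ["b1"]},
            ["o1", "o2"])
        assert len(model.edges) == 7
        assert ("ABA", "AO") in model.edges
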