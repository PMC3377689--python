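import numpy as np
import pandas as pd
import pytest

from hdmrnet import (
    DataTable,
    FitConfig,
    HDMRModel,
    build_orthonormal_basis,
    enumerate_candidates,
    f_test_select,
    fit_hdmr,
    fit_least_squares,
    normalize_unit_interval,
    predict,
)
from hdmrnet.basis import evaluate_terms

from conftest import make_unit_table


class TestEnumerateCandidates:
    def test_first_order_only(self):
        assert len(enumerate_candidates(["a", "b", "c"], 1)) == 3

    def test_exhaustive_pair_count(self):
        inputs = [f"x{i}" for i in range(10)]
        cands = enumerate_candidates(inputs, 2, policy="exhaustive")
        assert len(cands) == 10 + 45  # C(10,2) second-order tuples

    def test_hierarchical_restricts_to_selected(self):
        inputs = [f"x{i}" for i in range(10)]
        cands = enumerate_candidates(
            inputs, 2, policy="hierarchical", selected_first_order=["x0", "x3", "x7"]
        )
        assert len(cands) == 10 + 3  # C(3,2) pairs

    def test_third_order_counts(self):
        inputs = [f"x{i}" for i in range(6)]
        cands = enumerate_candidates(inputs, 3, policy="exhaustive")
        assert len(cands) == 6 + 15 + 20

    def test_lexicographic_deterministic(self):
        a = enumerate_candidates(["b", "a", "c"], 2, "exhaustive")
        assert a[:3] == [(1, ("a",)), (1, ("b",)), (1, ("c",))]
        assert a[3] == (2, ("a", "b"))


def _bases_for(table, inputs, degree=3):
    return {
        v: build_orthonormal_basis(table.values[v].to_numpy(), degree, v) for v in inputs
    }


class TestFTestSelect:
    def test_pure_noise_collapses_to_mean(self, rng):
        """Independent-noise outputs should reduce to the zeroth-order term."""
        n = 300
        cols = {f"x{i}": rng.uniform(0, 1, n) for i in range(4)}
        cols["y"] = rng.standard_normal(n)
        t = make_unit_table(cols)
        bases = _bases_for(t, [c for c in cols if c != "y"])
        cands = enumerate_candidates(list(bases), 1)
        sel, log = f_test_select(t, "y", cands, 0.01, bases)
        # individual candidates may sneak in at rate ~alpha; with 4 candidates
        # the expected count is 0.04, so demand near-certain collapse
        assert len(sel) <= 1
        assert len(log) == 4

    def test_strong_signal_always_selected(self, rng):
        n = 1000
        x1 = rng.uniform(0, 1, n)
        cols = {"x1": x1, "x2": rng.uniform(0, 1, n)}
        cols["y"] = np.sqrt(3) * (2 * x1 - 1) + 0.1 * rng.standard_normal(n)
        t = make_unit_table(cols)
        bases = _bases_for(t, ["x1", "x2"])
        sel, _ = f_test_select(t, "y", enumerate_candidates(["x1", "x2"], 1), 0.01, bases)
        assert (1, ("x1",)) in sel

    def test_false_inclusion_rate_tracks_alpha(self):
        """Per-candidate type-I error on null data sits near the alpha level."""
        alpha, n_rep, k = 0.05, 120, 5
        master = np.random.default_rng(2024)
        false_inc = trials = 0
        for _ in range(n_rep):
            n = 150
            cols = {f"x{i}": master.uniform(0, 1, n) for i in range(k)}
            cols["y"] = master.standard_normal(n)
            t = make_unit_table(cols)
            bases = _bases_for(t, [c for c in cols if c != "y"], degree=2)
            sel, log = f_test_select(
                t, "y", enumerate_candidates(list(bases), 1), alpha, bases
            )
            false_inc += len(sel)
            trials += len(log)
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], trials, alpha)
        assert lo <= false_inc <= hi

    def test_alpha_near_one_selects_everything(self, rng):
        n = 200
        cols = {f"x{i}": rng.uniform(0, 1, n) for i in range(3)}
        cols["y"] = rng.standard_normal(n)
        t = make_unit_table(cols)
        bases = _bases_for(t, [c for c in cols if c != "y"], degree=2)
        sel, _ = f_test_select(
            t, "y", enumerate_candidates(list(bases), 1), 0.999999, bases
        )
        assert len(sel) == 3

    def test_df_exhaustion_raises(self, rng):
        n = 4
        cols = {"x1": rng.uniform(0, 1, n), "y": rng.uniform(0, 1, n)}
        t = make_unit_table(cols)
        bases = {"x1": build_orthonormal_basis(cols["x1"], 3, "x1")}
        with pytest.raises(ValueError, match="df"):
            f_test_select(t, "y", [(1, ("x1",))], 0.01, bases)


class TestLeastSquares:
    def test_constant_output_reduces_to_f0(self, rng):
        n = 50
        cols = {"x1": rng.uniform(0, 1, n), "y": np.full(n, 0.4)}
        t = make_unit_table(cols)
        bases = _bases_for(t, ["x1"])
        m = fit_least_squares(t, "y", [(1, ("x1",))], bases)
        assert m.f0 == pytest.approx(0.4, abs=1e-12)
        assert np.allclose(m.components[0].weights, 0.0, atol=1e-10)
        assert m.residual_variance == pytest.approx(0.0, abs=1e-20)

    def test_recovers_generating_coefficients_exactly(self, rng):
        """Noiseless data from a known expansion: weights back to 1e-6."""
        n = 2000
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        b1 = build_orthonormal_basis(x1, 3, "x1")
        b2 = build_orthonormal_basis(x2, 3, "x2")
        alpha = np.array([0.9, -0.4, 0.2])
        beta12 = 0.6  # weight of phi_1(x1) * phi_1(x2)
        y = 0.5 + b1.evaluate(x1) @ alpha + beta12 * b1.evaluate(x1)[:, 0] * b2.evaluate(x2)[:, 0]
        t = make_unit_table({"x1": x1, "x2": x2, "y": y})
        cfg = FitConfig(degree_second=1)
        m = fit_least_squares(
            t, "y", [(1, ("x1",)), (1, ("x2",)), (2, ("x1", "x2"))],
            {"x1": b1, "x2": b2}, config=cfg,
        )
        by_vars = {c.variable_ids: c for c in m.components}
        assert np.allclose(by_vars[("x1",)].weights, alpha, atol=1e-6)
        assert np.allclose(by_vars[("x2",)].weights, 0.0, atol=1e-6)
        assert by_vars[("x1", "x2")].weights[0] == pytest.approx(beta12, abs=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        """Small random instance: solution equals brute-force normal equations."""
        n = 50
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y = rng.standard_normal(n)
        t = make_unit_table({"x1": x1, "x2": x2, "y": y})
        bases = _bases_for(t, ["x1", "x2"])
        selected = [(1, ("x1",)), (1, ("x2",))]
        m = fit_least_squares(t, "y", selected, bases)

        # oracle: centered design, normal equations solved directly
        cols = []
        for cand in selected:
            T = evaluate_terms(bases, (cand[0], cand[1], (3,) * cand[0]), t.values)
            cols.append(T - T.mean(axis=0))
        X = np.hstack(cols)
        yc = y - y.mean()
        beta = np.linalg.solve(X.T @ X, X.T @ yc)
        fitted = np.concatenate([c.weights for c in m.components])
        assert np.allclose(fitted, beta, atol=1e-8)

    def test_weighted_fit_weights_mean(self, rng):
        n = 40
        cols = {"x1": rng.uniform(0, 1, n), "y": rng.uniform(0, 1, n)}
        t = make_unit_table(cols)
        bases = _bases_for(t, ["x1"])
        w = rng.uniform(0.1, 2.0, n)
        m = fit_least_squares(t, "y", [], bases, sample_weights=w)
        assert m.f0 == pytest.approx(float(w @ cols["y"] / w.sum()), abs=1e-12)

    def test_collinear_design_reported(self, rng):
        n = 100
        x1 = rng.uniform(0, 1, n)
        t = make_unit_table({"x1": x1, "x2": x1.copy(), "y": rng.uniform(0, 1, n)})
        b1 = build_orthonormal_basis(x1, 2, "x1")
        b2 = build_orthonormal_basis(x1, 2, "x2")
        with pytest.raises(ValueError, match="collinear"):
            fit_least_squares(
                t, "y", [(1, ("x1",)), (1, ("x2",))], {"x1": b1, "x2": b2}
            )


class TestFitHdmr:
    def test_f0_equals_sample_mean(self, uniform_table):
        m = fit_hdmr(uniform_table, "y")
        assert m.f0 == pytest.approx(uniform_table.values["y"].mean(), abs=1e-10)

    def test_training_residual_mean_vanishes(self, uniform_table):
        m = fit_hdmr(uniform_table, "y", FitConfig(max_order=2))
        resid = predict(m, uniform_table) - uniform_table.values["y"].to_numpy()
        assert abs(resid.mean()) < 1e-8

    def test_requires_normalized_table(self, tiny_table):
        with pytest.raises(ValueError, match="normalized"):
            fit_hdmr(tiny_table, "a")

    def test_tiny_sample_high_degree_fails(self, rng):
        df = pd.DataFrame({"a": [0.0, 0.5, 1.0], "b": [0.2, 0.9, 0.1]})
        t = normalize_unit_interval(DataTable(values=df))
        with pytest.raises(ValueError):
            fit_hdmr(t, "b", FitConfig(degree_first=3))

    def test_deterministic_serialization(self, uniform_table):
        m1 = fit_hdmr(uniform_table, "y")
        m2 = fit_hdmr(uniform_table, "y")
        assert m1.to_json() == m2.to_json()

    def test_adding_selected_component_never_raises_rss(self, uniform_table):
        """Nested refits: training RSS is non-increasing along the selection."""
        m = fit_hdmr(uniform_table, "y", FitConfig(max_order=2))
        sel = [(c.order, c.variable_ids) for c in m.components]
        y = uniform_table.values["y"].to_numpy()
        prev = np.inf
        for k in range(len(sel) + 1):
            sub = fit_least_squares(
                uniform_table, "y", sel[:k], m.bases, config=FitConfig(max_order=2)
            )
            assert sub.residual_variance <= prev + 1e-12
            prev = sub.residual_variance

    def test_model_json_round_trip(self, uniform_table):
        m = fit_hdmr(uniform_table, "y")
        back = HDMRModel.from_json(m.to_json())
        assert back.to_json() == m.to_json()
        p1 = predict(m, uniform_table)
        p2 = predict(back, uniform_table)
        assert np.allclose(p1, p2)


class TestPredict:
    def test_zero_components_predicts_f0(self, rng):
        n = 30
        t = make_unit_table({"x1": rng.uniform(0, 1, n), "y": rng.uniform(0, 1, n)})
        m = fit_least_squares(t, "y", [], _bases_for(t, ["x1"]))
        out = predict(m, t)
        assert np.allclose(out, m.f0)

    def test_matches_termwise_summation_oracle(self, uniform_table):
        m = fit_hdmr(uniform_table, "y", FitConfig(max_order=2))
        pred = predict(m, uniform_table)
        cols = {v: uniform_table.values[v].to_numpy() for v in m.input_ids}
        oracle = np.full(uniform_table.n_samples, m.f0)
        for comp in m.components:
            T = evaluate_terms(m.bases, (comp.order, comp.variable_ids, comp.degrees), cols)
            for i in range(T.shape[1]):
                oracle += comp.weights[i] * (T[:, i] - comp.term_means[i])
        assert np.allclose(pred, oracle, atol=1e-12)

    def test_out_of_range_input_clamped_with_warning(self, rng):
        n = 200
        raw = pd.DataFrame(
            {"x1": rng.uniform(10, 20, n), "y": rng.uniform(0, 5, n)}
        )
        t = normalize_unit_interval(DataTable(values=raw))
        m = fit_hdmr(t, "y", FitConfig(alpha=0.5))
        if not m.components:  # ensure the transform path is exercised regardless
            m = fit_least_squares(t, "y", [(1, ("x1",))], m.bases, config=FitConfig())
        with pytest.warns(UserWarning, match="clamped"):
            out = predict(m, pd.DataFrame({"x1": [100.0]}))
        assert np.isfinite(out).all()

    def test_missing_input_named_in_error(self, uniform_table):
        m = fit_hdmr(uniform_table, "y", FitConfig(alpha=0.5))
        needed = m.input_ids
        assert needed, "fixture signal is strong; selection must be non-empty"
        drop = needed[0]
        df = uniform_table.values.drop(columns=[drop])
        with pytest.raises(KeyError, match=drop):
            predict(m, df)
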