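"""Objective function semantics, censoring rule, bounds, and swarm fitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsulepk import DoseSchedule, FitConfig, Measurement, PKParameters
from capsulepk.fitting import (
    MOUSE_CLEARANCE_PLAUSIBLE_BOUNDS,
    InfusionScenario,
    UnitPlausibilityWarning,
    default_bounds,
    fit_infusion_ktrans,
    fit_pso,
    objective,
    read_measurements_csv,
    score_fit,
    trajectory_sup_error,
    write_measurements_csv,
)
from capsulepk.synth import (
    MOUSE_TRUE_PARAMS,
    generate_dataset,
    human_infusion_spec,
    mouse_fig_pk_spec,
)


def meas(t, comp, mu, censored=False):
    return Measurement(t=t, compartment=comp, mu=mu, below_lod=censored)


class TestScoreFit:
    def test_perfect_fit_scores_zero(self):
        assert score_fit([meas(1.0, "ip", 10.0)], [10.0]) == 0.0

    def test_printed_formula(self):
        # (10-0)^2 / (10^2 + 1^2)
        assert score_fit([meas(1.0, "ip", 10.0)], [0.0], mu0=1.0) == pytest.approx(100 / 101)

    def test_censored_point_with_sublod_prediction_is_free(self):
        assert score_fit([meas(1.0, "ip", 0.0, censored=True)], [10.0], lod=30.0) == 0.0

    def test_censored_point_with_visible_prediction_penalized(self):
        # (0-50)^2 / (0 + 1)
        s = score_fit([meas(1.0, "ip", 0.0, censored=True)], [50.0], lod=30.0, mu0=1.0)
        assert s == pytest.approx(2500.0)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            score_fit([meas(1.0, "ip", 10.0)], [1.0, 2.0])

    def test_large_concentration_weight_approaches_relative_error(self):
        # for mu >> mu0 a relative error r contributes ~ r^2
        mu, r = 1e6, 0.07
        s = score_fit([meas(1.0, "ip", mu)], [mu * (1 + r)])
        assert s == pytest.approx(r**2, rel=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.1, 30.0),
                st.sampled_from(["ip", "blood"]),
                st.floats(0.0, 1e6),
                st.floats(0.0, 1e6),
            ),
            min_size=1,
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_order_invariant_and_additive(self, rows, rnd):
        ms = [meas(t, c, mu) for t, c, mu, _ in rows]
        ps = [p for *_, p in rows]
        total = score_fit(ms, ps)
        parts = sum(score_fit([m], [p]) for m, p in zip(ms, ps))
        assert total == pytest.approx(parts, rel=1e-12, abs=1e-12)
        order = list(range(len(ms)))
        rnd.shuffle(order)
        shuffled = score_fit([ms[i] for i in order], [ps[i] for i in order])
        assert shuffled == pytest.approx(total, rel=1e-12, abs=1e-12)


class TestObjective:
    def setup_method(self):
        self.spec = mouse_fig_pk_spec(seed=0, noise_cv=0.0)
        self.data = generate_dataset(self.spec).measurements

    def test_zero_at_generating_parameters(self):
        assert objective(self.spec.true_params, self.data, self.spec.dose) < 1e-10

    @pytest.mark.parametrize("name", ["k_prod", "k_trans", "k_clr", "lambda_decay"])
    def test_increases_when_any_parameter_doubled(self, name):
        perturbed = self.spec.true_params.replace(
            **{name: 2 * getattr(self.spec.true_params, name)}
        )
        assert objective(perturbed, self.data, self.spec.dose) > 1e-4

    def test_all_censored_dataset_scores_zero_for_sublod_model(self):
        data = [meas(t, "blood", 0.0, censored=True) for t in (5.0, 10.0, 20.0)]
        # huge clearance keeps blood < LOD everywhere
        p = MOUSE_TRUE_PARAMS.replace(k_clr=1e6)
        assert objective(p, data, self.spec.dose) == 0.0

    def test_ode_predictor_agrees_with_analytic(self):
        a = objective(self.spec.true_params, self.data, self.spec.dose, predictor="analytic")
        o = objective(self.spec.true_params, self.data, self.spec.dose, predictor="ode")
        assert o == pytest.approx(a, abs=1e-6)


class TestDefaultBounds:
    def test_mouse_bounds_as_printed(self):
        with pytest.warns(UnitPlausibilityWarning):
            b = default_bounds("mouse")
        assert b.bounds["lambda_decay"] == (0.01, 10.0)
        assert b.bounds["k_prod"] == (5e3, 2e4)
        assert b.bounds["k_clr"] == (250 * 1440.0, 750 * 1440.0)

    def test_nhp_bounds(self):
        b = default_bounds("NHP")
        assert b.bounds["k_clr"] == (7200.0, 28800.0)
        assert b.bounds["k_trans"] == (0.1, 24.0)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            default_bounds("ferret")


def mouse_fit_config(seed, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnitPlausibilityWarning)
        bounds = dict(default_bounds("mouse").bounds)
    bounds["k_clr"] = MOUSE_CLEARANCE_PLAUSIBLE_BOUNDS
    kw.setdefault("swarm_size", 30)
    kw.setdefault("max_iters", 60)
    return FitConfig(bounds=bounds, fixed={"V1": 1.0, "V2": 1.2}, seed=seed, **kw)


class TestFitPso:
    def test_noiseless_recovery_on_trajectory(self):
        spec = mouse_fig_pk_spec(seed=11, noise_cv=0.0)
        ds = generate_dataset(spec)
        res = fit_pso(ds.measurements, spec.dose, mouse_fit_config(seed=3))
        assert res.objective < 1e-3
        err = trajectory_sup_error(
            spec.true_params, res.params, spec.dose, np.linspace(0.5, 30, 60)
        )
        assert err < 0.01

    def test_seeded_determinism(self):
        spec = mouse_fig_pk_spec(seed=5, noise_cv=0.2)
        ds = generate_dataset(spec)
        cfg = dict(swarm_size=12, max_iters=15, polish=False)
        a = fit_pso(ds.measurements, spec.dose, mouse_fit_config(seed=9, **cfg))
        b = fit_pso(ds.measurements, spec.dose, mouse_fit_config(seed=9, **cfg))
        assert a.params == b.params
        assert a.objective == b.objective
        assert np.array_equal(a.trace, b.trace)

    def test_result_respects_bounds_excluding_truth(self):
        spec = mouse_fig_pk_spec(seed=2, noise_cv=0.0)
        ds = generate_dataset(spec)
        cfg = mouse_fit_config(seed=1, swarm_size=15, max_iters=25)
        cfg.bounds["lambda_decay"] = (1.0, 10.0)  # excludes the true 0.45
        res = fit_pso(ds.measurements, spec.dose, cfg)
        for name, (lo, hi) in cfg.bounds.items():
            assert lo <= getattr(res.params, name) <= hi
        assert res.objective > 1e-3

    def test_objective_recomputable_and_trace_monotone(self):
        spec = mouse_fig_pk_spec(seed=8, noise_cv=0.2)
        ds = generate_dataset(spec)
        res = fit_pso(ds.measurements, spec.dose, mouse_fit_config(seed=4, swarm_size=15, max_iters=25))
        assert objective(res.params, ds.measurements, spec.dose) == pytest.approx(
            res.objective, rel=1e-9
        )
        assert np.all(np.diff(res.trace) <= 0)

    def test_no_free_parameters_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(bounds={}, fixed={})


class TestInfusionFit:
    def test_recovers_generating_transport_rate(self):
        spec = human_infusion_spec(seed=3, noise_cv=0.0)
        ds = generate_dataset(spec)
        res = fit_infusion_ktrans(
            ds.measurements, k_in=5.775e8, V1=20.0, V2=5320.0, k_clr=1.68e5
        )
        assert not res.non_identifiable
        assert res.k_trans == pytest.approx(0.7, rel=0.01)

    def test_steady_state_gradient_reproduced(self):
        # steady-state-only dataset pins C1-C2 = k_in/(k_trans*V1)
        k_in, kt = 5.775e8, 0.7
        c2 = k_in / 1.68e5
        c1 = c2 + k_in / (kt * 20.0)
        data = [meas(60.0, "ip", c1), meas(60.0, "blood", c2)]
        res = fit_infusion_ktrans(data, k_in=k_in, V1=20.0, V2=5320.0, k_clr=1.68e5)
        assert res.k_trans == pytest.approx(kt, rel=1e-3)

    def test_zero_infusion_flat_objective_flagged(self):
        data = [meas(t, "ip", 0.0, censored=True) for t in (1.0, 5.0, 10.0)]
        res = fit_infusion_ktrans(data, k_in=0.0, V1=20.0, V2=5320.0, k_clr=1.68e5)
        assert res.non_identifiable

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_infusion_ktrans([], k_in=1.0, V1=20.0, V2=5320.0, k_clr=1.68e5)


def test_measurements_csv_roundtrip(tmp_path):
    ms = [meas(1.0, "ip", 100.0), meas(4.0, "blood", 0.0, censored=True)]
    path = tmp_path / "m.csv"
    write_measurements_csv(ms, path)
    header = path.read_text().splitlines()[0]
    assert header == "time_days,compartment,concentration_pg_per_ml,below_lod,replicate_id"
    assert read_measurements_csv(path) == ms
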