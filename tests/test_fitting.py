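import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from essclock.fitting import (
    FitConfig,
    FlatComponentError,
    SSystemFit,
    infer_regulation_signs,
    nmad,
    summarise_variability,
    wmse_component,
    wmse_components,
    wmse_total,
)
from essclock.light import LightProtocol
from essclock.model import (
    DegradationProcess,
    ESSModel,
    ProductionProcess,
    Species,
    SpeciesDynamics,
)
from essclock.simulate import Timeseries
from essclock.synthetic import TRAINING_PROTOCOL


class TestWMSE:
    def test_zero_for_identical(self):
        x = np.array([1.0, 2.0, 3.0])
        assert wmse_component(x, x) == 0.0

    def test_hand_example(self):
        # target (2,4) vs simulated (4,4): A = 4, W_i = ((-2/4)^2 + 0)/2
        assert wmse_component(np.array([2.0, 4.0]), np.array([4.0, 4.0])) == pytest.approx(0.125)

    def test_unit_normalised_offset(self):
        target = np.array([1.0, 3.0, 2.0])
        assert wmse_component(target, target + target.max()) == pytest.approx(1.0)

    def test_flat_zero_target_rejected(self):
        with pytest.raises(FlatComponentError):
            wmse_component(np.zeros(4), np.ones(4))

    def test_total_is_mean_of_components(self):
        t = np.array([0.0, 1.0, 2.0])
        a = Timeseries(t, np.column_stack([[2, 4, 4], [1, 1, 1]]), ["A", "B"])
        b = Timeseries(t, np.column_stack([[4, 4, 4], [1, 1, 2]]), ["A", "B"])
        comps = wmse_components(a, b)
        w_a = wmse_component(a.component("A"), b.component("A"))
        w_b = wmse_component(a.component("B"), b.component("B"))
        assert wmse_total(a, b) == pytest.approx((w_a + w_b) / 2)

    def test_component_mismatch_rejected(self):
        t = np.array([0.0, 1.0])
        a = Timeseries(t, np.ones((2, 1)), ["A"])
        b = Timeseries(t, np.ones((2, 1)), ["B"])
        with pytest.raises(ValueError, match="component mismatch"):
            wmse_components(a, b)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None)
    def test_invariant_to_joint_component_rescaling(self, scale):
        target = np.array([1.0, 3.0, 2.0, 0.5])
        sim = np.array([1.2, 2.7, 2.2, 0.4])
        assert wmse_component(scale * target, scale * sim) == pytest.approx(
            wmse_component(target, sim), rel=1e-12
        )

    def test_invariant_to_component_order(self):
        t = np.array([0.0, 1.0, 2.0])
        vals_a = np.column_stack([[2, 4, 4.0], [1, 2, 3.0]])
        vals_b = np.column_stack([[4, 4, 4.0], [1, 2, 4.0]])
        fwd = wmse_total(Timeseries(t, vals_a, ["A", "B"]), Timeseries(t, vals_b, ["A", "B"]))
        rev = wmse_total(
            Timeseries(t, vals_a[:, ::-1], ["B", "A"]), Timeseries(t, vals_b[:, ::-1], ["B", "A"])
        )
        assert fwd == pytest.approx(rev, rel=1e-14)


class TestNMAD:
    def test_identical_runs_give_zero(self):
        runs = np.tile([0.4, -1.2, 3.3], (6, 1))
        var = summarise_variability(["a", "b", "c"], runs, np.zeros(6))
        np.testing.assert_array_equal(var.nmad_values, 0.0)
        assert not var.degenerate.any()

    def test_hand_example(self):
        # optima {1,2,3}: median 2, |dev| = {1,0,1}, median 1 -> nMAD = 0.5
        assert nmad([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_zero_median_flagged(self):
        var = summarise_variability(["a"], np.array([[-1.0], [0.0], [1.0]]), np.zeros(3))
        assert var.degenerate[0]
        assert np.isnan(var.nmad_values[0])


class TestRegulationSigns:
    def test_sign_rule(self):
        species = [Species(1, "G"), Species(2, "P", "protein_aggregate")]
        for g, expected in [(0.7, "activator"), (-1.2, "inhibitor"), (0.0, "indeterminate")]:
            dyn = SpeciesDynamics(alpha=1.0, production=[ProductionProcess((2,), g)])
            model = ESSModel(species, [dyn, SpeciesDynamics()])
            assert infer_regulation_signs(model)["P->G"] == expected


def tiny_fit_problem():
    """One-species relaxation to a light-driven level: fast, two free parameters."""
    species = [Species(1, "X")]
    dyn = SpeciesDynamics(
        alpha=0.8,
        alpha_free=True,
        production=[ProductionProcess((1,), 0.0, exponent_free=False)],
        degradation=[DegradationProcess(rate=0.4, rate_free=True)],
    )
    model = ESSModel(species, [dyn])
    proto = LightProtocol(photoperiod=12.0, entrainment_cycles=1, release_regime="LL")
    from essclock.simulate import entrain_and_release

    data = entrain_and_release(model, proto, 12.0, 24.0, 2.0)
    return model, data, proto


class TestFit:
    def test_truth_start_is_fixed_point(self):
        model, data, proto = tiny_fit_problem()
        fitter = SSystemFit(model, data, proto, FitConfig(seed=0))
        res = fitter.fit()
        assert res.wmse <= fitter.loss(model.pack_parameters().values) + 1e-12
        assert res.converged

    def test_recovers_perturbed_parameters(self):
        model, data, proto = tiny_fit_problem()
        fitter = SSystemFit(model, data, proto, FitConfig(seed=0))
        truth = model.pack_parameters().values
        res = fitter.fit(start=truth * [1.3, 0.8])
        assert res.wmse < 1e-8
        np.testing.assert_allclose(res.params.values, truth, rtol=1e-2)

    def test_seeded_determinism(self):
        model, data, proto = tiny_fit_problem()
        start = model.pack_parameters().values * 1.2
        r1 = SSystemFit(model, data, proto, FitConfig(seed=7)).fit(start=start)
        r2 = SSystemFit(model, data, proto, FitConfig(seed=7)).fit(start=start)
        np.testing.assert_array_equal(r1.params.values, r2.params.values)

    def test_never_worse_than_incumbent(self):
        model, data, proto = tiny_fit_problem()
        fitter = SSystemFit(model, data, proto, FitConfig(seed=0))
        start = model.pack_parameters().values * 1.5
        res = fitter.fit(start=start)
        assert res.wmse <= fitter.loss(start)

    def test_summary_mentions_wmse_and_parameters(self):
        model, data, proto = tiny_fit_problem()
        res = SSystemFit(model, data, proto).fit()
        text = res.summary()
        assert "total WMSE" in text and "alpha[X]" in text

    def test_variability_analysis_feasible_draws(self):
        model, data, proto = tiny_fit_problem()
        fitter = SSystemFit(model, data, proto, FitConfig(seed=3))
        var = fitter.variability_analysis(n_runs=3, seed=3)
        assert var.runs.shape == (3, 2)
        assert np.all(var.runs[:, 0] >= 0)  # alpha stayed feasible in every run
        assert np.all(np.isfinite(var.nmad_values))

    def test_constrain_signs_noop_when_correct(self):
        model, data, proto = tiny_fit_problem()
        fitter = SSystemFit(model, data, proto, FitConfig(seed=0))
        res = fitter.fit()
        again = fitter.constrain_signs_and_refit(res, {})
        assert again.wmse <= res.wmse + 1e-15
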