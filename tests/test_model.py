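import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from essclock.model import (
    DegradationProcess,
    ESSModel,
    LightProcess,
    ModelConfigError,
    NotReducibleError,
    ProductionProcess,
    Species,
    SpeciesDynamics,
    build_model,
)


def single_gene_model(alpha=1.0, g=1.0, beta=0.0, regulator_value=None):
    """Two-species transcription template: one regulator, power-law activation."""
    species = [Species(1, "G"), Species(2, "P", "protein_aggregate")]
    dyn_g = SpeciesDynamics(
        alpha=alpha,
        alpha_free=True,
        production=[ProductionProcess(members=(2,), exponent=g)],
        degradation=[DegradationProcess(rate=beta)],
    )
    return ESSModel(species, [dyn_g, SpeciesDynamics()])


class TestBuildAndEvaluate:
    def test_empty_system_has_zero_derivative(self):
        model = build_model({"species": [{"name": "X"}]})
        assert model.rhs([3.7], 1.0) == pytest.approx([0.0])

    def test_single_regulator_transcription_structure(self):
        model = build_model(
            {
                "species": [{"name": "G"}, {"name": "P", "role": "protein_aggregate"}],
                "dynamics": {
                    "G": {
                        "alpha": {"value": 1.0, "free": True},
                        "production": [{"members": ["P"], "exponent": 0.5}],
                        "degradation": [{"rate": 0.2}],
                    }
                },
            }
        )
        dyn = model.dynamics[0]
        assert len(dyn.production) == 1
        assert len(dyn.degradation) == 1
        assert len(dyn.light) == 0

    def test_null_rates_give_zero_vector(self):
        model = single_gene_model(alpha=0.0, beta=0.0)
        assert np.allclose(model.rhs([4.0, 2.0], 1.0), 0.0)

    def test_hand_evaluated_power_law_balance(self):
        # dX/dt = 2 * X^0.5 - 1 * X at X = 4 -> 0
        species = [Species(1, "X")]
        dyn = SpeciesDynamics(
            alpha=2.0,
            production=[ProductionProcess(members=(1,), exponent=0.5)],
            degradation=[DegradationProcess(rate=1.0)],
        )
        model = ESSModel(species, [dyn])
        assert model.rhs([4.0], 0.0)[0] == pytest.approx(0.0, abs=1e-14)

    def test_negative_exponent_models_inhibition(self):
        model = single_gene_model(alpha=1.0, g=-1.0, beta=0.0)
        assert model.rhs([1.0, 2.0], 0.0)[0] == pytest.approx(0.5)

    def test_summed_membership_uses_group_total(self):
        species = [Species(1, "A"), Species(2, "B"), Species(3, "C")]
        dyn_a = SpeciesDynamics(
            alpha=1.0, production=[ProductionProcess(members=(2, 3), exponent=2.0)]
        )
        model = ESSModel(species, [dyn_a, SpeciesDynamics(), SpeciesDynamics()])
        assert model.rhs([1.0, 1.5, 0.5], 0.0)[0] == pytest.approx(4.0)

    def test_light_monomial_with_species_power(self):
        species = [Species(1, "X")]
        dyn = SpeciesDynamics(light=[LightProcess(gain=0.5, light=True, powers={1: 2})])
        model = ESSModel(species, [dyn])
        assert model.rhs([3.0], 1.0)[0] == pytest.approx(4.5)
        assert model.rhs([3.0], 0.0)[0] == pytest.approx(0.0)

    def test_config_errors(self):
        with pytest.raises(ModelConfigError):
            build_model(
                {
                    "species": [{"name": "G"}],
                    "dynamics": {"G": {"production": [{"members": ["Q"], "exponent": 1.0}]}},
                }
            )
        with pytest.raises(ModelConfigError):
            ProductionProcess(members=(), exponent=1.0)
        with pytest.raises(ModelConfigError):
            LightProcess(gain=1.0, powers={1: 3})


class TestSignAndStabilisationSemantics:
    @pytest.mark.parametrize("g", [0.7, -1.2])
    def test_production_monotone_in_regulator(self, g):
        model = single_gene_model(alpha=1.0, g=g)
        levels = np.linspace(0.2, 5.0, 20)
        prods = [model.rhs([1.0, p], 0.0)[0] for p in levels]
        diffs = np.diff(prods)
        assert np.all(diffs > 0) if g > 0 else np.all(diffs < 0)

    def test_negative_beta_stabilises(self, rng):
        species = [Species(1, "X"), Species(2, "Y", "protein_aggregate")]
        for _ in range(10):
            state = rng.uniform(0.1, 5.0, 2)
            h = rng.uniform(-1, 1)
            deg = DegradationProcess(rate=0.7, exponents={2: h})
            stab = DegradationProcess(rate=-0.7, exponents={2: h})
            m_deg = ESSModel(species, [SpeciesDynamics(degradation=[deg]), SpeciesDynamics()])
            m_stab = ESSModel(species, [SpeciesDynamics(degradation=[stab]), SpeciesDynamics()])
            assert m_stab.rhs(state, 0.0)[0] >= m_deg.rhs(state, 0.0)[0]


class TestParameterPacking:
    def test_round_trip_identity(self, ess_fixture):
        model, theta = ess_fixture
        again = model.unpack_parameters(theta).pack_parameters()
        assert again.names == theta.names
        np.testing.assert_array_equal(again.values, theta.values)

    def test_k_theta_matches_fixture_mask(self, ess_fixture):
        model, theta = ess_fixture
        assert model.k_theta == 12
        assert len(theta) == 12

    def test_masked_parameters_untouched(self, ess_fixture):
        model, theta = ess_fixture
        new = model.unpack_parameters(theta.values * 2.0)
        # the fixed G2->P2 translation exponent stays at 1
        assert new.dynamics[3].production[0].exponent == 1.0

    def test_wrong_length_rejected(self, ess_fixture):
        model, _ = ess_fixture
        with pytest.raises(ValueError):
            model.unpack_parameters(np.zeros(model.k_theta + 1))


def random_reducible_model(rng, n=3):
    """Random classical-form model in the extended representation, plus its
    independent direct evaluator (the oracle)."""
    alpha = rng.uniform(0.1, 2.0, n)
    beta = rng.uniform(0.1, 2.0, n)
    g = rng.uniform(-1.5, 1.5, (n, n))
    h = rng.uniform(-1.5, 1.5, (n, n))
    species = [Species(i + 1, f"X{i + 1}") for i in range(n)]
    dynamics = []
    for i in range(n):
        production = [ProductionProcess(members=(j + 1,), exponent=g[i, j]) for j in range(n)]
        exponents = {j + 1: h[i, j] - (1.0 if i == j else 0.0) for j in range(n)}
        dynamics.append(
            SpeciesDynamics(
                alpha=alpha[i],
                production=production,
                degradation=[DegradationProcess(rate=beta[i], exponents=exponents)],
            )
        )
    model = ESSModel(species, dynamics)

    def oracle(x):
        x = np.asarray(x, dtype=float)
        return alpha * np.prod(x[None, :] ** g, axis=1) - beta * np.prod(x[None, :] ** h, axis=1)

    return model, oracle


class TestReduction:
    def test_reducible_model_matches_classical_oracle(self, rng):
        worst = 0.0
        for _ in range(20):
            model, oracle = random_reducible_model(rng)
            reduced = model.reduce_to_original()
            for _ in range(20):
                x = rng.uniform(0.2, 3.0, 3)
                expect = oracle(x)
                scale = np.maximum(np.abs(expect), 1.0)
                worst = max(worst, np.max(np.abs(model.rhs(x, 0.0) - expect) / scale))
                worst = max(worst, np.max(np.abs(reduced.rhs(x) - expect) / scale))
        assert worst < 1e-10

    def test_light_term_blocks_reduction(self):
        species = [Species(1, "X")]
        dyn = SpeciesDynamics(
            degradation=[DegradationProcess(rate=1.0)],
            light=[LightProcess(gain=0.1)],
        )
        with pytest.raises(NotReducibleError, match="light"):
            ESSModel(species, [dyn]).reduce_to_original()

    def test_grouped_membership_blocks_reduction(self):
        species = [Species(1, "X"), Species(2, "Y")]
        dyn = SpeciesDynamics(
            alpha=1.0,
            production=[ProductionProcess(members=(1, 2), exponent=1.0)],
            degradation=[DegradationProcess(rate=1.0)],
        )
        with pytest.raises(NotReducibleError, match="membership"):
            ESSModel(species, [dyn, SpeciesDynamics(degradation=[DegradationProcess(rate=1.0)])]).reduce_to_original()

    def test_identity_exponents_balance(self):
        # alpha = beta with g = h = 0 gives dX/dt = alpha - beta = 0 everywhere
        species = [Species(1, "X")]
        dyn = SpeciesDynamics(
            alpha=1.3,
            production=[ProductionProcess(members=(1,), exponent=0.0)],
            degradation=[DegradationProcess(rate=1.3, exponents={1: -1.0})],
        )
        model = ESSModel(species, [dyn])
        for x in (0.3, 1.0, 7.5):
            assert model.rhs([x], 0.0)[0] == pytest.approx(0.0, abs=1e-12)


@given(st.floats(min_value=0.05, max_value=5.0), st.integers(min_value=1, max_value=6))
@settings(deadline=None, max_examples=50)
def test_power_law_base_floor_keeps_rhs_finite(x, n_hill):
    model = single_gene_model(alpha=1.0, g=-float(n_hill))
    value = model.rhs([x, 0.0], 0.0)[0]  # regulator at zero hits the EPS floor
    assert np.isfinite(value) and value > 0
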