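"""Bundled two-gene reference circuits and dataset generation.

Two frozen fixtures emulate the study workflow at desk scale:

* ``mm_two_gene`` — a Michaelis-Menten circuit: gene 1 is Hill-activated by
  protein 2 and light-driven at dawn, its protein shuttles between cytoplasm
  and nucleus, the nuclear form Hill-inhibits gene 2, whose protein is an
  aggregated single equation.  The closed loop is a delayed negative
  feedback oscillator entrained by the light-dark cycle.
* ``ess_two_gene`` — the extended S-System mirror of the same circuit with
  aggregated proteins: one positive regulatory kinetic order (P2 activates
  G1), one negative (P1 inhibits G2), a single additive light term on gene 1,
  and 12 free parameters.

Both produce a training set (12L:12D entrainment released into constant
light) and a validation set (released into constant dark) on a 24 h
pre-release + 72 h post-release grid at 1 h sampling (97 points).  Data are
noiseless by default; optional multiplicative Gaussian observation noise is
seeded.

Parameter values are implementation-frozen to give entrained 24 h rhythms
with a free-running period in the low-to-mid 20s of hours; see
``ESS_REFERENCE_SHEET`` for a hand-checked derivative evaluation at a
reference state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .light import LightProtocol
from .mm import MMBlock, MMModel
from .model import ESSModel, ParameterVector, load_model
from .simulate import Timeseries, entrain_and_release

ENTRAINMENT_CYCLES = 4
RECORD_BEFORE_H = 24.0
RECORD_AFTER_H = 72.0
SAMPLING_H = 1.0

TRAINING_PROTOCOL = LightProtocol(
    photoperiod=12.0, entrainment_cycles=ENTRAINMENT_CYCLES, release_regime="LL"
)
VALIDATION_PROTOCOL = LightProtocol(
    photoperiod=12.0, entrainment_cycles=ENTRAINMENT_CYCLES, release_regime="DD"
)


@dataclass(frozen=True)
class FixtureSpec:
    """Which circuit to sample, on what grid, with how much observation noise."""

    circuit: str = "ess_two_gene"  # "ess_two_gene" | "mm_two_gene"
    noise_sd: float = 0.0  # relative (multiplicative) Gaussian noise
    record_hours_before: float = RECORD_BEFORE_H
    record_hours_after: float = RECORD_AFTER_H
    sampling_interval: float = SAMPLING_H
    training_protocol: LightProtocol = TRAINING_PROTOCOL
    validation_protocol: LightProtocol = VALIDATION_PROTOCOL

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.circuit not in ("ess_two_gene", "mm_two_gene"):
            raise ValueError(f"unknown circuit {self.circuit!r}")


def _config_path(name: str):
    return resources.files("essclock.configs") / name


def build_ess_two_gene() -> tuple[ESSModel, ParameterVector]:
    """The extended S-System fixture and its ground-truth free parameters."""
    model = load_model(_config_path("ess_two_gene.yaml"))
    return model, model.pack_parameters(provenance="initial")


# ground-truth regulation-sign table of the ESS fixture, by construction
ESS_SIGN_TABLE = {"P2->G1": "activator", "P1->G2": "inhibitor"}

# Hand-evaluated derivative of the ESS fixture at the reference state
# X = (G1, P1, G2, P2) = (1.2, 0.8, 1.5, 0.6) in darkness (L = 0) and in
# light (L = 1); values checked against the term-by-term arithmetic in
# tests.  Entries are (state, light, expected dX/dt).
ESS_REFERENCE_SHEET = {
    "state": (1.2, 0.8, 1.5, 0.6),
    "dark": (
        0.25 * 0.6**2.0 - 0.30 * 1.2,
        0.30 * 1.2**1.0 - 0.25 * 0.8,
        0.25 * 0.8**-2.5 - 0.30 * 1.5,
        0.30 * 1.5**1.0 - 0.25 * 0.6,
    ),
    "light_extra_on_G1": 0.08,  # gamma * L with L = 1
}


def build_mm_two_gene() -> MMModel:
    """The Michaelis-Menten reference circuit with frozen parameters."""
    species = ["G1", "P1C", "P1N", "G2", "P2"]
    blocks = [
        MMBlock(
            "hill_activation",
            {"a": 0.92, "K": 1.0, "n": 2.0, "b": 0.35},
            {"target": "G1", "regulator": "P2"},
        ),
        MMBlock("light_drive", {"gain": 0.14}, {"target": "G1"}),
        MMBlock(
            "shuttling_pair",
            {"a": 0.52, "r_C": 0.46, "r_N": 0.12, "b_C": 0.23, "b_N": 0.29},
            {"gene": "G1", "cytoplasmic": "P1C", "nuclear": "P1N"},
        ),
        MMBlock(
            "hill_inhibition",
            {"a": 1.04, "K": 0.8, "n": 3.0, "b": 0.35},
            {"target": "G2", "regulator": "P1N"},
        ),
        MMBlock("aggregated_protein", {"a": 0.40, "b": 0.29}, {"gene": "G2", "protein": "P2"}),
    ]
    return MMModel(species, blocks)


# map from MM fixture species to the aggregated 4-component view used when
# the ESS fixture is fitted across formalisms (nuclear protein is the active
# transcription-factor pool)
MM_TO_ESS_COMPONENTS = {"G1": "G1", "P1N": "P1", "G2": "G2", "P2": "P2"}


def aggregate_mm_timeseries(ts: Timeseries) -> Timeseries:
    """Project an MM fixture trajectory onto the ESS fixture's components."""
    cols = [ts.labels.index(src) for src in MM_TO_ESS_COMPONENTS]
    return Timeseries(
        ts.time,
        ts.values[:, cols],
        list(MM_TO_ESS_COMPONENTS.values()),
        ts.protocol,
        ts.light,
    )


def generate_datasets(model, spec: FixtureSpec | None = None, seed: int | None = None) -> dict[str, Timeseries]:
    """Training (LD->LL) and validation (LD->DD) sets from a source model."""
    spec = spec or FixtureSpec()
    out: dict[str, Timeseries] = {}
    rng = np.random.default_rng(seed)
    for name, protocol in (
        ("training", spec.training_protocol),
        ("validation", spec.validation_protocol),
    ):
        ts = entrain_and_release(
            model,
            protocol,
            record_hours_before=spec.record_hours_before,
            record_hours_after=spec.record_hours_after,
            sampling_interval=spec.sampling_interval,
        )
        if spec.noise_sd > 0:
            noisy = ts.values * (1.0 + spec.noise_sd * rng.standard_normal(ts.values.shape))
            ts = Timeseries(ts.time, np.maximum(noisy, 0.0), list(ts.labels), ts.protocol, ts.light)
        out[name] = ts
    return out
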