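"""Extended S-System models of gene regulatory networks.

Each state X_i (an mRNA, protein or complex concentration) evolves as

    dX_i/dt =   alpha_i * prod_j ( sum_k b_{ijk} X_k )^{g_{ij}}      production
              - sum_j beta_{ij} X_i prod_k X_k^{h_{ijk}}             degradation
              + sum_j gamma_{ij} U_{ij}                              light input

where the b_{ijk} are Boolean membership flags grouping species inside a
power-law base, the kinetic orders g and h are real-valued (the sign of a
production exponent encodes activation vs inhibition), beta may be negative
(stabilisation), and each U_{ij} is a low-order monomial in the state
optionally multiplied by the external light signal L(t).

Setting one production process per species with singleton membership, a
single bare degradation term and no light processes recovers the classical
S-System form

    dX_i/dt = alpha_i * prod_j X_j^{g_{ij}} - beta_i * prod_j X_j^{h_{ij}},

and :meth:`ESSModel.reduce_to_original` returns an evaluator of that form
(or explains which structural condition fails).

Power-law bases are clamped to ``EPS = 1e-9`` before exponentiation so that
negative kinetic orders never divide by zero when an integrator undershoots.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

EPS = 1e-9

ROLES = ("mRNA", "protein_cytoplasmic", "protein_nuclear", "protein_aggregate", "complex")


class ModelConfigError(ValueError):
    """Raised for structurally invalid model configurations."""


class NotReducibleError(ValueError):
    """Raised when a model cannot be expressed in the original S-System form."""


@dataclass(frozen=True)
class Species:
    index: int  # 1-based
    name: str
    role: str = "mRNA"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelConfigError(f"unknown species role {self.role!r}")


@dataclass
class ProductionProcess:
    """One power-law production factor: (sum of member species)^exponent."""

    members: tuple[int, ...]  # 1-based species indices with b_{ijk} = 1
    exponent: float
    exponent_free: bool = True

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ModelConfigError("production process needs at least one member species")
        if not math.isfinite(self.exponent):
            raise ModelConfigError("production exponent must be finite")


@dataclass
class DegradationProcess:
    """One degradation/stabilisation term: rate * X_i * prod_k X_k^{h_k}.

    A negative rate represents stabilisation.
    """

    rate: float
    exponents: dict[int, float] = field(default_factory=dict)  # species index -> h
    rate_free: bool = True
    free_exponents: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate):
            raise ModelConfigError("degradation rate must be finite")
        for k, h in self.exponents.items():
            if not math.isfinite(h):
                raise ModelConfigError(f"degradation exponent for species {k} must be finite")
        unknown = set(self.free_exponents) - set(self.exponents)
        if unknown:
            raise ModelConfigError(f"free_exponents refer to absent exponents: {sorted(unknown)}")


@dataclass
class LightProcess:
    """One additive light-regulated monomial: gain * [L(t)] * prod_k X_k^{p_k}.

    Total polynomial order (sum of the integer species powers) is capped at 2;
    the light signal itself carries no exponent.
    """

    gain: float
    light: bool = True
    powers: dict[int, int] = field(default_factory=dict)  # species index -> power
    gain_free: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.gain):
            raise ModelConfigError("light gain must be finite")
        for k, p in self.powers.items():
            if not isinstance(p, int) or p < 0:
                raise ModelConfigError("light monomial powers must be non-negative integers")
        if sum(self.powers.values()) > 2:
            raise ModelConfigError("light monomial order exceeds 2")


@dataclass
class SpeciesDynamics:
    """All processes governing one species."""

    alpha: float = 0.0
    alpha_free: bool = False
    production: list[ProductionProcess] = field(default_factory=list)
    degradation: list[DegradationProcess] = field(default_factory=list)
    light: list[LightProcess] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ModelConfigError("production rate constant alpha must be >= 0")


@dataclass(frozen=True)
class ParameterVector:
    """Ordered free-parameter values of one model, pack/unpack-compatible."""

    names: tuple[str, ...]
    values: np.ndarray
    provenance: str = "initial"  # "initial" | "optimised"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")

    def __len__(self) -> int:
        return self.values.size

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


class ESSModel:
    """A fully parameterised extended S-System."""

    def __init__(self, species: list[Species], dynamics: list[SpeciesDynamics]):
        if len(species) != len(dynamics):
            raise ModelConfigError("species and dynamics lists must have equal length")
        indices = [s.index for s in species]
        if indices != list(range(1, len(species) + 1)):
            raise ModelConfigError("species indices must be contiguous 1..n")
        if len({s.name for s in species}) != len(species):
            raise ModelConfigError("species names must be unique")
        self.species = list(species)
        self.dynamics = list(dynamics)
        n = len(species)
        for dyn in dynamics:
            for proc in dyn.production:
                self._check_refs(proc.members, n)
            for proc in dyn.degradation:
                self._check_refs(proc.exponents, n)
            for proc in dyn.light:
                self._check_refs(proc.powers, n)
        self._plan = None

    @staticmethod
    def _check_refs(refs, n: int) -> None:
        for k in refs:
            if not 1 <= k <= n:
                raise ModelConfigError(f"reference to unknown species index {k}")

    # -- basic introspection ------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def index_of(self, name: str) -> int:
        """1-based index of a species by name."""
        for s in self.species:
            if s.name == name:
                return s.index
        raise KeyError(f"unknown species {name!r}")

    def copy(self) -> "ESSModel":
        return copy.deepcopy(self)

    # -- free-parameter mask ------------------------------------------------

    def _parameter_slots(self):
        """Yield (name, getter, setter) for every free parameter, in a fixed order."""
        for s, dyn in zip(self.species, self.dynamics):
            if dyn.alpha_free:
                yield (f"alpha[{s.name}]", dyn, "alpha")
            for j, proc in enumerate(dyn.production):
                if proc.exponent_free:
                    base = "+".join(self.species[k - 1].name for k in proc.members)
                    yield (f"g[{s.name};{base}]", proc, "exponent")
            for j, proc in enumerate(dyn.degradation):
                if proc.rate_free:
                    yield (f"beta[{s.name};{j + 1}]", proc, "rate")
                for k in proc.free_exponents:
                    yield (f"h[{s.name};{j + 1};{self.species[k - 1].name}]", (proc, k), None)
            for j, proc in enumerate(dyn.light):
                if proc.gain_free:
                    yield (f"gamma[{s.name};{j + 1}]", proc, "gain")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self._parameter_slots())

    @property
    def k_theta(self) -> int:
        """Number of free (optimised) parameters."""
        return len(self.parameter_names)

    def pack_parameters(self, provenance: str = "initial") -> ParameterVector:
        values = []
        for _, obj, attr in self._parameter_slots():
            if attr is None:
                proc, k = obj
                values.append(proc.exponents[k])
            else:
                values.append(getattr(obj, attr))
        return ParameterVector(self.parameter_names, np.array(values), provenance)

    def unpack_parameters(self, theta) -> "ESSModel":
        """Return a copy of the model with free parameters set from ``theta``."""
        values = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta, dtype=float)
        if values.size != self.k_theta:
            raise ValueError(f"parameter vector length {values.size} != K_Theta {self.k_theta}")
        new = self.copy()
        for value, (_, obj, attr) in zip(values, new._parameter_slots()):
            if attr is None:
                proc, k = obj
                proc.exponents[k] = float(value)
            else:
                setattr(obj, attr, float(value))
        new._plan = None
        return new

    # -- evaluation ---------------------------------------------------------

    def _compile(self):
        """Flatten the process structure into plain tuples for a fast rhs.

        States are tiny (a handful of species), where attribute chasing and
        numpy per-call overhead dominate; plain Python floats are ~10x faster
        inside solve_ivp here.
        """
        plan = []
        for dyn in self.dynamics:
            prod = tuple(
                (tuple(k - 1 for k in p.members), p.exponent) for p in dyn.production
            )
            deg = tuple(
                (p.rate, tuple((k - 1, h) for k, h in p.exponents.items()))
                for p in dyn.degradation
            )
            lig = tuple(
                (p.gain, p.light, tuple((k - 1, pw) for k, pw in p.powers.items() if pw))
                for p in dyn.light
            )
            plan.append((dyn.alpha, prod, deg, lig))
        self._plan = tuple(plan)
        return self._plan

    def rhs(self, state, light_value: float) -> np.ndarray:
        """Time derivative (per hour) at ``state`` under light level ``light_value``."""
        plan = self._plan or self._compile()
        x = [xi if xi > EPS else EPS for xi in state]
        out = np.empty(len(plan))
        for i, (alpha, prod, deg, lig) in enumerate(plan):
            term = alpha
            for members, g in prod:
                base = 0.0
                for k in members:
                    base += x[k]
                if base < EPS:
                    base = EPS
                term *= base ** g
            for rate, hs in deg:
                d = rate * x[i]
                for k, h in hs:
                    d *= x[k] ** h
                term -= d
            for gain, uses_light, pws in lig:
                u = gain
                if uses_light:
                    u *= light_value
                for k, p in pws:
                    u *= x[k] ** p
                term += u
            if not math.isfinite(term):
                raise FloatingPointError(
                    f"non-finite derivative for species {self.species[i].name}; "
                    "ill-conditioned parameters"
                )
            out[i] = term
        return out

    # -- reduction to the original S-System ----------------------------------

    def reduce_to_original(self) -> "OriginalSSystem":
        """Express the model in the classical form, or raise NotReducibleError.

        Requires, per species: singleton production memberships covering each
        species at most once, exactly one degradation process, and no light
        processes.
        """
        n = self.n
        alpha = np.zeros(n)
        beta = np.zeros(n)
        g = np.zeros((n, n))
        h = np.zeros((n, n))
        for i, (s, dyn) in enumerate(zip(self.species, self.dynamics)):
            if dyn.light:
                raise NotReducibleError(f"{s.name}: light processes present (n_i^L != 0)")
            if len(dyn.degradation) != 1:
                raise NotReducibleError(
                    f"{s.name}: expected exactly one degradation process, "
                    f"found {len(dyn.degradation)}"
                )
            seen = set()
            for proc in dyn.production:
                if len(proc.members) != 1:
                    raise NotReducibleError(
                        f"{s.name}: production membership is not a single species "
                        "(b_ijk not diagonal)"
                    )
                (k,) = proc.members
                if k in seen:
                    raise NotReducibleError(f"{s.name}: species {k} appears in two production processes")
                seen.add(k)
                g[i, k - 1] = proc.exponent
            alpha[i] = dyn.alpha
            proc = dyn.degradation[0]
            beta[i] = proc.rate
            for k, hk in proc.exponents.items():
                h[i, k - 1] = hk
            h[i, i] += 1.0  # the explicit X_i factor of the extended degradation term
        return OriginalSSystem(alpha, g, beta, h, self.species_names)

    def __repr__(self) -> str:
        return (
            f"ESSModel(n={self.n}, species={self.species_names}, "
            f"K_Theta={self.k_theta})"
        )


@dataclass
class OriginalSSystem:
    """Classical S-System evaluator: alpha_i prod X^g - beta_i prod X^h."""

    alpha: np.ndarray
    g: np.ndarray
    beta: np.ndarray
    h: np.ndarray
    names: list[str]

    def rhs(self, state) -> np.ndarray:
        x = np.maximum(np.asarray(state, dtype=float), EPS)
        prod = self.alpha * np.prod(x[None, :] ** self.g, axis=1)
        deg = self.beta * np.prod(x[None, :] ** self.h, axis=1)
        return prod - deg


# -- declarative configuration ------------------------------------------------


def build_model(config: dict) -> ESSModel:
    """Construct an :class:`ESSModel` from a declarative circuit description.

    Schema (YAML/JSON-compatible)::

        species:
          - {name: G1, role: mRNA}
          - {name: P1, role: protein_aggregate}
        dynamics:
          G1:
            alpha: {value: 0.25, free: true}
            production:
              - {members: [P1], exponent: 2.0, free: true}
            degradation:
              - {rate: 0.25, exponents: {}, free: true, free_exponents: []}
            light:
              - {gain: 0.05, light: true, powers: {}, free: true}

    Species must be declared before being referenced; all coefficients and
    exponents are decimal literals.
    """
    try:
        species_cfg = config["species"]
    except (KeyError, TypeError):
        raise ModelConfigError("config must contain a 'species' list")
    species = []
    for i, sc in enumerate(species_cfg, start=1):
        species.append(Species(index=i, name=str(sc["name"]), role=sc.get("role", "mRNA")))
    name_to_index = {s.name: s.index for s in species}

    def resolve(name) -> int:
        try:
            return name_to_index[name]
        except KeyError:
            raise ModelConfigError(f"reference to undeclared species {name!r}")

    dynamics = []
    dyn_cfg = config.get("dynamics", {})
    unknown = set(dyn_cfg) - set(name_to_index)
    if unknown:
        raise ModelConfigError(f"dynamics for undeclared species: {sorted(unknown)}")
    for s in species:
        block = dyn_cfg.get(s.name, {}) or {}
        alpha_block = block.get("alpha", {"value": 0.0, "free": False})
        if isinstance(alpha_block, (int, float)):
            alpha_block = {"value": float(alpha_block), "free": False}
        production = [
            ProductionProcess(
                members=tuple(resolve(m) for m in p["members"]),
                exponent=float(p["exponent"]),
                exponent_free=bool(p.get("free", True)),
            )
            for p in block.get("production", [])
        ]
        degradation = [
            DegradationProcess(
                rate=float(p["rate"]),
                exponents={resolve(k): float(v) for k, v in (p.get("exponents") or {}).items()},
                rate_free=bool(p.get("free", True)),
                free_exponents=tuple(resolve(k) for k in p.get("free_exponents", [])),
            )
            for p in block.get("degradation", [])
        ]
        light = [
            LightProcess(
                gain=float(p["gain"]),
                light=bool(p.get("light", True)),
                powers={resolve(k): int(v) for k, v in (p.get("powers") or {}).items()},
                gain_free=bool(p.get("free", True)),
            )
            for p in block.get("light", [])
        ]
        dynamics.append(
            SpeciesDynamics(
                alpha=float(alpha_block.get("value", 0.0)),
                alpha_free=bool(alpha_block.get("free", False)),
                production=production,
                degradation=degradation,
                light=light,
            )
        )
    return ESSModel(species, dynamics)


def load_model(path) -> ESSModel:
    """Read a YAML circuit config from ``path`` and build the model."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return build_model(config)
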