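"""Michaelis-Menten / linear building blocks for conventional clock circuits.

These are the kinetic templates that classical plant-clock models are built
from; here they serve as reference circuits whose simulated output provides
training and validation data for the power-law (extended S-System) models:

* Hill activation:  dG/dt = a P^n / (K^n + P^n) - b G
* Hill inhibition:  dG/dt = a K^n / (K^n + P^n) - b G
* cytoplasm/nucleus protein shuttling:
    dPc/dt = a G - r_C Pc + r_N Pn - b_C Pc
    dPn/dt = r_C Pc - r_N Pn - b_N Pn
* aggregated protein: dP/dt = a G - b P
* complex formation:  dC/dt = a P1 P2 ... PN - b C
* stabilised/mediated degradation:
    dP/dt = a G - b P + c_S P Ps - c_D P Pd
* additive light drive: dX/dt += gain * L(t)

A model is a list of wired blocks; each block accumulates its contribution
into the shared derivative vector, so a species may be touched by several
blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BLOCK_KINDS = (
    "hill_activation",
    "hill_inhibition",
    "shuttling_pair",
    "aggregated_protein",
    "complex",
    "stab_deg",
    "light_drive",
)

# parameters that must be strictly positive, per kind
_REQUIRED = {
    "hill_activation": ("a", "K", "n", "b"),
    "hill_inhibition": ("a", "K", "n", "b"),
    "shuttling_pair": ("a", "r_C", "r_N", "b_C", "b_N"),
    "aggregated_protein": ("a", "b"),
    "complex": ("a", "b"),
    "stab_deg": ("a", "b", "c_S", "c_D"),
    "light_drive": ("gain",),
}


@dataclass
class MMBlock:
    """One wired kinetic template.

    ``wiring`` maps role names to species names; roles per kind:

    * hill_activation / hill_inhibition: target, regulator
    * shuttling_pair: gene, cytoplasmic, nuclear
    * aggregated_protein: gene, protein
    * complex: proteins (list), complex
    * stab_deg: gene, protein, stabiliser, degrader
    * light_drive: target
    """

    kind: str
    params: dict[str, float]
    wiring: dict[str, object]

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        for p in _REQUIRED[self.kind]:
            if p not in self.params:
                raise ValueError(f"{self.kind} block missing parameter {p!r}")
            if self.params[p] <= 0:
                raise ValueError(f"{self.kind} parameter {p!r} must be > 0")
        if self.kind in ("hill_activation", "hill_inhibition") and self.params["n"] < 1:
            raise ValueError("Hill coefficient must be >= 1")


class MMModel:
    """Reference circuit assembled from Michaelis-Menten/linear blocks."""

    def __init__(self, species_names: list[str], blocks: list[MMBlock]):
        if len(set(species_names)) != len(species_names):
            raise ValueError("species names must be unique")
        self.species = list(species_names)
        self._index = {name: i for i, name in enumerate(species_names)}
        for blk in blocks:
            for role, ref in blk.wiring.items():
                refs = ref if isinstance(ref, (list, tuple)) else [ref]
                for r in refs:
                    if r not in self._index:
                        raise ValueError(f"block {blk.kind} wires unknown species {r!r}")
        self.blocks = list(blocks)

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def index_of(self, name: str) -> int:
        return self._index[name] + 1  # 1-based, matching ESSModel

    def rhs(self, state, light_value: float) -> np.ndarray:
        return mm_rhs(self.blocks, state, light_value, self._index)

    def copy(self) -> "MMModel":
        import copy as _copy

        return _copy.deepcopy(self)


def mm_rhs(blocks, state, light_value: float, index: dict[str, int] | None = None) -> np.ndarray:
    """Assemble the derivative vector for a list of wired blocks.

    ``index`` maps species name to 0-based position in ``state``; if omitted,
    wiring values are taken to be 0-based integer indices already.
    """
    x = np.asarray(state, dtype=float)
    dx = np.zeros_like(x)

    def at(ref) -> int:
        return index[ref] if index is not None else int(ref)

    for blk in blocks:
        p, w = blk.params, blk.wiring
        if blk.kind in ("hill_activation", "hill_inhibition"):
            G = x[at(w["target"])]
            P = max(x[at(w["regulator"])], 0.0)
            Kn = p["K"] ** p["n"]
            Pn = P ** p["n"]
            num = Pn if blk.kind == "hill_activation" else Kn
            dx[at(w["target"])] += p["a"] * num / (Kn + Pn) - p["b"] * G
        elif blk.kind == "shuttling_pair":
            G = x[at(w["gene"])]
            Pc = x[at(w["cytoplasmic"])]
            Pn_ = x[at(w["nuclear"])]
            dx[at(w["cytoplasmic"])] += p["a"] * G - p["r_C"] * Pc + p["r_N"] * Pn_ - p["b_C"] * Pc
            dx[at(w["nuclear"])] += p["r_C"] * Pc - p["r_N"] * Pn_ - p["b_N"] * Pn_
        elif blk.kind == "aggregated_protein":
            dx[at(w["protein"])] += p["a"] * x[at(w["gene"])] - p["b"] * x[at(w["protein"])]
        elif blk.kind == "complex":
            prod = p["a"]
            for name in w["proteins"]:
                prod *= x[at(name)]
            dx[at(w["complex"])] += prod - p["b"] * x[at(w["complex"])]
        elif blk.kind == "stab_deg":
            P = x[at(w["protein"])]
            dx[at(w["protein"])] += (
                p["a"] * x[at(w["gene"])]
                - p["b"] * P
                + p["c_S"] * P * x[at(w["stabiliser"])]
                - p["c_D"] * P * x[at(w["degrader"])]
            )
        elif blk.kind == "light_drive":
            dx[at(w["target"])] += p["gain"] * light_value
    if not np.all(np.isfinite(dx)):
        raise FloatingPointError("non-finite Michaelis-Menten derivative")
    return dx
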