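"""AIC-based ranking of alternative model formulations fitted to one dataset.

For weighted least-squares fits sharing the data, grid and weights, AIC
differences can be computed from the simplified criterion

    AIC = N_G * N_T * ln(W) + 2 * (K_Theta + 1),

where W is the training WMSE and K_Theta the number of optimised parameters;
the full log-likelihood form differs from it only by an additive constant
that cancels in the differences.  Akaike weights are the softmax of
-Delta/2 and the evidence ratio w_i/w_j quantifies support for model i over
model j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def aic_simplified(W: float, k_theta: int, n_g: int, n_t: int) -> float:
    """Simplified AIC for a WMSE fit; valid for differences across models."""
    if W <= 0:
        raise ValueError("training WMSE must be > 0")
    if min(k_theta, n_g, n_t) < 0 or n_g == 0 or n_t == 0:
        raise ValueError("K_Theta must be >= 0 and N_G, N_T positive")
    return n_g * n_t * math.log(W) + 2 * (k_theta + 1)


def full_loglik(W: float, A, n_g: int, n_t: int) -> float:
    """Maximised log-likelihood of a weighted least-squares fit.

    ``A`` are the per-component normalisation weights.  -2*lnL + 2K differs
    from :func:`aic_simplified` by a constant shared by all models fitted to
    the same data (same N_G, N_T, A_i), so both orderings coincide.
    """
    A = np.asarray(A, dtype=float)
    if W <= 0 or np.any(A <= 0):
        raise ValueError("W and all weights A_i must be > 0")
    return (
        -n_g * n_t / 2.0 * math.log(2.0 * math.pi + 1.0)
        - n_t * float(np.sum(np.log(A)))
        - n_g * n_t / 2.0 * math.log(W)
    )


def delta_aic(aic_values) -> np.ndarray:
    """AIC differences: each value minus the minimum (best model gets 0)."""
    aic_values = np.asarray(aic_values, dtype=float)
    if aic_values.size < 1:
        raise ValueError("need at least one AIC value")
    return aic_values - aic_values.min()


def akaike_weights(deltas) -> np.ndarray:
    """Akaike weights: softmax of -Delta/2.

    Differences are taken before exponentiation, so enormous Deltas underflow
    cleanly to a weight of 0 rather than producing 0/0.
    """
    deltas = np.asarray(deltas, dtype=float)
    raw = np.exp(-0.5 * (deltas - deltas.min()))
    return raw / raw.sum()


def evidence_ratio(w_i: float, w_j: float) -> tuple[float, bool]:
    """Support for model i over model j: w_i / w_j.

    Returns ``(ratio, finite)``; when w_j has underflowed to 0 the ratio is
    reported as infinity with ``finite=False``.
    """
    if w_j < 0 or w_i < 0:
        raise ValueError("weights must be non-negative")
    if w_j == 0:
        return float("inf"), False
    return w_i / w_j, True


@dataclass
class AICReport:
    """Per-model AIC ranking table."""

    names: list[str]
    k_theta: list[int]
    wmse: list[float]
    aic: np.ndarray
    delta: np.ndarray
    weights: np.ndarray
    full_aic: np.ndarray | None = None

    def evidence_ratios(self) -> dict[str, float]:
        """Pairwise evidence ratios w_i/w_j for all ordered model pairs."""
        out = {}
        for i, ni in enumerate(self.names):
            for j, nj in enumerate(self.names):
                if i != j:
                    ratio, _ = evidence_ratio(self.weights[i], self.weights[j])
                    out[f"{ni}/{nj}"] = ratio
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "K_Theta": self.k_theta,
                "WMSE": self.wmse,
                "AIC": self.aic,
                "Delta_AIC": self.delta,
                "Akaike_weight": self.weights,
            },
            index=self.names,
        )
        if self.full_aic is not None:
            df["AIC_full"] = self.full_aic
        return df

    def to_dict(self) -> dict:
        return {
            "models": [
                {
                    "name": n,
                    "K_Theta": int(k),
                    "WMSE": float(w),
                    "AIC": float(a),
                    "Delta_AIC": float(d),
                    "Akaike_weight": float(wt),
                }
                for n, k, w, a, d, wt in zip(
                    self.names, self.k_theta, self.wmse, self.aic, self.delta, self.weights
                )
            ],
            "evidence_ratios": {
                k: (v if math.isfinite(v) else "inf") for k, v in self.evidence_ratios().items()
            },
        }

    def format_table(self) -> str:
        """Formatted ranking: Delta to 2 dp, weights to 5 dp."""
        lines = [
            f"{'model':<16s} {'K':>4s} {'WMSE':>10s} {'dAIC':>10s} {'w':>9s}",
            "-" * 53,
        ]
        for n, k, w, d, wt in zip(self.names, self.k_theta, self.wmse, self.delta, self.weights):
            lines.append(f"{n:<16s} {k:>4d} {w:>10.5f} {d:>10.2f} {wt:>9.5f}")
        return "\n".join(lines)


def rank_models(entries, n_g: int, n_t: int, weights_a=None) -> AICReport:
    """Build an :class:`AICReport` from ``(name, WMSE, K_Theta)`` entries.

    ``weights_a`` optionally supplies the shared A_i normalisation weights,
    in which case the full-likelihood AIC (-2 lnL + 2K) is reported alongside
    the simplified one; the differences are identical by construction.
    """
    names = [e[0] for e in entries]
    wmse = [float(e[1]) for e in entries]
    ks = [int(e[2]) for e in entries]
    aic = np.array([aic_simplified(w, k, n_g, n_t) for w, k in zip(wmse, ks)])
    deltas = delta_aic(aic)
    full = None
    if weights_a is not None:
        full = np.array(
            [-2.0 * full_loglik(w, weights_a, n_g, n_t) + 2 * (k + 1) for w, k in zip(wmse, ks)]
        )
    return AICReport(
        names=names,
        k_theta=ks,
        wmse=wmse,
        aic=aic,
        delta=deltas,
        weights=akaike_weights(deltas),
        full_aic=full,
    )
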