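"""Mutant simulation and free-running period phenotyping.

Knockout/knockdown is simulated by multiplying the target's transcription
rate constant by 0.2 (an 80% reduction) and overexpression by multiplying
the translation rate by 2.0; when a species has no transcription term the
designated production rate is scaled instead.  Free-running period tau is
estimated per component from the mean gap between successive expression
maxima after release into constant conditions, then averaged across
components; the mutant phenotype is the sign of
delta_tau = tau_mut - tau_wt, with a small dead-band mapping to "0" and an
amplitude-collapse rule mapping to arrhythmic ("arr.").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .model import ESSModel
from .mm import MMModel
from .simulate import Timeseries

KNOCKOUT_SCALE = 0.2  # transcription rate reduced by 80%
OVEREXPRESSION_SCALE = 2.0  # translation rate doubled

PROMINENCE_FRACTION = 0.01  # of the component's range in the analysis window
MIN_PEAK_SPACING_H = 6.0
ARRHYTHMIA_AMPLITUDE_FRACTION = 0.10  # final cycle vs first cycle
DEAD_BAND_H = 0.05
MIN_PEAKS = 3


@dataclass(frozen=True)
class MutantSpec:
    """A genetic perturbation applied to a production rate constant.

    ``target`` is a species name (its production rate constant is scaled) or
    an explicit parameter reference understood by the model class.
    """

    target: str
    kind: str  # "knockout" | "overexpression"
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("knockout", "overexpression"):
            raise ValueError("kind must be 'knockout' or 'overexpression'")
        scale = self.effective_scale
        if scale <= 0:
            raise ValueError("scale must be > 0")
        if self.kind == "knockout" and not scale < 1 and scale != 1.0:
            raise ValueError("knockout scale must be < 1")
        if self.kind == "overexpression" and not scale > 1 and scale != 1.0:
            raise ValueError("overexpression scale must be > 1")

    @property
    def effective_scale(self) -> float:
        if self.scale is not None:
            return self.scale
        return KNOCKOUT_SCALE if self.kind == "knockout" else OVEREXPRESSION_SCALE


def apply_mutant(model, spec: MutantSpec):
    """Return a copy of ``model`` with the targeted production rate scaled.

    For an extended S-System model the target species' alpha is scaled; for a
    Michaelis-Menten reference circuit, the ``a`` parameter of the block
    producing the target species is scaled.  Everything else is untouched.
    """
    mutated = model.copy()
    if isinstance(model, ESSModel):
        idx = mutated.index_of(spec.target)  # KeyError for missing targets
        mutated.dynamics[idx - 1].alpha *= spec.effective_scale
        mutated._plan = None
        return mutated
    if isinstance(model, MMModel):
        produced_roles = {"target", "protein", "complex", "cytoplasmic"}
        for blk in mutated.blocks:
            for role in produced_roles:
                if blk.wiring.get(role) == spec.target and "a" in blk.params:
                    blk.params["a"] *= spec.effective_scale
                    return mutated
        raise KeyError(f"no production block found for species {spec.target!r}")
    raise TypeError(f"unsupported model type {type(model).__name__}")


@dataclass
class PeriodEstimate:
    """Per-component and mean free-running period."""

    periods: dict[str, float]  # qualifying components only
    tau: float | None  # mean across qualifying components; None if arrhythmic
    rhythmic: bool
    excluded: list[str]  # components with too few peaks or collapsed amplitude
    peak_times: dict[str, np.ndarray]


def _cycle_amplitudes(x: np.ndarray, peak_idx: np.ndarray) -> tuple[float, float]:
    """Peak-to-trough amplitude of the first and last complete cycles."""
    first = x[peak_idx[0] : peak_idx[1] + 1]
    last = x[peak_idx[-2] : peak_idx[-1] + 1]
    return float(first.max() - first.min()), float(last.max() - last.min())


def estimate_period(ts: Timeseries, window: tuple[float, float] | None = None) -> PeriodEstimate:
    """Estimate the oscillation period from successive expression maxima.

    Local maxima are detected per component with a prominence of 1% of the
    component's range in the window and a minimum spacing of 6 h; components
    with fewer than three peaks, or whose final complete cycle has collapsed
    below 10% of the first cycle's amplitude, are excluded.  The component
    period is the mean gap between successive maxima and tau averages the
    qualifying components.
    """
    if window is None:
        if ts.protocol is not None and ts.protocol.released:
            window = (float(ts.protocol.release_time), float(ts.time[-1]))
        else:
            window = (float(ts.time[0]), float(ts.time[-1]))
    sub = ts.window(*window)
    dt = float(np.median(np.diff(sub.time)))
    distance = max(1, int(round(MIN_PEAK_SPACING_H / dt)))
    periods: dict[str, float] = {}
    peak_times: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for lab in sub.labels:
        x = sub.component(lab)
        rng = float(x.max() - x.min())
        if rng <= 0:
            excluded.append(lab)
            continue
        idx, _ = find_peaks(x, prominence=PROMINENCE_FRACTION * rng, distance=distance)
        if idx.size < MIN_PEAKS:
            excluded.append(lab)
            continue
        amp_first, amp_last = _cycle_amplitudes(x, idx)
        if amp_first > 0 and amp_last < ARRHYTHMIA_AMPLITUDE_FRACTION * amp_first:
            excluded.append(lab)
            continue
        tpk = sub.time[idx]
        periods[lab] = float(np.mean(np.diff(tpk)))
        peak_times[lab] = tpk
    rhythmic = len(periods) > 0
    tau = float(np.mean(list(periods.values()))) if rhythmic else None
    return PeriodEstimate(periods=periods, tau=tau, rhythmic=rhythmic, excluded=excluded, peak_times=peak_times)


def classify_shift(tau_mut: float | None, tau_wt: float, rhythmic_mut: bool, dead_band: float = DEAD_BAND_H) -> str:
    """Phenotype label from the period shift delta_tau = tau_mut - tau_wt.

    Returns "arr." for an arrhythmic mutant, "0" within the dead-band, else
    "+" (long period) or "-" (short period).
    """
    if tau_wt is None or tau_wt <= 0:
        raise ValueError("wild-type run must be rhythmic with tau > 0")
    if not rhythmic_mut or tau_mut is None:
        return "arr."
    delta = tau_mut - tau_wt
    if abs(delta) < dead_band:
        return "0"
    return "+" if delta > 0 else "-"
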