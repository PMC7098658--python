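"""Deterministic ODE simulation of clock models under light protocols.

The light forcing is piecewise constant, so integration is restarted at every
dawn/dusk/release discontinuity and the light level is held fixed inside each
segment; this keeps the stiff integrator's step-size control honest across
the jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .light import LightProtocol, light_signal, switch_times

DEFAULT_INIT = 0.1  # model units; all species start here unless overridden
DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


class SimulationError(RuntimeError):
    """Integration failure, annotated with the offending time and state."""


@dataclass
class Timeseries:
    """Sampled expression trajectories: time grid x component values."""

    time: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # (N_T, N_G), expression in model units
    labels: list[str]
    protocol: LightProtocol | None = None
    light: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.time.size:
            raise ValueError("values row count must match time grid length")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("values column count must match number of labels")
        if self.time.size == 0 or len(self.labels) == 0:
            raise ValueError("empty timeseries")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timeseries values must be finite")

    @property
    def n_points(self) -> int:
        return self.time.size

    @property
    def n_components(self) -> int:
        return len(self.labels)

    def component(self, label: str) -> np.ndarray:
        try:
            return self.values[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown component {label!r}")

    def window(self, t_start: float, t_end: float) -> "Timeseries":
        mask = (self.time >= t_start) & (self.time <= t_end)
        light = self.light[mask] if self.light is not None else None
        return Timeseries(self.time[mask], self.values[mask], list(self.labels), self.protocol, light)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "time_h", self.time)
        if self.light is not None:
            df["light"] = self.light
        return df

    def plot(self, ax=None):
        """Quick-look line plot of all components (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, lab in enumerate(self.labels):
            ax.plot(self.time, self.values[:, i], label=lab)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("expression (model units)")
        ax.legend()
        return ax


def simulate(
    model,
    protocol: LightProtocol,
    grid,
    init,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Timeseries:
    """Integrate ``model`` over ``grid`` and sample the solution there.

    ``model`` needs ``rhs(state, light_value)`` and ``species_names``
    (both :class:`~essclock.model.ESSModel` and :class:`~essclock.mm.MMModel`
    qualify).  The state is held non-negative in the returned samples.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    init = np.asarray(init, dtype=float)
    if init.size != model.n:
        raise ValueError("init length must equal number of species")
    if np.any(init < 0):
        raise ValueError("init must be non-negative")

    t0, t1 = float(grid[0]), float(grid[-1])
    values = np.empty((grid.size, model.n))
    state = init.copy()
    if t0 == t1:
        values[0] = state
    else:
        boundaries = [t0] + switch_times(protocol, t0, t1)
        if boundaries[-1] < t1:
            boundaries.append(t1)
        pos = 0
        if grid[0] == t0:
            values[0] = state
            pos = 1
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            L = light_signal(0.5 * (a + b), protocol)
            seg_end = pos
            while seg_end < grid.size and grid[seg_end] <= b + 1e-12:
                seg_end += 1
            t_eval = grid[pos:seg_end]
            need_endpoint = t_eval.size == 0 or t_eval[-1] < b - 1e-12
            t_out = np.concatenate([t_eval, [b]]) if need_endpoint else t_eval
            sol = solve_ivp(
                lambda t, x: model.rhs(x, L),
                (a, b),
                state,
                method=method,
                t_eval=t_out,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"integration failed near t={sol.t[-1] if sol.t.size else a:.3f} h, "
                    f"state={state}: {sol.message}"
                )
            if t_eval.size:
                values[pos:seg_end] = sol.y[:, : t_eval.size].T
            state = sol.y[:, -1]
            pos = seg_end
        if pos < grid.size:  # t1 coincides with last boundary endpoint
            values[pos:] = state
    values = np.maximum(values, 0.0)
    light = np.array([light_signal(t, protocol) for t in grid])
    return Timeseries(grid, values, model.species_names, protocol, light)


def entrain_and_release(
    model,
    protocol: LightProtocol,
    record_hours_before: float = 24.0,
    record_hours_after: float = 72.0,
    sampling_interval: float = 1.0,
    init=None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Timeseries:
    """Run the standard entrainment-then-release experiment.

    The model starts from the default initial state at dawn of the first
    entrainment cycle, runs through the protocol's entrainment cycles, and the
    recorded window straddles the release time: ``record_hours_before`` h of
    the final light-dark cycles plus ``record_hours_after`` h of the constant
    regime, sampled every ``sampling_interval`` h
    (N_T = (before + after)/interval + 1 points).
    """
    if protocol.entrainment_cycles < 1:
        raise ValueError("entrain_and_release requires entrainment_cycles >= 1")
    if not protocol.released:
        raise ValueError("protocol must release into LL or DD")
    release = float(protocol.release_time)
    start = release - record_hours_before
    if start < 0:
        raise ValueError("recording window starts before t=0; reduce record_hours_before")
    if init is None:
        init = np.full(model.n, DEFAULT_INIT)
    n_pts = int(round((record_hours_before + record_hours_after) / sampling_interval)) + 1
    grid = start + sampling_interval * np.arange(n_pts)
    if start > 0:
        burn = simulate(model, protocol, np.array([0.0, start]), init, rtol=rtol, atol=atol)
        init = burn.values[-1]
    return simulate(model, protocol, grid, init, rtol=rtol, atol=atol)
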