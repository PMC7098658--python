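"""Weighted least-squares fitting of extended S-System models to timeseries.

The cost is the weighted mean squared error (WMSE): each component's
residuals are normalised by that component's maximum over the training
window,

    W_i = (1/N_T) sum_j ((X_i(t_j) - Xhat_i(t_j)) / A_i)^2,
    A_i = max_j X_i(t_j),
    W   = (1/N_G) sum_i W_i,

so components of very different amplitude contribute comparably.  W is
minimised over the model's free parameters with the Nelder-Mead simplex,
restarting from the incumbent until a restart improves W by less than a
threshold (the "no further improvement" local-minimum criterion made
quantitative).

The model object / results object split follows the usual statistical
modelling convention: :class:`SSystemFit` holds the data, protocol and
optimisation configuration; :meth:`SSystemFit.fit` returns a
:class:`SSystemFitResults` carrying the estimates and diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import ESSModel, ParameterVector
from .light import LightProtocol
from .simulate import SimulationError, Timeseries, simulate, entrain_and_release


class FlatComponentError(ValueError):
    """A target component is identically zero and cannot be normalised."""


# -- WMSE scoring -------------------------------------------------------------


def component_weight(target: np.ndarray) -> float:
    """Normalisation weight A_i: the component's maximum over the window."""
    A = float(np.max(target))
    if A <= 0:
        raise FlatComponentError("unnormalisable component: max of target is 0")
    return A


def wmse_component(target: np.ndarray, simulated: np.ndarray, A: float | None = None) -> float:
    """Per-component WMSE: mean squared residual normalised by A_i."""
    target = np.asarray(target, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if target.shape != simulated.shape:
        raise ValueError("target and simulated grids differ")
    if A is None:
        A = component_weight(target)
    return float(np.mean(((target - simulated) / A) ** 2))


def wmse_total(target: Timeseries, simulated: Timeseries) -> float:
    """Total WMSE: arithmetic mean of the per-component WMSEs."""
    return float(np.mean(list(wmse_components(target, simulated).values())))


def wmse_components(target: Timeseries, simulated: Timeseries) -> dict[str, float]:
    """Per-component WMSE values, keyed by component label."""
    if not set(target.labels) <= set(simulated.labels):
        raise ValueError(
            f"component mismatch: target has {target.labels}, simulated has {simulated.labels}"
        )
    if target.n_points != simulated.n_points or not np.allclose(target.time, simulated.time):
        raise ValueError("target and simulated time grids differ")
    return {
        lab: wmse_component(target.component(lab), simulated.component(lab))
        for lab in target.labels
    }


# -- configuration and results -------------------------------------------------


@dataclass
class FitConfig:
    """Optimiser settings for one WMSE minimisation run."""

    max_fev_per_restart: int | None = None  # default: 400 * K_Theta
    xatol: float = 1e-6
    fatol: float = 1e-9
    restart_improvement: float = 1e-6  # stop when a restart gains less than this
    max_restarts: int = 10
    seed: int = 0
    failure_penalty: float = 1e6  # cost assigned when a candidate cannot be simulated
    rtol: float = 1e-6
    atol: float = 1e-9


@dataclass
class SSystemFitResults:
    """Optimised parameters plus goodness-of-fit diagnostics."""

    model: "SSystemFit"
    params: ParameterVector
    wmse: float
    wmse_per_component: dict[str, float]
    n_fev: int
    n_restarts: int
    seed: int
    converged: bool

    @property
    def fitted_model(self) -> ESSModel:
        return self.model.ess_model.unpack_parameters(self.params)

    def simulated(self) -> Timeseries:
        """Model trajectory at the optimum on the training grid."""
        return self.model.simulate_candidate(self.params.values)

    def validate(self, validation: Timeseries, protocol: LightProtocol) -> tuple[float, dict[str, float]]:
        """Out-of-sample WMSE under a different light protocol; no re-fitting."""
        sim = self.model.simulate_candidate(self.params.values, protocol=protocol, grid=validation.time)
        comps = wmse_components(validation, sim)
        return float(np.mean(list(comps.values()))), comps

    def regulation_signs(self) -> dict[str, str]:
        return infer_regulation_signs(self.fitted_model)

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.params.values}, index=list(self.params.names))

    def summary(self) -> str:
        lines = [
            "Extended S-System WMSE fit",
            "=" * 54,
            f"components (N_G): {len(self.wmse_per_component):>6d}"
            f"    points (N_T): {self.model.training.n_points}",
            f"free parameters (K_Theta): {len(self.params):>4d}"
            f"    evaluations: {self.n_fev}",
            f"restarts: {self.n_restarts}    seed: {self.seed}"
            f"    converged: {self.converged}",
            f"total WMSE: {self.wmse:.6g}",
            "",
            "Per-component WMSE",
            "-" * 54,
        ]
        for lab, wi in self.wmse_per_component.items():
            lines.append(f"  {lab:<16s} {wi:.6g}")
        lines += ["", "Parameters", "-" * 54]
        for name, value in self.params.as_dict().items():
            lines.append(f"  {name:<24s} {value: .6g}")
        signs = self.regulation_signs()
        if signs:
            lines += ["", "Inferred regulation", "-" * 54]
            for inter, kind in signs.items():
                lines.append(f"  {inter:<24s} {kind}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "wmse": self.wmse,
            "wmse_per_component": self.wmse_per_component,
            "parameters": self.params.as_dict(),
            "n_fev": self.n_fev,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "converged": self.converged,
            "regulation_signs": self.regulation_signs(),
        }


@dataclass
class VariabilityResult:
    """Multistart parameter variability summarised by the normalised MAD."""

    names: tuple[str, ...]
    runs: np.ndarray  # (n_runs, K) optimised parameter values
    wmse: np.ndarray  # (n_runs,) final costs
    medians: np.ndarray
    nmad_values: np.ndarray  # NaN where the median is zero
    degenerate: np.ndarray  # bool flags for median == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.medians, "nMAD": self.nmad_values, "degenerate": self.degenerate},
            index=list(self.names),
        )


def summarise_variability(names, runs, wmse) -> VariabilityResult:
    """Summarise multistart optima (rows of ``runs``) by per-parameter nMAD."""
    runs = np.atleast_2d(np.asarray(runs, dtype=float))
    medians = np.median(runs, axis=0)
    nmads = np.array([nmad(runs[:, j]) for j in range(runs.shape[1])])
    return VariabilityResult(
        names=tuple(names),
        runs=runs,
        wmse=np.asarray(wmse, dtype=float),
        medians=medians,
        nmad_values=nmads,
        degenerate=medians == 0.0,
    )


def nmad(values) -> float:
    """Normalised median absolute deviation: median(|x - med|) / |med|.

    Returns NaN when the median is zero (flagged degenerate upstream).
    """
    values = np.asarray(values, dtype=float)
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    if med == 0.0:
        return float("nan")
    return mad / abs(med)


# -- regulation-sign inference -------------------------------------------------


def infer_regulation_signs(model: ESSModel) -> dict[str, str]:
    """Classify every production interaction by the sign of its exponent.

    Positive kinetic order -> activator, negative -> inhibitor, zero ->
    indeterminate.  Keys are ``"regulators->target"`` strings.
    """
    signs: dict[str, str] = {}
    for s, dyn in zip(model.species, model.dynamics):
        for proc in dyn.production:
            base = "+".join(model.species[k - 1].name for k in proc.members)
            key = f"{base}->{s.name}"
            if proc.exponent > 0:
                signs[key] = "activator"
            elif proc.exponent < 0:
                signs[key] = "inhibitor"
            else:
                signs[key] = "indeterminate"
    return signs


# -- the model object ----------------------------------------------------------


class SSystemFit:
    """WMSE fitting problem: an ESS model structure, training data, protocol.

    Parameters
    ----------
    ess_model : ESSModel
        Structure and initial parameter values; its free-parameter mask
        defines the optimisation space (K_Theta).
    training : Timeseries
        Target trajectories; labels must cover the model species.
    protocol : LightProtocol
        Light schedule under which the training data were produced.  Each
        candidate is simulated from the standard initial state at t = 0
        through this protocol and sampled on the training grid.
    config : FitConfig, optional
    """

    def __init__(
        self,
        ess_model: ESSModel,
        training: Timeseries,
        protocol: LightProtocol,
        config: FitConfig | None = None,
    ):
        if ess_model.k_theta == 0:
            raise ValueError("model has no free parameters to fit")
        missing = set(ess_model.species_names) - set(training.labels)
        if missing:
            raise ValueError(f"training data lacks components {sorted(missing)}")
        self.ess_model = ess_model
        self.training = training
        self.protocol = protocol
        self.config = config or FitConfig()
        self.weights = {lab: component_weight(training.component(lab)) for lab in ess_model.species_names}
        self._alpha_mask = np.array([n.startswith("alpha[") for n in ess_model.parameter_names])
        self._order = [training.labels.index(lab) for lab in ess_model.species_names]
        self._target = training.values[:, self._order]
        self._A = np.array([self.weights[lab] for lab in ess_model.species_names])

    # -- simulation of a candidate ------------------------------------------

    def simulate_candidate(self, theta, protocol: LightProtocol | None = None, grid=None) -> Timeseries:
        protocol = protocol or self.protocol
        grid = self.training.time if grid is None else np.asarray(grid, dtype=float)
        model = self.ess_model.unpack_parameters(theta)
        init = np.full(model.n, 0.1)
        if grid[0] > 0:
            burn = simulate(
                model, protocol, np.array([0.0, grid[0]]), init,
                rtol=self.config.rtol, atol=self.config.atol,
            )
            init = burn.values[-1]
        return simulate(model, protocol, grid, init, rtol=self.config.rtol, atol=self.config.atol)

    def loss(self, theta, sign_constraints: dict[str, int] | None = None) -> float:
        """WMSE of one candidate; infeasible/failed candidates get a finite penalty."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta[self._alpha_mask] < 0):
            # keep the simplex inside alpha >= 0 with a graded penalty
            overshoot = float(-theta[self._alpha_mask].clip(max=0).sum())
            return self.config.failure_penalty * (1.0 + overshoot)
        if sign_constraints:
            names = self.ess_model.parameter_names
            for pname, sign in sign_constraints.items():
                value = theta[names.index(pname)]
                if sign * value <= 0:
                    return self.config.failure_penalty * (1.0 + abs(value))
        try:
            sim = self.simulate_candidate(theta)
        except (SimulationError, FloatingPointError, OverflowError):
            return self.config.failure_penalty
        resid = (self._target - sim.values) / self._A
        return float(np.mean(resid * resid))

    # -- optimisation --------------------------------------------------------

    def fit(
        self,
        start: ParameterVector | np.ndarray | None = None,
        sign_constraints: dict[str, int] | None = None,
        seed: int | None = None,
    ) -> SSystemFitResults:
        """Nelder-Mead minimisation with resample-free restarts from the incumbent."""
        cfg = self.config
        if start is None:
            start = self.ess_model.pack_parameters()
        theta = start.values.copy() if isinstance(start, ParameterVector) else np.asarray(start, dtype=float)
        if theta.size != self.ess_model.k_theta:
            raise ValueError("start length must equal K_Theta")
        maxfev = cfg.max_fev_per_restart or 400 * self.ess_model.k_theta

        best = self.loss(theta, sign_constraints)
        if best >= cfg.failure_penalty:
            raise RuntimeError("infeasible start: initial candidate cannot be simulated")
        best_theta = theta.copy()
        n_fev = 1
        converged = False
        restarts = 0
        for restarts in range(1, cfg.max_restarts + 1):
            res = minimize(
                self.loss,
                best_theta,
                args=(sign_constraints,),
                method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": cfg.xatol, "fatol": cfg.fatol},
            )
            n_fev += res.nfev
            improvement = best - res.fun
            if res.fun < best:
                best = float(res.fun)
                best_theta = np.asarray(res.x, dtype=float)
            if improvement < cfg.restart_improvement:
                converged = True
                break

        sim = self.simulate_candidate(best_theta)
        comps = {
            lab: wmse_component(self.training.component(lab), sim.component(lab), self.weights[lab])
            for lab in self.ess_model.species_names
        }
        params = ParameterVector(self.ess_model.parameter_names, best_theta, "optimised")
        return SSystemFitResults(
            model=self,
            params=params,
            wmse=float(np.mean(list(comps.values()))),
            wmse_per_component=comps,
            n_fev=n_fev,
            n_restarts=restarts,
            seed=cfg.seed if seed is None else seed,
            converged=converged,
        )

    def constrain_signs_and_refit(
        self,
        result: SSystemFitResults,
        required_signs: dict[str, int],
    ) -> SSystemFitResults:
        """Flip wrongly-signed production exponents and re-optimise with the signs pinned.

        ``required_signs`` maps free-parameter names (``g[...]``) to +1/-1.
        With an empty mapping this is a plain continuation of the fit.
        """
        theta = result.params.values.copy()
        names = self.ess_model.parameter_names
        for pname, sign in required_signs.items():
            i = names.index(pname)
            if sign * theta[i] < 0:
                theta[i] = -theta[i]
        refit = self.fit(start=theta, sign_constraints=required_signs or None, seed=result.seed)
        if refit.wmse > result.wmse and not required_signs:
            return result
        return refit

    def variability_analysis(self, n_runs: int = 6, seed: int = 0, start=None) -> VariabilityResult:
        """Multistart identifiability analysis.

        Run 1 starts from ``start`` (default: the model's current parameters);
        runs 2..n start from draws of a multivariate normal centred on run 1's
        optimum with identity covariance.  Draws giving a negative production
        rate constant are rejected and redrawn (at most 100 attempts each).
        Per-parameter spread across the run optima is summarised by the nMAD.
        """
        if n_runs < 2:
            raise ValueError("variability analysis needs n_runs >= 2")
        rng = np.random.default_rng(seed)
        first = self.fit(start=start, seed=seed)
        optima = [first.params.values]
        costs = [first.wmse]
        K = self.ess_model.k_theta
        for _ in range(n_runs - 1):
            for _attempt in range(100):
                draw = first.params.values + rng.standard_normal(K)
                # reject infeasible draws: negative production rates, or
                # candidates whose simulation diverges outright
                if np.all(draw[self._alpha_mask] >= 0) and self.loss(draw) < self.config.failure_penalty:
                    break
            else:
                raise RuntimeError("could not draw a feasible start in 100 attempts")
            run = self.fit(start=draw, seed=seed)
            optima.append(run.params.values)
            costs.append(run.wmse)
        return summarise_variability(self.ess_model.parameter_names, np.vstack(optima), costs)
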