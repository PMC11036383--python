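"""Cake/filtration parameter estimation from filtrate volume-time data.

The estimation problem mirrors the validation workflow of the case
studies: given one or more constant-pressure filtration experiments
(scenario + observed V(t) series), estimate any subset of

* ``sphericity``            - Carman-Kozeny particle shape factor psi,
* ``porosity``              - cake porosity eps,
* ``medium_resistance``     - filter medium resistance Rm (1/m),
* ``compressibility_index`` - power-law exponent n of alpha(dP),

by bounded nonlinear least squares on the normalized volume residuals

    sum_exp sum_t ((V_sim(t) - V_obs(t)) / max|V_obs|)^2,

optionally augmented with a retained-liquid-mass residual. The objective
is a plain normalized least-squares criterion, not the proprietary
maximum-likelihood objective of the original estimation tool, so
objective values are not comparable across tools (parameter estimates
are).

The compressibility index is identifiable only when the experiments span
more than one driving pressure; with a single pressure the fit pins
n = 0 and raises an identifiability flag, matching the zero-
compressibility outcomes reported for single-pressure designs.

Usage follows the model/results idiom::

    problem = EstimationProblem([Experiment(scenario, t, v), ...],
                                free_parameters=("sphericity", "porosity"))
    result = problem.fit()
    print(result.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidArgumentError, InvalidStateError
from .filtration import _hydraulics, predict_volumes, simulate_filtration
from .scenarios import Scenario

PARAMETER_NAMES = (
    "sphericity",
    "porosity",
    "medium_resistance",
    "compressibility_index",
)

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "sphericity": (0.05, 1.0),
    "porosity": (0.2, 0.9),
    "medium_resistance": (1e4, 1e12),
    "compressibility_index": (0.0, 3.0),
}

_DEFAULT_GUESS: dict[str, float] = {
    "sphericity": 0.5,
    "porosity": 0.5,
    "medium_resistance": 1e8,
    "compressibility_index": 0.5,
}

# Medium resistance spans decades; optimize it in log10 space.
_LOG_PARAMS = {"medium_resistance"}


@dataclass(frozen=True)
class Experiment:
    """One calibration experiment: a scenario and its observed series."""

    scenario: Scenario
    times: np.ndarray  # s
    volumes: np.ndarray  # m3
    retained_liquid_mass: float | None = None  # kg, optional extra datum

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or len(t) < 3:
            raise InvalidArgumentError(
                "experiment needs aligned 1-D times/volumes with >= 3 points"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)


def _apply_parameters(
    scenario: Scenario, params: Mapping[str, float]
) -> Scenario:
    cake = scenario.cake_properties
    filt = scenario.filter
    if "sphericity" in params:
        cake = replace(cake, sphericity=params["sphericity"])
    if "porosity" in params:
        cake = replace(cake, porosity=params["porosity"])
    if "compressibility_index" in params:
        cake = replace(cake, compressibility_index=params["compressibility_index"])
    if "medium_resistance" in params:
        filt = replace(filt, medium_resistance=params["medium_resistance"])
    return replace(scenario, cake_properties=cake, filter=filt)


class EstimationProblem:
    """Model object for the filtration parameter-estimation problem.

    Parameters
    ----------
    experiments : sequence of Experiment
    free_parameters : sequence of str
        Subset of :data:`PARAMETER_NAMES` to estimate; the rest keep the
        scenario values.
    bounds, initial_guess : mapping, optional
        Per-parameter overrides of the defaults. Every free parameter
        gets finite bounds containing its initial guess.
    retained_mass_weight : float
        Weight of the optional retained-liquid-mass residual term.
    dryland_endpoint : bool
        Treat each experiment's last sample as the observed dryland
        endpoint and add a residual on the simulated dryland volume.
        The volume series alone cannot identify porosity from below
        (any cake with matching Darcy curvature but a larger dryland
        volume fits the pre-dryland samples exactly); the observation
        that filtration *stopped* at the last sample removes that
        degeneracy. Disable for series truncated before dryland.
    """

    def __init__(
        self,
        experiments: Sequence[Experiment],
        free_parameters: Sequence[str] = (
            "sphericity", "porosity", "medium_resistance"
        ),
        bounds: Mapping[str, tuple[float, float]] | None = None,
        initial_guess: Mapping[str, float] | None = None,
        retained_mass_weight: float = 0.0,
        dryland_endpoint: bool = True,
    ):
        if not experiments:
            raise InvalidArgumentError("need at least one experiment")
        if not free_parameters:
            raise InvalidArgumentError("no free parameters to estimate")
        for p in free_parameters:
            if p not in PARAMETER_NAMES:
                raise InvalidArgumentError(
                    f"unknown parameter {p!r}; expected among {PARAMETER_NAMES}"
                )
        self.experiments = list(experiments)
        self.free_parameters = list(dict.fromkeys(free_parameters))
        self.bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
        self.initial_guess = {**_DEFAULT_GUESS, **(initial_guess or {})}
        # seed guesses for fixed parameters from the first scenario
        scen0 = self.experiments[0].scenario
        self.initial_guess.setdefault("sphericity", scen0.cake_properties.sphericity)
        self.retained_mass_weight = retained_mass_weight
        self.dryland_endpoint = dryland_endpoint
        for p in self.free_parameters:
            lo, hi = self.bounds[p]
            g = self.initial_guess[p]
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise InvalidArgumentError(f"bounds for {p!r} must be finite")
            if not (lo <= g <= hi):
                raise InvalidArgumentError(
                    f"initial guess {g:g} for {p!r} outside bounds [{lo:g}, {hi:g}]"
                )

    # -- identifiability ---------------------------------------------------

    def pressures(self) -> tuple[float, ...]:
        return tuple(
            sorted({e.scenario.conditions.driving_force for e in self.experiments})
        )

    def compressibility_identifiable(self) -> bool:
        return len(self.pressures()) > 1

    # -- fitting -----------------------------------------------------------

    def _encode(self, name: str, value: float) -> float:
        return math.log10(value) if name in _LOG_PARAMS else value

    def _decode(self, name: str, value: float) -> float:
        return 10.0**value if name in _LOG_PARAMS else value

    def _residuals(self, params: Mapping[str, float]) -> np.ndarray:
        res: list[np.ndarray] = []
        for exp in self.experiments:
            scen = _apply_parameters(exp.scenario, params)
            v_sim = predict_volumes(scen, exp.times)
            scale = float(np.max(np.abs(exp.volumes)))
            res.append((v_sim - exp.volumes) / scale)
            if self.dryland_endpoint:
                v_end = _hydraulics(scen).v_end
                res.append(
                    np.array([(v_end - float(exp.volumes[-1])) / scale])
                )
            if (
                self.retained_mass_weight > 0
                and exp.retained_liquid_mass is not None
            ):
                cake = simulate_filtration(scen, n_points=2).end_state
                r = (
                    (cake.liquor_mass - exp.retained_liquid_mass)
                    / exp.retained_liquid_mass
                )
                res.append(
                    np.array([math.sqrt(self.retained_mass_weight) * r])
                )
        return np.concatenate(res)

    def objective(self, params: Mapping[str, float]) -> float:
        """Weighted sum of squared normalized residuals at `params`."""
        full = {**self._fixed_values(), **params}
        return float(np.sum(self._residuals(full) ** 2))

    def _fixed_values(self) -> dict[str, float]:
        scen0 = self.experiments[0].scenario
        return {
            "sphericity": scen0.cake_properties.sphericity,
            "porosity": scen0.cake_properties.porosity,
            "medium_resistance": scen0.filter.medium_resistance,
            "compressibility_index": scen0.cake_properties.compressibility_index,
        }

    def fit(
        self, multistart: int = 0, seed: int | None = None
    ) -> "EstimationResult":
        """Estimate the free parameters.

        Bounded trust-region least squares from the configured initial
        guess; with ``multistart > 0``, that many extra seeded random
        starts are tried and the best solution kept. Deterministic given
        (multistart, seed).
        """
        free = list(self.free_parameters)
        flags: list[str] = []
        pinned: dict[str, float] = {}
        if (
            "compressibility_index" in free
            and not self.compressibility_identifiable()
        ):
            free.remove("compressibility_index")
            pinned["compressibility_index"] = 0.0
            flags.append(
                "compressibility_unidentifiable: all experiments share one "
                "driving force; n pinned to 0"
            )
            if not free:
                raise InvalidArgumentError(
                    "compressibility is the only free parameter but is "
                    "unidentifiable at a single driving pressure"
                )

        fixed = {**self._fixed_values(), **pinned}

        def residual_vec(x: np.ndarray) -> np.ndarray:
            params = dict(fixed)
            params.update(
                {name: self._decode(name, xi) for name, xi in zip(free, x)}
            )
            return self._residuals(params)

        x0 = np.array(
            [self._encode(p, self.initial_guess[p]) for p in free]
        )
        lo = np.array([self._encode(p, self.bounds[p][0]) for p in free])
        hi = np.array([self._encode(p, self.bounds[p][1]) for p in free])

        try:
            residual_vec(x0)
        except Exception as exc:  # simulator failed at the initial guess
            raise InvalidStateError(
                f"forward model failed at the initial guess: {exc}"
            ) from exc

        starts = [x0]
        if multistart > 0:
            rng = np.random.default_rng(seed)
            starts += [
                lo + (hi - lo) * rng.random(len(free))
                for _ in range(multistart)
            ]
        best = None
        for start in starts:
            sol = least_squares(
                residual_vec, start, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol

        estimates = dict(fixed)
        estimates.update(
            {name: self._decode(name, xi) for name, xi in zip(free, best.x)}
        )
        per_exp = []
        for exp in self.experiments:
            scen = _apply_parameters(exp.scenario, estimates)
            v_sim = predict_volumes(scen, exp.times)
            per_exp.append(v_sim - exp.volumes)
        return EstimationResult(
            problem=self,
            estimates={p: estimates[p] for p in self.free_parameters
                       if p in free or p in pinned},
            all_parameters=estimates,
            objective_value=float(2.0 * best.cost),  # cost = 0.5 sum r^2
            per_experiment_residuals=per_exp,
            converged=bool(best.success),
            identifiability_flags=tuple(flags),
            n_function_evaluations=int(best.nfev),
        )


def estimate_parameters(problem: EstimationProblem, **kwargs) -> "EstimationResult":
    """Functional alias for :meth:`EstimationProblem.fit`."""
    return problem.fit(**kwargs)


@dataclass(frozen=True)
class EstimationResult:
    """Fitted parameters, diagnostics and residuals."""

    problem: EstimationProblem
    estimates: dict[str, float]
    all_parameters: dict[str, float]
    objective_value: float
    per_experiment_residuals: list[np.ndarray]
    converged: bool
    identifiability_flags: tuple[str, ...]
    n_function_evaluations: int

    def scenario_with_estimates(self, index: int = 0) -> Scenario:
        """Experiment `index`'s scenario with the fitted parameters applied."""
        return _apply_parameters(
            self.problem.experiments[index].scenario, self.all_parameters
        )

    def summary(self) -> str:
        lines = [
            "Filtration parameter estimation",
            "=" * 47,
            f"experiments:        {len(self.problem.experiments)}",
            f"driving pressures:  "
            + ", ".join(f"{p / 100:.0f} mbar" for p in self.problem.pressures()),
            f"objective (SSR):    {self.objective_value:.6g}",
            f"converged:          {self.converged}",
            f"function evals:     {self.n_function_evaluations}",
            "-" * 47,
            f"{'parameter':<24}{'estimate':>12}",
        ]
        units = {"medium_resistance": " 1/m"}
        for name, value in self.estimates.items():
            lines.append(f"{name:<24}{value:>12.5g}{units.get(name, '')}")
        for flag in self.identifiability_flags:
            lines.append(f"note: {flag}")
        return "\n".join(lines)
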