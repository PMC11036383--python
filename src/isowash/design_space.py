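"""Design-space sweeps, knee detection and wash-plan optimization.

The design question behind API isolation is how much wash solvent to
spend, and whether to spend it in one large aliquot or several small
ones. This module evaluates the integrated filtration + washing pipeline
over grids of wash volumes (and optionally the number of washes or the
cake Peclet number), finds the *knee* of the wash-volume vs impurity
curve — the volume beyond which the marginal impurity reduction per mL
becomes negligible — and searches for the impurity-minimizing split of a
solvent budget over up to three wash stages.

Responses are impurity concentrations in the final cake liquor in kg per
m3 of liquor. For the well-mixed feed-and-bleed mechanism the response to
a single wash of volume V is exactly ``c0 exp(-V / V_void)``, which makes
that mechanism split-invariant: any partition of a total volume gives the
same final purity. The accumulate (no-outflow) mode is split-sensitive:
equal splits beat one large dilution, since
``prod_i V0/(V0 + V_i) < V0/(V0 + sum V_i)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidSweepError
from .filtration import CakeState, simulate_filtration
from .materials import LiquidComposition
from .scenarios import Scenario
from .washing import WashStage, run_wash_program

SWEEP_VARIABLES = (
    "wash1_volume",
    "wash2_volume",
    "wash3_volume",
    "n_washes",
    "peclet",
)


@dataclass(frozen=True)
class SweepSpec:
    """A full-factorial design-space sweep over wash-program variables.

    ``variables`` maps names from :data:`SWEEP_VARIABLES` to strictly
    increasing grids; volumes in m3. ``response_species`` defaults to the
    impurity species dissolved in the mother liquor.
    """

    scenario: Scenario
    variables: tuple[tuple[str, tuple[float, ...]], ...]
    mechanism: str = "well_mixed"
    mixed_mode: str = "feed_and_bleed"
    peclet: float | None = None
    response_species: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.variables:
            raise InvalidArgumentError("sweep needs at least one variable")
        for name, grid in self.variables:
            if name not in SWEEP_VARIABLES:
                raise InvalidArgumentError(
                    f"unknown sweep variable {name!r}; "
                    f"expected among {SWEEP_VARIABLES}"
                )
            g = np.asarray(grid, dtype=float)
            if g.ndim != 1 or len(g) == 0 or np.any(np.diff(g) <= 0):
                raise InvalidArgumentError(
                    f"grid for {name!r} must be non-empty and strictly "
                    "increasing"
                )


@dataclass(frozen=True)
class SweepResult:
    """Tidy table of sweep evaluations plus provenance."""

    table: pd.DataFrame
    variable_names: tuple[str, ...]
    response_names: tuple[str, ...]
    provenance: dict


def _tracked_impurities(scenario: Scenario) -> tuple[str, ...]:
    db = scenario.species_db
    return tuple(
        name
        for name in scenario.suspension.liquor.species
        if scenario.suspension.liquor.fraction(name) > 0
        and db[name].role == "impurity"
    )


def _stage_compositions(scenario: Scenario, n: int) -> list[LiquidComposition]:
    """Stage wash compositions: the scenario's program where defined,
    pure wash solvent beyond it."""
    program = scenario.wash_program
    comps = [s.wash_composition for s in program]
    if not comps:
        raise InvalidArgumentError("scenario has no wash program")
    last = comps[-1]
    while len(comps) < n:
        comps.append(last)
    return comps[:n]


def _final_concentrations(
    cake: CakeState, scenario: Scenario, volumes: Sequence[float],
    mechanism: str, mixed_mode: str, peclet: float | None,
    species: Sequence[str],
) -> dict[str, float]:
    """Impurity concentrations (kg/m3 liquor) after washing `cake` with
    the given per-stage volumes."""
    active = [v for v in volumes if v > 0]
    if not active:
        current = cake
    else:
        comps = _stage_compositions(scenario, len(active))
        stages = [
            WashStage(
                wash_composition=comp,
                mechanism=mechanism,
                volume=v,
                mixed_mode=mixed_mode,
                peclet=peclet,
            )
            for v, comp in zip(active, comps)
        ]
        current = run_wash_program(
            cake, stages, scenario.species_db, curve_points=0
        ).final_cake
    masses = current.species_masses()
    vol = current.liquor_volume
    return {name: masses.get(name, 0.0) / vol for name in species}


def sweep_design_space(spec: SweepSpec) -> SweepResult:
    """Evaluate the filtration + washing pipeline on the full grid.

    Filtration is independent of the wash variables, so the dryland cake
    is computed once. Grid points whose evaluation fails are recorded
    with NaN responses and the diagnostic message; the sweep continues.
    Deterministic: rerunning a spec reproduces the table bit-for-bit.
    """
    scenario = spec.scenario
    cake = simulate_filtration(scenario).end_state
    species = spec.response_species or _tracked_impurities(scenario)
    if not species:
        raise InvalidArgumentError("no impurity species to track")
    names = [name for name, _ in spec.variables]
    grids = [grid for _, grid in spec.variables]
    rows = []
    for combo in itertools.product(*grids):
        point = dict(zip(names, combo))
        n_washes = int(point.get("n_washes", 0)) or None
        volumes = [
            point.get("wash1_volume", 0.0),
            point.get("wash2_volume", 0.0),
            point.get("wash3_volume", 0.0),
        ]
        if n_washes is not None:
            volumes = volumes[:n_washes]
        peclet = point.get("peclet", spec.peclet)
        row = dict(point)
        try:
            conc = _final_concentrations(
                cake, scenario, volumes, spec.mechanism, spec.mixed_mode,
                peclet, species,
            )
            for name in species:
                row[f"impurity_conc_{name}"] = conc[name]
            row["total_solvent_used"] = float(sum(v for v in volumes if v > 0))
            row["error"] = ""
        except Exception as exc:  # record and continue
            for name in species:
                row[f"impurity_conc_{name}"] = math.nan
            row["total_solvent_used"] = math.nan
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(
        table=table,
        variable_names=tuple(names),
        response_names=tuple(f"impurity_conc_{s}" for s in species),
        provenance={
            "scenario": scenario.name,
            "mechanism": spec.mechanism,
            "mixed_mode": spec.mixed_mode,
            "peclet": peclet if spec.mechanism == "dispersion" else None,
        },
    )


@dataclass(frozen=True)
class KneeResult:
    """Knee of a single-variable sweep."""

    volume: float  # m3
    threshold: float
    degenerate: bool  # flat response or no interval below threshold
    note: str = ""


def knee_volume(
    result: SweepResult,
    threshold: float = 0.05,
    species: str | None = None,
    baseline: tuple[float, float] | None = None,
) -> KneeResult:
    """Smallest volume where the marginal impurity reduction goes flat.

    The per-mL reduction rate over each grid interval is compared with
    the rate over the first interval; the knee is the left endpoint of
    the first interval whose rate drops below ``threshold`` times the
    initial rate. For an exponential response ``c0 exp(-V/V*)`` this
    converges to ``V* ln(1/threshold)`` as the grid refines.

    `baseline` optionally prepends an unswept point, typically
    ``(0.0, unwashed_concentration)``, so the initial rate is measured
    from the unwashed cake. The response must be monotone non-increasing.
    """
    if not (0 < threshold < 1):
        raise InvalidArgumentError("threshold must be in (0, 1)")
    if len(result.variable_names) != 1:
        raise InvalidSweepError("knee detection needs a single-variable sweep")
    if species is None:
        column = result.response_names[0]
    else:
        column = f"impurity_conc_{species}"
    var = result.variable_names[0]
    v = result.table[var].to_numpy(dtype=float)
    c = result.table[column].to_numpy(dtype=float)
    if baseline is not None:
        v = np.concatenate([[float(baseline[0])], v])
        c = np.concatenate([[float(baseline[1])], c])
    if np.any(~np.isfinite(c)):
        raise InvalidSweepError("sweep contains failed grid points")
    if np.any(np.diff(c) > 1e-12 * max(abs(c[0]), 1e-300)):
        raise InvalidSweepError("response must be monotone non-increasing")
    rates = -np.diff(c) / np.diff(v)
    initial = rates[0]
    if initial <= 0:
        return KneeResult(
            volume=float(v[1]), threshold=threshold, degenerate=True,
            note="flat response; no impurity reduction at any volume",
        )
    below = np.nonzero(rates < threshold * initial)[0]
    below = below[below >= 1]
    if len(below) == 0:
        return KneeResult(
            volume=float(v[-1]), threshold=threshold, degenerate=True,
            note="marginal reduction never fell below threshold on this grid",
        )
    return KneeResult(
        volume=float(v[below[0]]), threshold=threshold, degenerate=False
    )


def compare_wash_splits(
    scenario: Scenario,
    total_volume: float,
    n_washes: Sequence[int] = (1, 2, 3),
    mechanism: str = "well_mixed",
    mixed_mode: str = "feed_and_bleed",
    peclet: float | None = None,
    species: str | None = None,
) -> pd.DataFrame:
    """Final impurity concentration for equal splits of a total volume.

    One row per split count: the total wash volume is divided into k
    equal aliquots and the program evaluated end to end. Feed-and-bleed
    washing is split-invariant (identical purity for every k); the
    accumulate mode strictly rewards splitting.
    """
    if not total_volume > 0:
        raise InvalidArgumentError("total_volume must be > 0")
    cake = simulate_filtration(scenario).end_state
    tracked = [species] if species else list(_tracked_impurities(scenario))
    rows = []
    for k in n_washes:
        if k < 1:
            raise InvalidArgumentError("n_washes entries must be >= 1")
        volumes = [total_volume / k] * k
        conc = _final_concentrations(
            cake, scenario, volumes, mechanism, mixed_mode, peclet, tracked
        )
        row = {"n_washes": k, "stage_volume": total_volume / k,
               "total_volume": total_volume}
        for name in tracked:
            row[f"impurity_conc_{name}"] = conc[name]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WashPlan:
    """An impurity-minimizing wash plan found by exhaustive search."""

    volumes: tuple[float, ...]  # m3 per stage
    impurity_concentration: float  # kg/m3 liquor, primary species
    final_composition: LiquidComposition
    species: str
    mechanism: str

    @property
    def n_washes(self) -> int:
        return len(self.volumes)

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes))


def optimize_wash_plan(
    scenario: Scenario,
    solvent_budget: float,
    max_washes: int = 3,
    mechanism: str = "well_mixed",
    mixed_mode: str = "feed_and_bleed",
    peclet: float | None = None,
    species: str | None = None,
    grid_steps: int = 20,
) -> WashPlan:
    """Search per-stage volumes (summing to <= budget) minimizing the
    final impurity concentration.

    Exhaustive enumeration on a ``budget / grid_steps`` volume grid over
    1..`max_washes` stages. Responses are monotone in each stage volume
    for every mechanism, so the optimum spends the full budget; ties
    (e.g. the split-invariant feed-and-bleed mechanism) are broken toward
    the fewest stages, then lexicographically largest first stage.
    """
    if not solvent_budget > 0:
        raise InvalidArgumentError("solvent_budget must be > 0")
    if not 1 <= max_washes <= 3:
        raise InvalidArgumentError("max_washes must be between 1 and 3")
    step = solvent_budget / grid_steps
    if step <= 0:
        raise InvalidArgumentError("budget below one grid step")
    cake = simulate_filtration(scenario).end_state
    tracked = species or (_tracked_impurities(scenario) or (None,))[0]
    if tracked is None:
        raise InvalidArgumentError("no impurity species to minimize")

    best: tuple | None = None  # (volumes, conc)
    rtol = 1e-9  # concentrations this close count as a tie
    for k in range(1, max_washes + 1):
        for units in itertools.product(range(grid_steps + 1), repeat=k):
            if sum(units) > grid_steps or min(units) == 0:
                continue
            volumes = tuple(u * step for u in units)
            conc = _final_concentrations(
                cake, scenario, volumes, mechanism, mixed_mode, peclet,
                [tracked],
            )[tracked]
            if best is None:
                best = (volumes, conc)
                continue
            b_vol, b_conc = best
            scale = max(abs(b_conc), abs(conc), 1e-300)
            if conc < b_conc - rtol * scale:
                best = (volumes, conc)
            elif abs(conc - b_conc) <= rtol * scale:
                # tie: prefer fewer stages, then the front-loaded plan
                if (len(volumes), tuple(-v for v in volumes)) < (
                    len(b_vol), tuple(-v for v in b_vol)
                ):
                    best = (volumes, conc)
    if best is None:
        raise InvalidArgumentError("no feasible plan on the search grid")
    volumes, conc = best
    final = _final_cake(cake, scenario, volumes, mechanism, mixed_mode, peclet)
    return WashPlan(
        volumes=volumes,
        impurity_concentration=conc,
        final_composition=final.liquor,
        species=tracked,
        mechanism=mechanism,
    )


def _final_cake(cake, scenario, volumes, mechanism, mixed_mode, peclet):
    comps = _stage_compositions(scenario, len(volumes))
    stages = [
        WashStage(
            wash_composition=comp, mechanism=mechanism, volume=v,
            mixed_mode=mixed_mode, peclet=peclet,
        )
        for v, comp in zip(volumes, comps)
    ]
    return run_wash_program(
        cake, stages, scenario.species_db, curve_points=0
    ).final_cake
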