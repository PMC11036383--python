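"""Constant-pressure dead-end cake filtration to dryland.

The cake resistance comes from Carman-Kozeny theory,

    alpha = 180 (1 - eps) / (rho_s psi^2 x^2 eps^3)      [m/kg]

with porosity ``eps``, sphericity ``psi``, mean particle size ``x`` and
crystal density ``rho_s``. Compressible cakes scale the resistance with a
power law in the driving pressure, ``alpha(dP) = alpha_ref (dP/dP_ref)^n``.

At constant driving pressure the filtrate volume obeys the classic Darcy
cake-filtration relation

    dV/dt = dP A^2 / (mu (alpha w V + Rm A)),

whose integral is the quadratic

    t(V) = (mu / (A dP)) (alpha w V^2 / (2 A) + Rm V),

where ``w`` is the dry solid mass deposited per unit filtrate volume.
Because dP is constant, the compressible case only rescales ``alpha``, so
the closed form is exact and the simulator evaluates it directly rather
than integrating numerically. Filtration stops at *dryland*: the point
where the free liquid above the cake is exhausted and the cake pores are
left saturated with mother liquor. The dryland filtrate volume is the
suspension liquor volume minus the cake void volume, which also fixes
``w`` self-consistently.

The module also provides the two data-reduction fits used on experimental
series: the Darcy linearization (t/V against V) extracting (alpha, Rm),
and the ln alpha - ln dP regression extracting the compressibility index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    InvalidSeriesError,
    InvalidStateError,
)
from .materials import (
    LiquidComposition,
    ParticlePopulation,
    SpeciesTable,
    Suspension,
    mixture_properties,
)

DEFAULT_REFERENCE_PRESSURE = 1.0e5  # Pa (1 bar)

#: Compressibility classification bands on the power-law index n.
#: Pharmaceutical cakes are typically low-to-moderately compressible.
COMPRESSIBILITY_BANDS = (
    (1.0, "low/moderate"),   # n < 1
    (10.0, "high"),          # 1 <= n < 10
    (math.inf, "extreme"),   # n >> 1; the high/extreme border is fuzzy
)


@dataclass(frozen=True)
class FilterSpec:
    """Filter geometry and medium."""

    diameter: float  # m
    medium_resistance: float  # 1/m
    equipment_volume: float | None = None  # m3

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise InvalidArgumentError("filter diameter must be > 0")
        if self.medium_resistance < 0:
            raise InvalidArgumentError(
                "medium_resistance must be >= 0 for simulation; negative "
                "fitted values are reported by darcy_fit but rejected here"
            )

    @property
    def area(self) -> float:
        """Filtration area pi d^2 / 4 (m2)."""
        return math.pi * self.diameter**2 / 4.0


@dataclass(frozen=True)
class OperatingConditions:
    driving_force: float  # Pa
    temperature: float = 25.0  # degC

    def __post_init__(self) -> None:
        if not self.driving_force > 0:
            raise InvalidArgumentError("driving_force must be > 0")


@dataclass(frozen=True)
class CakeProperties:
    """Cake structure parameters entering the resistance model.

    ``alpha_ref`` is the specific cake resistance at ``reference_pressure``.
    When omitted it is computed from Carman-Kozeny theory using the
    scenario's particle population, and the power-law compressibility
    scaling is applied about the reference pressure.
    """

    porosity: float
    sphericity: float
    compressibility_index: float = 0.0
    reference_pressure: float = DEFAULT_REFERENCE_PRESSURE
    alpha_ref: float | None = None  # m/kg

    def __post_init__(self) -> None:
        if not (0 < self.porosity < 1):
            raise InvalidArgumentError("porosity must be in (0, 1)")
        if not (0 < self.sphericity <= 1):
            raise InvalidArgumentError("sphericity must be in (0, 1]")
        if self.compressibility_index < 0:
            raise InvalidArgumentError("compressibility_index must be >= 0")
        if not self.reference_pressure > 0:
            raise InvalidArgumentError("reference_pressure must be > 0")


@dataclass(frozen=True)
class CakeState:
    """A filter cake and the liquor it holds.

    At dryland the pores are exactly saturated (``saturation = 1``) and
    ``liquor_volume`` equals the void volume. The well-mixed accumulate
    washing mode can push ``liquor_volume`` beyond the voids (no outflow);
    the excess is tracked here while ``saturation`` stays capped at 1.
    """

    solid_mass: float  # kg
    solid_density: float  # kg/m3
    porosity: float
    area: float  # m2
    liquor: LiquidComposition
    liquor_mass: float  # kg
    liquor_volume: float  # m3

    def __post_init__(self) -> None:
        if self.solid_mass < 0 or self.liquor_mass < 0:
            raise InvalidArgumentError("cake masses must be >= 0")

    @property
    def solid_volume(self) -> float:
        return self.solid_mass / self.solid_density

    @property
    def bulk_volume(self) -> float:
        return self.solid_volume / (1.0 - self.porosity)

    @property
    def void_volume(self) -> float:
        return self.porosity * self.bulk_volume

    @property
    def height(self) -> float:
        """Cake height L = solid_volume / ((1 - eps) A)."""
        return self.solid_volume / ((1.0 - self.porosity) * self.area)

    @property
    def saturation(self) -> float:
        if self.void_volume == 0:
            return 0.0
        return min(1.0, self.liquor_volume / self.void_volume)

    @property
    def wet_mass(self) -> float:
        return self.solid_mass + self.liquor_mass

    def species_masses(self) -> dict[str, float]:
        """Dissolved species masses in the pore liquor (kg)."""
        return {
            name: w * self.liquor_mass for name, w in self.liquor.items()
        }


@dataclass(frozen=True)
class FiltrationResult:
    """Simulated constant-pressure filtration run."""

    times: np.ndarray  # s, strictly increasing
    filtrate_volumes: np.ndarray  # m3, non-decreasing
    filtrate_density: float  # kg/m3
    viscosity: float  # Pa s
    alpha_used: float  # m/kg at the applied driving force
    medium_resistance: float  # 1/m
    solids_per_volume: float  # w, kg dry solids per m3 filtrate
    stopped_at: str  # 'dryland' | 'max_time'
    end_state: CakeState | None
    scenario_name: str = ""

    @property
    def filtrate_mass(self) -> float:
        return float(self.filtrate_volumes[-1]) * self.filtrate_density

    def to_frame(self) -> pd.DataFrame:
        """Series as a DataFrame in interface units (s, mL, g)."""
        v = np.asarray(self.filtrate_volumes)
        return pd.DataFrame(
            {
                "time_s": self.times,
                "filtrate_volume_ml": v * 1e6,
                "filtrate_mass_g": v * self.filtrate_density * 1e3,
            }
        )

    def plot(self, ax=None):
        """Quick-look Darcy plot (cumulative filtrate volume vs time)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, np.asarray(self.filtrate_volumes) * 1e6, "-")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("cumulative filtrate volume (mL)")
        ax.set_title(self.scenario_name or "filtration")
        return ax


def carman_kozeny_alpha(
    particles: ParticlePopulation, porosity: float, solid_density: float
) -> float:
    """Specific cake resistance from Carman-Kozeny theory (m/kg)."""
    if not (0 < porosity < 1):
        raise InvalidArgumentError("porosity must be in (0, 1)")
    if not solid_density > 0:
        raise InvalidArgumentError("solid_density must be > 0")
    x = particles.mean_size_m
    psi = particles.sphericity
    return 180.0 * (1.0 - porosity) / (
        solid_density * psi**2 * x**2 * porosity**3
    )


def alpha_at_pressure(props: CakeProperties, driving_force: float) -> float:
    """Power-law compressibility scaling of the specific cake resistance."""
    if not driving_force > 0:
        raise InvalidArgumentError("driving_force must be > 0")
    if props.alpha_ref is None:
        raise InvalidArgumentError(
            "CakeProperties.alpha_ref is not set; use scenario_alpha() to "
            "derive it from Carman-Kozeny theory"
        )
    ratio = driving_force / props.reference_pressure
    return props.alpha_ref * ratio**props.compressibility_index


@dataclass(frozen=True)
class CompressibilityFit:
    """Result of the ln alpha vs ln dP regression."""

    n: float
    alpha_ref: float  # m/kg at reference_pressure
    reference_pressure: float
    label: str
    identifiable: bool

    def classify(self) -> str:
        return self.label


def classify_compressibility(n: float) -> str:
    """Band label for a compressibility index."""
    for upper, label in COMPRESSIBILITY_BANDS:
        if n < upper:
            return label
    return COMPRESSIBILITY_BANDS[-1][1]


def fit_compressibility(
    pairs: Sequence[tuple[float, float]],
    reference_pressure: float = DEFAULT_REFERENCE_PRESSURE,
) -> CompressibilityFit:
    """Least-squares compressibility index from (dP, alpha) pairs.

    The index is the slope of ln(alpha) against ln(dP). With a single
    distinct pressure the slope is unidentifiable; the fit then reports
    n = 0 with ``identifiable=False`` and the geometric-mean alpha.
    """
    if len(pairs) < 2:
        raise InvalidArgumentError("need at least two (dP, alpha) pairs")
    dp = np.asarray([p for p, _ in pairs], dtype=float)
    alpha = np.asarray([a for _, a in pairs], dtype=float)
    if np.any(dp <= 0) or np.any(alpha <= 0):
        raise InvalidArgumentError("pressures and resistances must be > 0")
    log_dp, log_a = np.log(dp), np.log(alpha)
    if np.allclose(log_dp, log_dp[0]):
        alpha_ref = float(np.exp(log_a.mean()))
        return CompressibilityFit(
            0.0, alpha_ref, reference_pressure, classify_compressibility(0.0),
            identifiable=False,
        )
    slope, intercept = np.polyfit(log_dp, log_a, 1)
    n = float(slope)
    alpha_ref = float(np.exp(intercept + n * math.log(reference_pressure)))
    return CompressibilityFit(
        n, alpha_ref, reference_pressure, classify_compressibility(n),
        identifiable=True,
    )


# ---------------------------------------------------------------------------
# Forward simulation


def scenario_alpha(scenario) -> float:
    """Specific cake resistance at the scenario's driving force.

    If the cake properties carry an explicit ``alpha_ref`` it is scaled by
    the compressibility power law; otherwise the Carman-Kozeny value
    (computed with the cake's fitted porosity/sphericity and the particle
    mean size) serves as the resistance at the reference pressure.
    """
    props = scenario.cake_properties
    if props.alpha_ref is None:
        particles = replace(
            scenario.suspension.particles, sphericity=props.sphericity
        )
        alpha_ref = carman_kozeny_alpha(
            particles,
            props.porosity,
            scenario.suspension.solid_species.solid_density,
        )
        props = replace(props, alpha_ref=alpha_ref)
    return alpha_at_pressure(props, scenario.conditions.driving_force)


@dataclass(frozen=True)
class _Hydraulics:
    """Precomputed constant-pressure filtration coefficients.

    t(V) = a V^2 + b V with a = mu alpha w / (2 A^2 dP), b = mu Rm / (A dP).
    """

    a: float
    b: float
    v_end: float
    t_end: float
    alpha: float
    w: float
    rho: float
    mu: float


def _hydraulics(scenario) -> _Hydraulics:
    susp: Suspension = scenario.suspension
    db: SpeciesTable = scenario.species_db
    area = scenario.filter.area
    dp = scenario.conditions.driving_force
    rm = scenario.filter.medium_resistance
    rho, mu = mixture_properties(susp.liquor, db)

    # equipment_volume is capacity metadata (batches may be charged in
    # portions); it does not gate the simulation
    liquor_volume = susp.liquor_mass / rho
    if susp.solid_mass > 0:
        eps = scenario.cake_properties.porosity
        solid_volume = susp.solid_mass / susp.solid_species.solid_density
        void_volume = eps / (1.0 - eps) * solid_volume
        v_end = liquor_volume - void_volume
        if v_end <= 0:
            raise InvalidArgumentError(
                "cake voids would hold the entire liquor; dryland is "
                "unreachable (check porosity and masses)"
            )
        w = susp.solid_mass / v_end
        alpha = scenario_alpha(scenario)
    else:
        v_end = liquor_volume
        w = 0.0
        alpha = 0.0
    a = mu * alpha * w / (2.0 * area**2 * dp)
    b = mu * rm / (area * dp)
    t_end = a * v_end**2 + b * v_end
    return _Hydraulics(a, b, v_end, t_end, alpha, w, rho, mu)


def predict_volumes(scenario, times: np.ndarray) -> np.ndarray:
    """Filtrate volume V(t) for the scenario, capped at the dryland volume.

    Inverts t = a V^2 + b V analytically; used by the calibration module
    where the forward model is evaluated at observed times.
    """
    h = _hydraulics(scenario)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidArgumentError("times must be >= 0")
    if h.a > 0:
        v = (-h.b + np.sqrt(h.b**2 + 4.0 * h.a * t)) / (2.0 * h.a)
    elif h.b > 0:
        v = t / h.b
    else:
        raise InvalidArgumentError(
            "both cake and medium resistance are zero; flow is unbounded"
        )
    return np.minimum(v, h.v_end)


def simulate_filtration(
    scenario, n_points: int = 200, max_time: float | None = None
) -> FiltrationResult:
    """Simulate constant-pressure filtration of the scenario to dryland.

    Returns the monotone V(t) series on `n_points` volumes evenly spaced
    from zero to the dryland volume (or to the volume reached at
    `max_time`), the resistances used, and - when dryland is reached -
    the saturated :class:`CakeState`.
    """
    if n_points < 2:
        raise InvalidArgumentError("n_points must be >= 2")
    h = _hydraulics(scenario)
    stopped_at = "dryland"
    v_stop = h.v_end
    if max_time is not None and max_time < h.t_end:
        stopped_at = "max_time"
        v_stop = float(predict_volumes_from(h, np.array([max_time]))[0])
    volumes = np.linspace(0.0, v_stop, n_points)
    times = h.a * volumes**2 + h.b * volumes

    end_state = None
    if stopped_at == "dryland" and scenario.suspension.solid_mass > 0:
        end_state = _dryland_cake(scenario, h.rho)
    return FiltrationResult(
        times=times,
        filtrate_volumes=volumes,
        filtrate_density=h.rho,
        viscosity=h.mu,
        alpha_used=h.alpha,
        medium_resistance=scenario.filter.medium_resistance,
        solids_per_volume=h.w,
        stopped_at=stopped_at,
        end_state=end_state,
        scenario_name=getattr(scenario, "name", ""),
    )


def predict_volumes_from(h: _Hydraulics, times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if h.a > 0:
        v = (-h.b + np.sqrt(h.b**2 + 4.0 * h.a * t)) / (2.0 * h.a)
    else:
        v = t / h.b
    return np.minimum(v, h.v_end)


def _dryland_cake(scenario, rho_liquor: float) -> CakeState:
    susp = scenario.suspension
    eps = scenario.cake_properties.porosity
    solid_volume = susp.solid_mass / susp.solid_species.solid_density
    void_volume = eps / (1.0 - eps) * solid_volume
    return CakeState(
        solid_mass=susp.solid_mass,
        solid_density=susp.solid_species.solid_density,
        porosity=eps,
        area=scenario.filter.area,
        liquor=susp.liquor,
        liquor_mass=void_volume * rho_liquor,
        liquor_volume=void_volume,
    )


def dryland_state(result: FiltrationResult) -> CakeState:
    """The saturated cake at the dryland stopping point.

    Cake geometry follows from the dry solid mass, crystal density,
    porosity and filter area; the retained liquor fills the voids exactly
    and keeps the mother-liquor composition (no washing has happened).
    """
    if result.stopped_at != "dryland" or result.end_state is None:
        raise InvalidStateError(
            "filtration did not stop at dryland; no saturated cake state"
        )
    return result.end_state


# ---------------------------------------------------------------------------
# Experimental data reduction


@dataclass(frozen=True)
class DarcyFit:
    """Result of the t/V vs V linearization of a filtrate series."""

    alpha: float  # m/kg
    medium_resistance: float  # 1/m
    slope: float  # s/m6
    intercept: float  # s/m3
    negative_medium_resistance: bool

    def warnings(self) -> list[str]:
        if self.negative_medium_resistance:
            return [
                "fitted medium resistance is negative (commonly caused by "
                "pre-settled cake on the medium); reported verbatim but "
                "unusable for forward simulation"
            ]
        return []


def darcy_fit(
    times: np.ndarray,
    volumes: np.ndarray,
    area: float,
    driving_force: float,
    viscosity: float,
    solids_per_volume: float,
) -> DarcyFit:
    """Extract (alpha, Rm) from a constant-pressure filtrate series.

    Regresses t/V against V: the slope is mu alpha w / (2 A^2 dP) and the
    intercept mu Rm / (A dP). Points with V = 0 are dropped. Negative
    intercepts (pre-settling artefacts) are reported verbatim with a flag.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise InvalidSeriesError("times and volumes must be 1-D and aligned")
    keep = v > 0
    t, v = t[keep], v[keep]
    if len(v) < 3:
        raise InvalidSeriesError("need at least 3 points with V > 0")
    if np.any(np.diff(v) <= 0):
        raise InvalidSeriesError("volumes must be strictly increasing")
    if not (area > 0 and driving_force > 0 and viscosity > 0):
        raise InvalidArgumentError("area, driving_force, viscosity must be > 0")
    if not solids_per_volume > 0:
        raise InvalidArgumentError("solids_per_volume must be > 0")
    slope, intercept = np.polyfit(v, t / v, 1)
    alpha = slope * 2.0 * area**2 * driving_force / (
        viscosity * solids_per_volume
    )
    rm = intercept * area * driving_force / viscosity
    return DarcyFit(
        alpha=float(alpha),
        medium_resistance=float(rm),
        slope=float(slope),
        intercept=float(intercept),
        negative_medium_resistance=bool(rm < 0),
    )
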