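"""Case-study scenario fixtures and synthetic-observation generators.

Two published isolation case studies ship as runnable fixtures:

* ``mfa_expt1`` .. ``mfa_expt9`` — mefenamic acid (MFA) crystallized from
  ethyl acetate or a diglyme-water blend, washed with heptane or
  cyclohexane, with chlorobenzoic acid (CBA), copper(II) acetate and
  2,3-dimethylaniline as synthesis impurities. Filtered on a 27 mm
  Biotage-type dead-end unit from a 47.7 g batch (4.34 g solids).
* ``pcm_expt1`` .. ``pcm_expt9`` — paracetamol (PCM) from ethanol or
  isoamyl alcohol, washed with dodecane or isopropyl acetate, with
  acetanilide and metacetamol impurities. 24 mm filter, 65 g batch, per-
  experiment solid load (15-25 % w/w).

Each fixture carries the experiment's driving pressure, wash ratio and
stage count, the calibrated cake parameters (sphericity, porosity,
medium resistance, compressibility index) for its solvent pair, and a
wash program whose first stage is the anti-solvent-safe crystallization/
wash solvent blend with later stages of pure wash solvent.

The source studies publish no solvent or solid physical properties, so a
literature table at 25 degC ships here (`default_species_table`); every
value can be overridden per scenario. The diglyme-water crystallization
liquor is carried as a single pseudo-solvent at the fixed 89:11 weight
ratio, since none of the models resolve the two components separately.

Synthetic observations (`generate_filtration_observations`,
`generate_wash_observations`) stand in for unpublished raw data: they
forward-simulate a scenario and apply seeded multiplicative Gaussian
noise, reproducible bit-for-bit from (scenario, noise_sd, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .filtration import (
    CakeProperties,
    FilterSpec,
    OperatingConditions,
    simulate_filtration,
)
from .materials import (
    LiquidComposition,
    ParticlePopulation,
    Species,
    SpeciesTable,
    Suspension,
    volume_fractions_to_mass,
)
from .units import g_to_kg, mbar_to_pa, ml_to_m3, mm_to_m
from .washing import WashStage, run_wash_program


def default_species_table() -> SpeciesTable:
    """Literature physical properties at 25 degC.

    Densities in kg/m3, viscosities in Pa s. Dissolved solids (API and
    impurities) get melt-like liquid densities equal to their crystal
    densities and a nominal 5 mPa s viscosity contribution; they are
    minority components of every liquor, so the mixture viscosity is
    dominated by the measured solvent values.
    """
    return SpeciesTable(
        [
            # solvents
            Species("ethyl_acetate", "crystallization_solvent", 894.0, 4.23e-4),
            # diglyme:water 89:11 by weight, treated as one pseudo-solvent
            Species("diglyme_water", "crystallization_solvent", 948.7, 9.78e-4),
            Species("ethanol", "crystallization_solvent", 789.0, 1.07e-3),
            Species("isoamyl_alcohol", "crystallization_solvent", 810.0, 3.68e-3),
            Species("heptane", "wash_solvent", 679.5, 3.86e-4),
            Species("cyclohexane", "wash_solvent", 773.9, 8.90e-4),
            Species("dodecane", "wash_solvent", 749.0, 1.34e-3),
            Species("isopropyl_acetate", "wash_solvent", 870.0, 4.90e-4),
            # APIs
            Species("mefenamic_acid", "api", 1260.0, 5.0e-3, solid_density=1260.0),
            Species("paracetamol", "api", 1293.0, 5.0e-3, solid_density=1293.0),
            # impurities
            Species("cba", "impurity", 1544.0, 5.0e-3),
            Species("copper_acetate", "impurity", 1880.0, 5.0e-3),
            Species("dimethylaniline", "impurity", 993.0, 3.3e-3),
            Species("acetanilide", "impurity", 1219.0, 5.0e-3),
            Species("metacetamol", "impurity", 1293.0, 5.0e-3),
        ]
    )


@dataclass(frozen=True)
class Scenario:
    """One isolation experiment: feed, filter, conditions, wash program."""

    name: str
    suspension: Suspension
    filter: FilterSpec
    conditions: OperatingConditions
    cake_properties: CakeProperties
    wash_program: tuple[WashStage, ...]
    species_db: SpeciesTable
    provenance: str = ""

    def with_updates(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


# --- MFA case study -------------------------------------------------------

# expt -> (crystallization solvent, wash solvent, pressure mbar,
#          wash ratio, number of washes)
_MFA_DESIGN = {
    1: ("ethyl_acetate", "cyclohexane", 100.0, 2.0, 3),
    2: ("diglyme_water", "heptane", 600.0, 2.0, 3),
    3: ("ethyl_acetate", "heptane", 600.0, 2.0, 2),
    4: ("ethyl_acetate", "heptane", 100.0, 4.0, 2),
    5: ("diglyme_water", "cyclohexane", 100.0, 4.0, 2),
    6: ("diglyme_water", "cyclohexane", 350.0, 3.0, 3),
    7: ("diglyme_water", "cyclohexane", 350.0, 3.0, 3),
    8: ("diglyme_water", "heptane", 100.0, 4.0, 3),
    9: ("diglyme_water", "cyclohexane", 350.0, 3.0, 3),
}

# (crystallization, wash) -> (sphericity, porosity, Rm 1/m, n)
_MFA_ESTIMATES = {
    ("diglyme_water", "heptane"): (0.526, 0.694, 1.31e8, 0.833),
    ("diglyme_water", "cyclohexane"): (0.4964, 0.5258, 1.31e7, 0.0),
    ("ethyl_acetate", "heptane"): (0.4134, 0.4804, 1.6e9, 1.312),
    ("ethyl_acetate", "cyclohexane"): (0.399, 0.476, 1.46e9, 0.0),
}

# Input-stream mass fractions per crystallization liquor. The
# diglyme-water column closes to 1.001 as printed and is renormalized.
_MFA_LIQUORS = {
    "ethyl_acetate": {
        "ethyl_acetate": 0.876,
        "mefenamic_acid": 0.097,
        "cba": 0.009,
        "copper_acetate": 0.008,
        "dimethylaniline": 0.01,
    },
    "diglyme_water": {
        "diglyme_water": 0.821,  # diglyme 0.731 + water 0.090, 89:11 blend
        "mefenamic_acid": 0.141,
        "cba": 0.012,
        "copper_acetate": 0.012,
        "dimethylaniline": 0.015,
    },
}

_MFA_PARTICLES = ParticlePopulation(
    x10=39.03, x50=86.95, x90=176.48, d43=94.0, sphericity=0.468, sd=174.0
)

_MFA_SOLID_MASS_G = 4.34
_MFA_LIQUOR_MASS_G = 43.4
_MFA_FILTER_DIAMETER_MM = 27.0
_MFA_EQUIPMENT_VOLUME_ML = 50.0

# First-stage wash blend: 10:90 (v/v) crystallization:wash solvent, to
# suppress the anti-solvent precipitation risk of a neat first wash.
_MFA_WASH1_CRYST_VV = 0.10


# --- PCM case study -------------------------------------------------------

# expt -> (crystallization solvent, wash solvent, solid load w/w,
#          grade, pressure mbar, wash ratio, number of washes)
_PCM_DESIGN = {
    1: ("ethanol", "dodecane", 0.25, "powder", 800.0, 2.0, 2),
    2: ("ethanol", "dodecane", 0.25, "powder", 200.0, 2.0, 2),
    3: ("isoamyl_alcohol", "dodecane", 0.15, "powder", 200.0, 2.0, 2),
    4: ("isoamyl_alcohol", "dodecane", 0.15, "micronized", 800.0, 2.0, 2),
    5: ("ethanol", "isopropyl_acetate", 0.15, "micronized", 800.0, 2.0, 2),
    6: ("ethanol", "isopropyl_acetate", 0.15, "powder", 200.0, 2.0, 2),
    7: ("isoamyl_alcohol", "isopropyl_acetate", 0.20, "powder", 500.0, 3.0, 2),
    8: ("isoamyl_alcohol", "isopropyl_acetate", 0.20, "powder", 500.0, 3.0, 2),
    9: ("isoamyl_alcohol", "isopropyl_acetate", 0.20, "powder", 500.0, 3.0, 2),
}

_PCM_ESTIMATES = {
    ("ethanol", "dodecane"): (0.676, 0.44, 1.00e8, 0.321),
    ("isoamyl_alcohol", "dodecane"): (0.691, 0.44, 1.00e8, 0.61),
    ("ethanol", "isopropyl_acetate"): (0.636, 0.44, 1.00e8, 0.0),
    ("isoamyl_alcohol", "isopropyl_acetate"): (0.328, 0.44, 1.00e8, 0.0),
}

# First-stage wash: crystallization-solvent volume fraction of the blend,
# from the anti-solvent screening map (0 means a neat wash solvent is
# already safe).
_PCM_WASH1_CRYST_VV = {
    ("ethanol", "dodecane"): 0.30,
    ("ethanol", "isopropyl_acetate"): 0.30,
    ("isoamyl_alcohol", "dodecane"): 0.20,
    ("isoamyl_alcohol", "isopropyl_acetate"): 0.0,
}

# Grade percentiles; the Carman-Kozeny mean size is the case study's
# calibrated 61 um for both grades (mean_size_um override below).
_PCM_PARTICLES = {
    "micronized": ParticlePopulation(
        x10=11.1, x50=31.7, x90=195.0, d43=34.48, sphericity=0.629,
        sd=77.0, mean_size_um=61.0,
    ),
    "powder": ParticlePopulation(
        x10=16.6, x50=69.8, x90=198.0, d43=77.36, sphericity=0.4127,
        sd=77.0, mean_size_um=61.0,
    ),
}

_PCM_BATCH_MASS_G = 65.0  # one slurry dose: solid + liquor
_PCM_FILTER_DIAMETER_MM = 24.0
_PCM_EQUIPMENT_VOLUME_ML = 100.0
_PCM_SOLUTE_FRACTION = 0.13  # dissolved PCM mass fraction of the liquor
#: Impurity feed level: mass fraction of the *total suspension*, per
#: impurity (acetanilide and metacetamol).
_PCM_IMPURITY_SUSPENSION_FRACTION = 0.0015


def scenario_names() -> tuple[str, ...]:
    return tuple(
        [f"mfa_expt{i}" for i in _MFA_DESIGN]
        + [f"pcm_expt{i}" for i in _PCM_DESIGN]
    )


def make_scenario(
    name: str,
    mechanism: str = "displacement",
    peclet: float | None = None,
    mixed_mode: str = "accumulate",
    species_db: SpeciesTable | None = None,
) -> Scenario:
    """Build a named case-study scenario.

    `name` is one of ``mfa_expt1..9`` / ``pcm_expt1..9``. The wash
    program's mechanism (and, where relevant, Peclet number or well-mixed
    mode) applies to every stage; the displacement default matches the
    integrated pressure-filter model, ``well_mixed`` the MSMPR surrogate.
    """
    db = species_db or default_species_table()
    if name.startswith("mfa_expt"):
        return _make_mfa(name, db, mechanism, peclet, mixed_mode)
    if name.startswith("pcm_expt"):
        return _make_pcm(name, db, mechanism, peclet, mixed_mode)
    raise InvalidArgumentError(
        f"unknown scenario {name!r}; expected one of {scenario_names()}"
    )


def _expt_index(name: str, prefix: str, table: Mapping[int, tuple]) -> int:
    try:
        idx = int(name.removeprefix(prefix))
    except ValueError:
        idx = -1
    if idx not in table:
        raise InvalidArgumentError(
            f"unknown scenario {name!r}; expected one of {scenario_names()}"
        )
    return idx


def _wash_stages(
    n_washes: int,
    wash_ratio: float,
    stage1_comp: LiquidComposition,
    pure_wash: LiquidComposition,
    mechanism: str,
    peclet: float | None,
    mixed_mode: str,
) -> tuple[WashStage, ...]:
    stages = []
    for k in range(n_washes):
        comp = stage1_comp if k == 0 else pure_wash
        stages.append(
            WashStage(
                wash_composition=comp,
                mechanism=mechanism,
                wash_ratio=wash_ratio,
                peclet=peclet,
                mixed_mode=mixed_mode,
            )
        )
    return tuple(stages)


def _make_mfa(
    name: str, db: SpeciesTable, mechanism: str, peclet: float | None,
    mixed_mode: str,
) -> Scenario:
    idx = _expt_index(name, "mfa_expt", _MFA_DESIGN)
    cryst, wash, p_mbar, wash_ratio, n_washes = _MFA_DESIGN[idx]
    psi, eps, rm, n_comp = _MFA_ESTIMATES[(cryst, wash)]
    liquor = LiquidComposition.normalized(_MFA_LIQUORS[cryst])
    suspension = Suspension(
        solid_species=db["mefenamic_acid"],
        solid_mass=g_to_kg(_MFA_SOLID_MASS_G),
        liquor=liquor,
        liquor_mass=g_to_kg(_MFA_LIQUOR_MASS_G),
        particles=_MFA_PARTICLES,
    )
    stage1 = volume_fractions_to_mass(
        {cryst: _MFA_WASH1_CRYST_VV, wash: 1.0 - _MFA_WASH1_CRYST_VV}, db
    )
    return Scenario(
        name=name,
        suspension=suspension,
        filter=FilterSpec(
            diameter=mm_to_m(_MFA_FILTER_DIAMETER_MM),
            medium_resistance=rm,
            equipment_volume=ml_to_m3(_MFA_EQUIPMENT_VOLUME_ML),
        ),
        conditions=OperatingConditions(driving_force=mbar_to_pa(p_mbar)),
        cake_properties=CakeProperties(
            porosity=eps, sphericity=psi, compressibility_index=n_comp
        ),
        wash_program=_wash_stages(
            n_washes, wash_ratio, stage1, LiquidComposition.pure(wash),
            mechanism, peclet, mixed_mode,
        ),
        species_db=db,
        provenance=(
            f"MFA experiment {idx}: {cryst} liquor, {wash} wash, "
            f"{p_mbar:g} mbar, W={wash_ratio:g} x {n_washes} washes; "
            "calibrated cake parameters for this solvent pair"
        ),
    )


def _make_pcm(
    name: str, db: SpeciesTable, mechanism: str, peclet: float | None,
    mixed_mode: str,
) -> Scenario:
    idx = _expt_index(name, "pcm_expt", _PCM_DESIGN)
    cryst, wash, load, grade, p_mbar, wash_ratio, n_washes = _PCM_DESIGN[idx]
    psi, eps, rm, n_comp = _PCM_ESTIMATES[(cryst, wash)]
    solid_mass_g = load * _PCM_BATCH_MASS_G
    liquor_mass_g = _PCM_BATCH_MASS_G - solid_mass_g
    # Impurities are dosed as a fraction of the whole suspension; express
    # them in the liquor, with dissolved PCM at its saturation fraction
    # and the crystallization solvent as the remainder.
    w_imp = (
        _PCM_IMPURITY_SUSPENSION_FRACTION * _PCM_BATCH_MASS_G / liquor_mass_g
    )
    liquor = LiquidComposition(
        {
            "paracetamol": _PCM_SOLUTE_FRACTION,
            "acetanilide": w_imp,
            "metacetamol": w_imp,
            cryst: 1.0 - _PCM_SOLUTE_FRACTION - 2.0 * w_imp,
        }
    )
    particles = replace(_PCM_PARTICLES[grade], sphericity=0.6361)
    suspension = Suspension(
        solid_species=db["paracetamol"],
        solid_mass=g_to_kg(solid_mass_g),
        liquor=liquor,
        liquor_mass=g_to_kg(liquor_mass_g),
        particles=particles,
    )
    vv = _PCM_WASH1_CRYST_VV[(cryst, wash)]
    if vv > 0:
        stage1 = volume_fractions_to_mass({cryst: vv, wash: 1.0 - vv}, db)
    else:
        stage1 = LiquidComposition.pure(wash)
    return Scenario(
        name=name,
        suspension=suspension,
        filter=FilterSpec(
            diameter=mm_to_m(_PCM_FILTER_DIAMETER_MM),
            medium_resistance=rm,
            equipment_volume=ml_to_m3(_PCM_EQUIPMENT_VOLUME_ML),
        ),
        conditions=OperatingConditions(driving_force=mbar_to_pa(p_mbar)),
        cake_properties=CakeProperties(
            porosity=eps, sphericity=psi, compressibility_index=n_comp
        ),
        wash_program=_wash_stages(
            n_washes, wash_ratio, stage1, LiquidComposition.pure(wash),
            mechanism, peclet, mixed_mode,
        ),
        species_db=db,
        provenance=(
            f"PCM experiment {idx}: {cryst} liquor, {wash} wash, "
            f"{load:.0%} solid load, {grade} grade, {p_mbar:g} mbar, "
            f"W={wash_ratio:g} x {n_washes} washes"
        ),
    )


# ---------------------------------------------------------------------------
# Synthetic observations


@dataclass(frozen=True)
class SyntheticObservation:
    """A noisy filtrate volume-time series for a scenario."""

    scenario_name: str
    times: np.ndarray  # s
    volumes: np.ndarray  # m3
    noise_sd: float
    seed: int


def generate_filtration_observations(
    scenario: Scenario,
    noise_sd: float,
    seed: int,
    n_points: int = 50,
) -> SyntheticObservation:
    """Forward-simulate a scenario and add multiplicative Gaussian noise.

    Observed volumes are ``V_true (1 + noise_sd * z)`` with standard
    normal ``z`` from a generator seeded with `seed`; the series is
    reproducible bit-for-bit from (scenario, noise_sd, seed).
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    result = simulate_filtration(scenario, n_points=n_points + 1)
    # drop the t = 0, V = 0 point: it carries no information and
    # multiplicative noise cannot perturb it
    times = result.times[1:]
    volumes = result.filtrate_volumes[1:].copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        volumes = volumes * (1.0 + noise_sd * rng.standard_normal(len(volumes)))
    return SyntheticObservation(
        scenario_name=scenario.name,
        times=times,
        volumes=volumes,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_wash_observations(
    scenario: Scenario,
    mechanism: str,
    noise_sd: float,
    seed: int,
    mixed_mode: str = "accumulate",
    peclet: float | None = None,
):
    """Per-stage wash filtrate compositions with seeded relative noise.

    Rebuilds the scenario's wash program under `mechanism`, runs
    filtration + washing, perturbs each stage's filtrate mass fractions
    multiplicatively and renormalizes, so the observed compositions still
    close to one.

    Returns a list with one ``(filtrate_mass_kg, composition)`` pair per
    stage; accumulate-mode stages have no outflow and report mass 0 with
    composition ``None``.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    scen = make_scenario(
        scenario.name, mechanism=mechanism, peclet=peclet,
        mixed_mode=mixed_mode, species_db=scenario.species_db,
    )
    cake = simulate_filtration(scen).end_state
    result = run_wash_program(cake, scen.wash_program, scen.species_db,
                              curve_points=0)
    rng = np.random.default_rng(seed)
    observed = []
    for rec in result.per_stage:
        if rec.filtrate_composition is None:
            observed.append((0.0, None))
            continue
        names = list(rec.filtrate_composition.species)
        w = np.array([rec.filtrate_composition.fraction(n) for n in names])
        if noise_sd > 0:
            w = w * (1.0 + noise_sd * rng.standard_normal(len(w)))
            w = np.clip(w, 0.0, None)
            w = w / w.sum()
        comp = LiquidComposition(dict(zip(names, w.tolist())))
        mass = rec.filtrate_mass
        if noise_sd > 0:
            mass = mass * (1.0 + noise_sd * rng.standard_normal())
        observed.append((mass, comp))
    return observed
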