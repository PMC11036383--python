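"""Species data model, liquid mixture rules and wash-ratio geometry.

A :class:`Species` carries the physical properties the filtration and
washing models need: liquid density and viscosity for anything dissolved
or flowing, and the true solid (crystal) density for the species that
forms the cake. A :class:`LiquidComposition` is an immutable map of mass
fractions that must close to one; every composition emitted anywhere in
the package satisfies that invariant to 1e-9.

Mixture rules (the source material fixes none, so these are package
choices, documented in docs/methods.md):

* density — mass-weighted specific volumes, ``1/rho = sum_i w_i / rho_i``;
* viscosity — mass-weighted logarithms, ``ln mu = sum_i w_i ln mu_i``
  (Arrhenius mixing rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import (
    InvalidArgumentError,
    InvalidCompositionError,
    MissingSpeciesError,
)
from .units import um_to_m

ROLES = ("api", "impurity", "crystallization_solvent", "wash_solvent")

#: Tolerance on the sum-to-one invariant for compositions.
COMPOSITION_ATOL = 1e-9


@dataclass(frozen=True)
class Species:
    """One chemical species (or pseudo-species) and its properties.

    Parameters
    ----------
    name : str
        Unique identifier within a scenario.
    role : str
        One of ``api``, ``impurity``, ``crystallization_solvent``,
        ``wash_solvent``. The API species additionally needs a solid
        density for cake geometry.
    liquid_density : float
        Density in the liquid phase, kg/m3. For dissolved solids this is
        the partial (melt-like) density used by the mixing rule.
    viscosity : float
        Dynamic viscosity contribution, Pa s.
    solid_density : float, optional
        True crystal density, kg/m3. Required when the species forms the
        cake (role ``api``).
    """

    name: str
    role: str
    liquid_density: float
    viscosity: float
    solid_density: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidArgumentError(
                f"unknown role {self.role!r} for species {self.name!r}; "
                f"expected one of {ROLES}"
            )
        if not self.liquid_density > 0:
            raise InvalidArgumentError(
                f"liquid_density of {self.name!r} must be > 0"
            )
        if not self.viscosity > 0:
            raise InvalidArgumentError(f"viscosity of {self.name!r} must be > 0")
        if self.solid_density is not None and not self.solid_density > 0:
            raise InvalidArgumentError(
                f"solid_density of {self.name!r} must be > 0"
            )


class SpeciesTable(Mapping):
    """Immutable name -> :class:`Species` lookup with override support."""

    def __init__(self, species: Iterable[Species]):
        table: dict[str, Species] = {}
        for sp in species:
            if sp.name in table:
                raise InvalidArgumentError(f"duplicate species name {sp.name!r}")
            table[sp.name] = sp
        self._table = table

    def __getitem__(self, name: str) -> Species:
        try:
            return self._table[name]
        except KeyError:
            raise MissingSpeciesError(
                f"species {name!r} not found in property table"
            ) from None

    def __iter__(self):
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def with_overrides(self, *species: Species) -> "SpeciesTable":
        """Return a new table with the given species replaced or added."""
        merged = dict(self._table)
        for sp in species:
            merged[sp.name] = sp
        return SpeciesTable(merged.values())


@dataclass(frozen=True)
class LiquidComposition:
    """Mass-fraction composition of a liquid phase.

    Fractions must be in [0, 1] and sum to one within 1e-9. Use
    :meth:`normalized` to ingest raw table data that closes only
    approximately.
    """

    mass_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        fracs = dict(self.mass_fractions)
        for name, w in fracs.items():
            if not (-COMPOSITION_ATOL <= w <= 1 + COMPOSITION_ATOL):
                raise InvalidCompositionError(
                    f"mass fraction of {name!r} is {w}, outside [0, 1]"
                )
        total = sum(fracs.values())
        if abs(total - 1.0) > COMPOSITION_ATOL:
            raise InvalidCompositionError(
                f"mass fractions sum to {total:.12g}, expected 1 within "
                f"{COMPOSITION_ATOL:g}"
            )
        object.__setattr__(self, "mass_fractions", dict(fracs))

    @classmethod
    def normalized(
        cls, mass_fractions: Mapping[str, float], atol: float = 2e-3
    ) -> "LiquidComposition":
        """Build a composition from fractions that close only within `atol`.

        Printed tables often sum to 0.999 or 1.001; this renormalizes them.
        A deficit/excess beyond `atol` is treated as a data error.
        """
        total = sum(mass_fractions.values())
        if abs(total - 1.0) > atol:
            raise InvalidCompositionError(
                f"mass fractions sum to {total:.6g}; refusing to renormalize "
                f"beyond tolerance {atol:g}"
            )
        return cls({k: v / total for k, v in mass_fractions.items()})

    @classmethod
    def pure(cls, name: str) -> "LiquidComposition":
        return cls({name: 1.0})

    def fraction(self, name: str) -> float:
        """Mass fraction of `name`, 0.0 if absent."""
        return self.mass_fractions.get(name, 0.0)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.mass_fractions)

    def items(self):
        return self.mass_fractions.items()


def mixture_properties(
    comp: LiquidComposition, db: Mapping[str, Species]
) -> tuple[float, float]:
    """Density and viscosity of a liquid mixture.

    Density from mass-weighted specific volumes, viscosity from the
    Arrhenius (log-linear) rule. Species with zero mass fraction are
    ignored, so compositions may carry the full species universe.

    Returns
    -------
    (density, viscosity) in (kg/m3, Pa s).
    """
    present = [(name, w) for name, w in comp.items() if w > 0.0]
    if not present:
        raise InvalidCompositionError("composition has no mass")
    if len(present) == 1:
        sp = db[present[0][0]]  # single species: bit-exact pass-through
        return sp.liquid_density, sp.viscosity
    spec_vol = 0.0
    log_mu = 0.0
    for name, w in present:
        sp = db[name]  # raises MissingSpeciesError
        spec_vol += w / sp.liquid_density
        log_mu += w * math.log(sp.viscosity)
    return 1.0 / spec_vol, math.exp(log_mu)


def volume_fractions_to_mass(
    volume_fractions: Mapping[str, float], db: Mapping[str, Species]
) -> LiquidComposition:
    """Convert v/v solvent fractions (e.g. a 10:90 wash blend) to mass
    fractions using the species' liquid densities."""
    masses = {
        name: phi * db[name].liquid_density
        for name, phi in volume_fractions.items()
        if phi > 0
    }
    total = sum(masses.values())
    if total <= 0:
        raise InvalidCompositionError("volume fractions have no mass")
    return LiquidComposition({k: v / total for k, v in masses.items()})


@dataclass(frozen=True)
class ParticlePopulation:
    """Summary of a volume-weighted particle size distribution.

    All sizes in micrometres. ``mean_size_um`` is the size the
    Carman-Kozeny relation uses; it defaults to D[4,3].
    """

    x10: float
    x50: float
    x90: float
    d43: float
    sphericity: float
    sd: float
    mean_size_um: float | None = None

    def __post_init__(self) -> None:
        if not (self.x10 <= self.x50 <= self.x90):
            raise InvalidArgumentError("require x10 <= x50 <= x90")
        if not (0 < self.sphericity <= 1):
            raise InvalidArgumentError("sphericity must be in (0, 1]")
        for label, v in (("x10", self.x10), ("d43", self.d43), ("sd", self.sd)):
            if not v > 0:
                raise InvalidArgumentError(f"{label} must be > 0")
        if self.mean_size_um is None:
            object.__setattr__(self, "mean_size_um", self.d43)
        elif not self.mean_size_um > 0:
            raise InvalidArgumentError("mean_size_um must be > 0")

    @property
    def mean_size_m(self) -> float:
        """Carman-Kozeny mean particle size in metres."""
        return um_to_m(self.mean_size_um)


@dataclass(frozen=True)
class Suspension:
    """Feed slurry: solid particles suspended in saturated mother liquor."""

    solid_species: Species
    solid_mass: float  # kg
    liquor: LiquidComposition
    liquor_mass: float  # kg
    particles: ParticlePopulation
    temperature: float = 25.0  # degC

    def __post_init__(self) -> None:
        if self.solid_mass < 0:
            raise InvalidArgumentError("solid_mass must be >= 0")
        if not self.liquor_mass > 0:
            raise InvalidArgumentError("liquor_mass must be > 0")
        if self.solid_mass > 0 and self.solid_species.solid_density is None:
            raise InvalidArgumentError(
                f"solid species {self.solid_species.name!r} needs a "
                "solid_density to form a cake"
            )

    @property
    def solid_load(self) -> float:
        """Solid mass fraction of the whole suspension (kg/kg)."""
        return self.solid_mass / (self.solid_mass + self.liquor_mass)

    @property
    def total_mass(self) -> float:
        return self.solid_mass + self.liquor_mass


def wash_ratio_to_volume(wash_ratio: float, cake) -> float:
    """Wash liquid volume (m3) delivering `wash_ratio` cake pore volumes.

    A wash ratio of 1 delivers exactly the cake void volume. `cake` is any
    object exposing ``void_volume`` (m3).
    """
    if wash_ratio < 0:
        raise InvalidArgumentError("wash_ratio must be >= 0")
    void = cake.void_volume
    if not void > 0:
        raise InvalidArgumentError("cake has no void volume")
    return wash_ratio * void
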