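"""Energy-dependent attenuation physics.

Mass-attenuation coefficients are bundled as small NIST-style two-column
text tables (keV, cm^2/g) and interpolated log-log, the conventional way to
interpolate photon cross sections away from absorption edges.  Compound
materials without their own table (calcium hydroxyapatite, lipid) are
assembled from elemental tables through mass-fraction weighting, which is
exact for incoherent mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AttenuationTable",
    "MixtureRule",
    "load_attenuation_table",
    "available_materials",
    "linear_attenuation",
    "mu_to_hu",
    "hu_to_mu",
]

#: Mass fractions of compound materials derived from chemical formula.
#: Calcium hydroxyapatite is Ca10(PO4)6(OH)2 (M = 1004.6 g/mol); lipid is
#: modelled as tripalmitin C51H98O6 (M = 807.3 g/mol).
_COMPOSITIONS: dict[str, tuple[float, dict[str, float]]] = {
    "calcium hydroxyapatite": (
        3.16,
        {"calcium": 0.39894, "phosphorus": 0.18499, "oxygen": 0.41406, "hydrogen": 0.00201},
    ),
    "lipid": (
        0.92,
        {"carbon": 0.75889, "hydrogen": 0.12238, "oxygen": 0.11873},
    ),
}

_ALIASES = {
    "ha": "calcium hydroxyapatite",
    "hydroxyapatite": "calcium hydroxyapatite",
    "calcium_hydroxyapatite": "calcium hydroxyapatite",
    "fat": "lipid",
    "soft tissue": "water",  # soft-tissue-equivalent matrix is water-equivalent here
}

_TABULATED = (
    "water",
    "air",
    "pmma",
    "aluminum",
    "hydrogen",
    "carbon",
    "nitrogen",
    "oxygen",
    "phosphorus",
    "calcium",
)


@dataclass(frozen=True)
class AttenuationTable:
    """Mass attenuation mu/rho (cm^2/g) of one material on an energy grid (keV)."""

    material_name: str
    energies: np.ndarray
    mass_atten: np.ndarray
    nominal_density: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mass_atten, dtype=float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("energies and mass_atten must be matching 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if not np.all(m > 0):
            raise ValueError("mass attenuation values must be strictly positive")
        if e[0] > 10.0 or e[-1] < 140.0:
            raise ValueError(
                f"table for {self.material_name!r} must cover at least 10-140 keV, "
                f"got {e[0]:g}-{e[-1]:g}"
            )
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mass_atten", m)

    def __call__(self, energy_kev) -> np.ndarray | float:
        """Interpolate mu/rho at ``energy_kev`` (log-log; no extrapolation)."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise ValueError(
                f"energy outside the {self.material_name!r} table range "
                f"[{self.energies[0]:g}, {self.energies[-1]:g}] keV"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(self.mass_atten))
        )
        return float(out) if np.isscalar(energy_kev) else out


def _read_fixture(name: str) -> AttenuationTable:
    path = resources.files("cacsim").joinpath(f"data/attenuation/{name}.txt")
    density = np.nan
    energies, mus = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            if "Nominal density" in line:
                density = float(line.split(":")[1].split("g/cm")[0])
            continue
        if not line:
            continue
        e, m = line.split()
        energies.append(float(e))
        mus.append(float(m))
    return AttenuationTable(name, np.array(energies), np.array(mus), density)


def available_materials() -> tuple[str, ...]:
    return _TABULATED + tuple(_COMPOSITIONS)


def load_attenuation_table(material_name: str) -> AttenuationTable:
    """Load the bundled attenuation table for ``material_name``.

    Compound materials listed in the composition registry are built from the
    elemental fixtures by mass-fraction weighting on the elemental energy grid.
    """
    key = _ALIASES.get(material_name.lower(), material_name.lower())
    if key in _TABULATED:
        return _read_fixture(key)
    if key in _COMPOSITIONS:
        density, fractions = _COMPOSITIONS[key]
        parts = {el: _read_fixture(el) for el in fractions}
        grid = next(iter(parts.values())).energies
        mu = np.zeros_like(grid)
        for el, w in fractions.items():
            mu += w * parts[el](grid)
        return AttenuationTable(key, grid, mu, density)
    raise KeyError(
        f"unknown material {material_name!r}; available: "
        + ", ".join(sorted(available_materials()))
    )


@dataclass(frozen=True)
class MixtureRule:
    """Mass-fraction mixture of bundled materials (fractions sum to 1)."""

    components: tuple[tuple[str, float], ...]
    _tables: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        comps = tuple((str(n), float(f)) for n, f in self.components)
        for name, f in comps:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mass fraction of {name!r} outside [0, 1]: {f}")
        total = sum(f for _, f in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 1 (got {total!r})")
        object.__setattr__(self, "components", comps)
        object.__setattr__(
            self, "_tables", {name: load_attenuation_table(name) for name, _ in comps}
        )

    @classmethod
    def pure(cls, material: str) -> "MixtureRule":
        return cls(((material, 1.0),))

    def mass_attenuation(self, energy_kev) -> np.ndarray | float:
        """Mixture mu/rho at ``energy_kev`` (mass-fraction weighted)."""
        out = 0.0
        for name, f in self.components:
            out = out + f * self._tables[name](energy_kev)
        return out


def linear_attenuation(mixture: MixtureRule, density: float, energy_kev) -> np.ndarray | float:
    """Linear attenuation mu (cm^-1) = density * sum_i f_i (mu/rho)_i(E)."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return density * mixture.mass_attenuation(energy_kev)


def mu_to_hu(mu_image, mu_water_eff: float, mu_air_eff: float) -> np.ndarray:
    """Convert effective linear attenuation to Hounsfield units.

    HU = 1000 (mu - mu_water) / (mu_water - mu_air); water maps to 0 and air
    to -1000 by construction.
    """
    mu_image = np.asarray(mu_image, dtype=float)
    if not (np.isfinite(mu_water_eff) and np.isfinite(mu_air_eff)):
        raise ValueError("mu_water_eff and mu_air_eff must be finite")
    if not np.all(np.isfinite(mu_image)):
        raise ValueError("mu image contains non-finite values")
    if not mu_water_eff > mu_air_eff:
        raise ValueError("mu_water_eff must exceed mu_air_eff")
    return 1000.0 * (mu_image - mu_water_eff) / (mu_water_eff - mu_air_eff)


def hu_to_mu(hu_image, mu_water_eff: float, mu_air_eff: float) -> np.ndarray:
    """Inverse of :func:`mu_to_hu` (exact, the map is affine)."""
    hu_image = np.asarray(hu_image, dtype=float)
    if not mu_water_eff > mu_air_eff:
        raise ValueError("mu_water_eff must exceed mu_air_eff")
    return mu_water_eff + hu_image / 1000.0 * (mu_water_eff - mu_air_eff)
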