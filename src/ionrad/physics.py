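"""Ion-matter physics for single-ion radiography.

Everything here is continuous-slowing-down (CSDA) bookkeeping for light
therapeutic ions in the 0.5-500 MeV/u window: Bethe-Bloch mass stopping
power (first-order, no shell or density-effect corrections), range and
residual-energy tables, water-equivalent thickness, Highland multiple
Coulomb scattering, Bohr energy-loss straggling and fluence-to-dose
conversion.  The same routines drive both the detector-stack simulator and
the analytic cross-checks, so they are kept free of any detector state.

Units follow medical-physics convention: energies in MeV per nucleon
(MeV/u) unless a total energy is stated, thicknesses in cm at this layer of
the API (mm appear only in the geometry modules), stopping powers in
MeV cm^2/g, doses in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "IonSpecies", "Material", "EnergyGrid", "PROTON", "HELIUM", "CARBON",
    "WATER", "PMMA", "SILICON", "AIR", "MATERIALS", "IONS",
    "PhysicsDomainError", "mass_stopping_power", "csda_range", "energy_after",
    "water_equivalent_thickness", "relative_stopping_power", "highland_sigma",
    "bohr_straggling_sigma", "fluence_to_dose", "deposition_in_silicon",
    "beta_gamma", "momentum_per_nucleon",
]

#: electron rest energy, MeV
ELECTRON_MASS = 0.51099895
#: 4 pi N_A r_e^2 m_e c^2, MeV cm^2/mol -> coefficient of the Bethe formula
K_BETHE = 0.307075
#: 4 pi N_A r_e^2 (m_e c^2)^2, MeV^2 cm^2/g -- Bohr straggling coefficient
K_BOHR = 0.1569
#: MeV/g -> Gy
MEV_PER_G_TO_GY = 1.602176634e-10

#: validity window of the stopping-power model, MeV/u
E_MIN, E_MAX = 0.5, 500.0


class PhysicsDomainError(ValueError):
    """Raised when an input falls outside the model's validity window."""


@dataclass(frozen=True)
class IonSpecies:
    """A fully stripped projectile ion.

    ``mass_per_nucleon`` is the rest energy per nucleon in MeV/c^2; for bare
    nuclei heavier than the proton the nuclear binding makes it slightly
    smaller than the proton mass.
    """

    name: str
    charge_number: int
    mass_number: int
    mass_per_nucleon: float

    def __post_init__(self) -> None:
        if self.charge_number < 1 or self.mass_number < self.charge_number:
            raise ValueError("require Z >= 1 and A >= Z")


@dataclass(frozen=True)
class Material:
    """Homogeneous stopping medium.

    ``z_over_a`` is the electrons-per-nucleon ratio <Z/A> (mol/g up to N_A),
    ``mean_excitation_energy`` the I-value in eV and ``radiation_length`` X0
    in g/cm^2.
    """

    name: str
    density: float
    mean_excitation_energy: float
    z_over_a: float
    radiation_length: float

    def __post_init__(self) -> None:
        if self.density <= 0 or self.mean_excitation_energy <= 0:
            raise ValueError("density and I must be positive")


@dataclass(frozen=True)
class EnergyGrid:
    """Ascending energy grid (MeV/u) for range/stopping tables.

    Must cover at least the 1-250 MeV/u clinical window (water ranges of
    roughly 2-30 cm for protons and helium).
    """

    energies_per_nucleon: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_per_nucleon, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] > 1.0 or e[-1] < 250.0:
            raise ValueError("energy grid must cover 1-250 MeV/u")
        object.__setattr__(self, "energies_per_nucleon", tuple(e))

    @classmethod
    def default(cls) -> "EnergyGrid":
        return cls(tuple(np.geomspace(E_MIN, E_MAX, 4096)))


PROTON = IonSpecies("proton", 1, 1, 938.27209)
HELIUM = IonSpecies("helium", 2, 4, 931.49410)
CARBON = IonSpecies("carbon", 6, 12, 931.49410)

WATER = Material("water", 1.000, 75.0, 0.55509, 36.08)
PMMA = Material("pmma", 1.190, 74.0, 0.53937, 40.55)
SILICON = Material("silicon", 2.330, 173.0, 0.49848, 21.82)
AIR = Material("air", 1.205e-3, 85.7, 0.49919, 36.62)

IONS = {i.name: i for i in (PROTON, HELIUM, CARBON)}
MATERIALS = {m.name: m for m in (WATER, PMMA, SILICON, AIR)}


def beta_gamma(ion: IonSpecies, energy_per_nucleon):
    """Return (beta^2, gamma) for the given kinetic energy per nucleon."""
    gamma = 1.0 + np.asarray(energy_per_nucleon, dtype=float) / ion.mass_per_nucleon
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    return beta2, gamma


def momentum_per_nucleon(ion: IonSpecies, energy_per_nucleon) -> float:
    """pc per nucleon in MeV."""
    beta2, gamma = beta_gamma(ion, energy_per_nucleon)
    return ion.mass_per_nucleon * gamma * np.sqrt(beta2)


def _check_energy(energy_per_nucleon) -> None:
    e = np.asarray(energy_per_nucleon, dtype=float)
    if np.any(e < E_MIN) or np.any(e > E_MAX):
        raise PhysicsDomainError(
            f"energy {energy_per_nucleon} MeV/u outside [{E_MIN}, {E_MAX}]"
        )


def mass_stopping_power(ion: IonSpecies, energy_per_nucleon, material: Material):
    """Electronic mass stopping power S/rho in MeV cm^2/g.

    First-order Bethe-Bloch at the ion's beta, with the maximum
    energy-transfer term approximated by 2 m_e c^2 beta^2 gamma^2 and no
    shell or density-effect corrections; adequate to ~2% over 10-250 MeV/u
    for the light ions used here.
    """
    _check_energy(energy_per_nucleon)
    beta2, gamma = beta_gamma(ion, energy_per_nucleon)
    w_max_ev = 2.0 * ELECTRON_MASS * beta2 * gamma * gamma * 1e6
    z = ion.charge_number
    return (
        K_BETHE * material.z_over_a * z * z / beta2
        * (np.log(w_max_ev / material.mean_excitation_energy) - beta2)
    )


@lru_cache(maxsize=64)
def _range_table(ion: IonSpecies, material: Material,
                 grid: EnergyGrid | None = None):
    """Cached (E, R(E)) arrays over the default log-spaced energy grid.

    R(E) = integral_{E_MIN}^{E} A dE'/(S(E') rho); the residual range below
    the 0.5 MeV/u cutoff (< 0.01 mm in solids) is neglected.
    """
    energies = np.asarray((grid or EnergyGrid.default()).energies_per_nucleon)
    dedx = mass_stopping_power(ion, energies, material) * material.density
    ranges = cumulative_trapezoid(ion.mass_number / dedx, energies, initial=0.0)
    return energies, ranges


def csda_range(ion: IonSpecies, energy_per_nucleon, material: Material):
    """CSDA range in cm of material."""
    _check_energy(energy_per_nucleon)
    energies, ranges = _range_table(ion, material)
    return np.interp(energy_per_nucleon, energies, ranges)


def energy_after(ion: IonSpecies, energy_per_nucleon, material: Material, thickness_cm):
    """Residual energy (MeV/u) after a slab; 0 where the ion stops inside.

    Inverts the range table: solves R(E_out) = R(E_in) - thickness.
    """
    t = np.asarray(thickness_cm, dtype=float)
    if np.any(t < 0):
        raise PhysicsDomainError("negative thickness")
    _check_energy(energy_per_nucleon)
    energies, ranges = _range_table(ion, material)
    residual = np.interp(energy_per_nucleon, energies, ranges) - t
    out = np.interp(residual, ranges, energies)
    out = np.where(residual <= 0.0, 0.0, out)
    return out if out.ndim else float(out)


def relative_stopping_power(material: Material, energy_per_nucleon,
                            ion: IonSpecies = HELIUM):
    """Linear stopping power relative to water (RSP) at the given energy."""
    s_mat = mass_stopping_power(ion, energy_per_nucleon, material) * material.density
    s_wat = mass_stopping_power(ion, energy_per_nucleon, WATER) * WATER.density
    return s_mat / s_wat


def water_equivalent_thickness(material: Material, thickness_mm,
                               reference_energy: float,
                               ion: IonSpecies = HELIUM):
    """WET in mm of water: thickness x RSP at the reference energy.

    Additive over stacked slabs by construction.
    """
    t = np.asarray(thickness_mm, dtype=float)
    if np.any(t < 0):
        raise PhysicsDomainError("negative thickness")
    return t * relative_stopping_power(material, reference_energy, ion)


def highland_sigma(ion: IonSpecies, energy_per_nucleon: float, material: Material,
                   thickness_cm: float) -> float:
    """Highland multiple-scattering angle theta_0 (rad, per projected plane).

    theta_0 = 13.6 MeV / (beta c p) * z * sqrt(x/X0) * [1 + 0.038 ln(x/X0)]
    with p the *total* ion momentum, so at equal energy per nucleon a helium
    ion scatters half as much as a proton.
    """
    x_over_x0 = thickness_cm * material.density / material.radiation_length
    if x_over_x0 <= 0:
        raise PhysicsDomainError("x/X0 must be positive")
    beta2, _ = beta_gamma(ion, energy_per_nucleon)
    pc_total = ion.mass_number * momentum_per_nucleon(ion, energy_per_nucleon)
    beta_pc = np.sqrt(beta2) * pc_total
    theta = (13.6 / beta_pc) * ion.charge_number * np.sqrt(x_over_x0) \
        * (1.0 + 0.038 * np.log(x_over_x0))
    # the log correction can turn negative for very thin slabs; clamp at 0
    return float(max(theta, 0.0))


def bohr_straggling_sigma(ion: IonSpecies, material: Material,
                          thickness_cm: float) -> float:
    """Gaussian energy-loss straggling sigma (MeV, total energy) for a slab.

    Bohr's formula: sigma^2 = 0.1569 z^2 (Z/A) rho x  [MeV^2, x in cm].
    """
    if thickness_cm <= 0:
        raise PhysicsDomainError("thickness must be positive")
    z = ion.charge_number
    var = K_BOHR * z * z * material.z_over_a * material.density * thickness_cm
    return float(np.sqrt(var))


def fluence_to_dose(fluence_per_cm2, ion: IonSpecies, energy: float,
                    material: Material, per_nucleon: bool = True):
    """Dose in Gy from a fluence: D = Phi * (S/rho) * 1.602e-10 Gy g/MeV.

    ``energy`` is MeV/u when ``per_nucleon`` (default), else total MeV.
    """
    phi = np.asarray(fluence_per_cm2, dtype=float)
    if np.any(phi < 0):
        raise PhysicsDomainError("fluence must be non-negative")
    e_u = energy if per_nucleon else energy / ion.mass_number
    s = mass_stopping_power(ion, e_u, material)
    return phi * s * MEV_PER_G_TO_GY


def deposition_in_silicon(ion: IonSpecies, energy_per_nucleon: float,
                          thickness_um: float) -> float:
    """Mean energy (MeV, total) deposited in a silicon layer.

    Integrated over the slowing-down within the layer (not S * x), so it is
    exact in the CSDA sense even on the steep Bragg flank; equals the full
    residual kinetic energy if the ion stops inside.
    """
    if energy_per_nucleon <= 0:
        return 0.0
    if energy_per_nucleon < E_MIN:  # below the model window: stops immediately
        return ion.mass_number * energy_per_nucleon
    e_out = energy_after(ion, energy_per_nucleon, SILICON, thickness_um * 1e-4)
    return ion.mass_number * (energy_per_nucleon - e_out)
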