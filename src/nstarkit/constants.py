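"""Physical constants and unit conventions.

Units used throughout the package:

* length      : angstrom (A)
* energy      : kcal/mol
* time        : picosecond (ps)
* charge      : elementary charge (e)
* temperature : kelvin (K)

Friction coefficients are therefore expressed in kcal ps / (mol A^2) and
viscosities in kcal ps / (mol A^3).
"""

AVOGADRO = 6.02214076e23  # 1/mol
KB = 0.0019872041  # Boltzmann constant, kcal/(mol K)
COULOMB = 332.0637  # e^2 prefactor of Coulomb's law in vacuum, kcal A / (mol e^2)

# 1 Pa s expressed in kcal ps / (mol A^3):
#   1 Pa s = 1 J s / m^3 -> (N_A / 4184) kcal s / (mol m^3) -> x1e12 ps, x1e-30 A^-3
PAS_TO_INTERNAL = AVOGADRO / 4184.0 * 1e12 * 1e-30  # ~= 143.93

#: Viscosity of water at 298 K (the solvent model's viscosity), Pa s.
WATER_VISCOSITY_PAS = 1.0e-3

#: Default bead hydrodynamic radius in A.  Together with the water viscosity
#: above this pins the per-bead friction gamma = 6 pi eta a_h and hence the
#: natural Brownian time unit tau_HF = gamma a^2 / k_B T ~= 13.2 ps at 298 K
#: (with the conventional length scale a = 1 A).
DEFAULT_HYDRO_RADIUS = 2.8817  # A

DEFAULT_TEMPERATURE = 298.0  # K


def kBT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in kcal/mol at the given temperature."""
    return KB * temperature


def viscosity_internal(eta_pas: float = WATER_VISCOSITY_PAS) -> float:
    """Convert a viscosity in Pa s to internal units (kcal ps / mol A^3)."""
    return eta_pas * PAS_TO_INTERNAL


def stokes_friction(hydro_radius: float = DEFAULT_HYDRO_RADIUS,
                    eta_pas: float = WATER_VISCOSITY_PAS) -> float:
    """Stokes friction gamma = 6 pi eta a_h in kcal ps / (mol A^2)."""
    import math

    return 6.0 * math.pi * viscosity_internal(eta_pas) * hydro_radius
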