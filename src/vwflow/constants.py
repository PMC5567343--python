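"""Physical constants and unit conventions.

Conventions used throughout the package: force in pN, length in nm (contour
profiles reported in μm), wall shear stress in dyn cm⁻² (1 dyn cm⁻² = 0.1 Pa),
viscosity in cP, concentration in nM, bimolecular rates in M⁻¹ s⁻¹.
"""

#: Boltzmann constant in pN·nm per kelvin.
KB_PN_NM_PER_K = 0.0138

#: Boltzmann constant in J per kelvin (SI, for collision-rate estimates).
KB_J_PER_K = 1.380649e-23

AVOGADRO = 6.02214076e23

#: Default assay temperature (22 °C), kelvin.
DEFAULT_TEMPERATURE_K = 295.0

DYN_CM2_TO_PA = 0.1
CP_TO_PA_S = 1.0e-3


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """k_BT in pN·nm at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_PN_NM_PER_K * temperature
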