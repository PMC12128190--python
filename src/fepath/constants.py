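"""Physical constants in the kcal/mol, Å, e, K unit system.

Values are fixed here (not read from scipy at run time) so that numeric
output is stable across library versions; the test suite re-derives each one
from CODATA constants as an independent check.
"""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹ (R in kcal units).
KB_KCAL_MOL_K = 0.0019872041

#: Coulomb constant e²/(4πε₀) on the molar scale, kcal·Å·mol⁻¹·e⁻².
COULOMB_KCAL_A_E2 = 332.0637

#: Field-unit conversion: 1 kcal·mol⁻¹·e⁻¹·Å⁻¹ expressed in MV·cm⁻¹.
KCAL_MOL_E_A_TO_MV_CM = 4.3364


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal·mol⁻¹ for a temperature in kelvin."""
    return KB_KCAL_MOL_K * temperature
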