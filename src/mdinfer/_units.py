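"""Physical constants and the few unit conversions used across modules.

All energies handled by the estimators are in kJ/mol unless a function
explicitly works in reduced (kT) units; temperatures are in kelvin.
Diffusion coefficients are carried in nm^2/ps and converted for display.
"""

# CODATA exact values
KB_J_PER_K = 1.380649e-23  # Boltzmann constant, J/K
AVOGADRO = 6.02214076e23  # 1/mol
R_KJ_PER_MOL_K = KB_J_PER_K * AVOGADRO / 1000.0  # 8.31446... x 1e-3 kJ/mol/K

NM2_PER_PS_TO_M2_PER_S = 1.0e-6  # 1 nm^2/ps = 1e-18 m^2 / 1e-12 s
M2_PER_S_TO_NM2_PER_PS = 1.0e6
M2_PER_S_TO_1E5_CM2_PER_S = 1.0e9  # 1 m^2/s = 1e4 cm^2/s = 1e9 x (1e-5 cm^2/s)


def kt_kj_per_mol(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_PER_MOL_K * temperature


def beta_mol_per_kj(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol/kJ."""
    return 1.0 / kt_kj_per_mol(temperature)
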