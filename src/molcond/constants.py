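"""Physical constants and unit conventions.

All energies are in eV, distances in Å, temperatures in K.  Internally we
work in natural units with ħ = 1, so rates carry energy units (eV) and the
time unit is ħ/eV ≈ 0.658 fs.  Conductance prefactors e²/h and e²/ħ = 2π·e²/h
convert the dimensionless contractions to Siemens at the very end.
"""

import math

#: Boltzmann constant, eV/K.
K_B = 8.617333262e-5

#: Conductance quantum prefactor e²/h in Siemens (CODATA: G0 = 2e²/h).
E2_OVER_H_S = 3.874045865e-5

#: e²/ħ = 2π e²/h in Siemens.
E2_OVER_HBAR_S = 2.0 * math.pi * E2_OVER_H_S

#: ħ in eV·s (used only to report the internal time unit).
HBAR_EV_S = 6.582119569e-16

#: Bohr radius in Å (Slater exponents are tabulated per Bohr).
BOHR_A = 0.529177210903

#: Siemens → nanoSiemens.
S_TO_NS = 1e9


def kT(temperature_K: float) -> float:
    """Thermal energy k_B·T in eV."""
    return K_B * temperature_K
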