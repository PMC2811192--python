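"""Physical constants and unit conversions.

Internal conventions: lengths in Å, charges in elementary charge units e,
potentials in kT/e, energies reported in kJ/mol.
"""

from __future__ import annotations

import numpy as np
import scipy.constants as sc

DEFAULT_TEMPERATURE = 298.15  # K


def kT_kJ_per_mol(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT expressed in kJ/mol."""
    return sc.R * temperature / 1000.0


def coulomb_constant_kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Coulomb prefactor C such that phi(r) = C*q/(eps*r) in kT/e, r in Å.

    C = e^2 / (4*pi*eps0 * kB*T * 1 Å) ~ 560.5 at 298.15 K.
    """
    return sc.e**2 / (4.0 * np.pi * sc.epsilon_0 * sc.k * temperature * 1e-10)


def debye_kappa(ionic_strength: float, eps_solvent: float,
                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse Debye screening length kappa_D in 1/Å.

    ionic_strength in mol/L for a symmetric 1:1 electrolyte.
    At 135 mM in eps 78.54 water this gives ~0.121 1/Å (Debye length ~8.3 Å).
    """
    if ionic_strength <= 0.0:
        return 0.0
    # kappa^2 = 2 NA e^2 I / (eps0 eps_s kB T), I in mol/m^3; convert to Å^-2
    kappa2_m = (2.0 * sc.N_A * sc.e**2 * ionic_strength * 1000.0
                / (sc.epsilon_0 * eps_solvent * sc.k * temperature))
    return float(np.sqrt(kappa2_m) * 1e-10)


def debye_length(ionic_strength: float, eps_solvent: float = 78.54,
                 temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Debye screening length in Å (inf for zero ionic strength)."""
    k = debye_kappa(ionic_strength, eps_solvent, temperature)
    return float("inf") if k == 0.0 else 1.0 / k
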