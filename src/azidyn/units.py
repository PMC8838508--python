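"""Physical constants and unit conversions.

The internal unit system is Å, fs, amu, kcal/mol (AKMA-like), so the
harmonic force-field constants quoted for the azide label can be used
verbatim.  Every frequency/energy conversion funnels through the constants
defined here — one source of truth.
"""

from __future__ import annotations

import math

from scipy import constants as _c

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872041

#: Speed of light, cm/fs (for wavenumber axes).
C_CM_PER_FS = _c.c * 100.0 * 1e-15

#: hc/kB in cm*K: converts wavenumber*T into the dimensionless x = beta*hbar*omega.
HC_OVER_KB_CM_K = _c.h * _c.c * 100.0 / _c.k

#: 1 amu*Å^2/fs^2 expressed in kcal/mol (kinetic-energy conversion).
KCAL_PER_AMU_A2_FS2 = _c.atomic_mass * 1e-20 / 1e-30 * _c.N_A / 4184.0

#: Mass-weighted Hessian eigenvalue (kcal/mol/Å^2/amu) -> angular frequency^2 (1/fs^2).
OMEGA2_PER_EIGVAL = 1.0 / KCAL_PER_AMU_A2_FS2


def eigval_to_wavenumber(eigval: float) -> float:
    """Convert a mass-weighted Hessian eigenvalue (kcal/mol/Å²/amu) to cm⁻¹.

    Negative eigenvalues (numerical noise around zero modes) map to 0.
    """
    if eigval <= 0.0:
        return 0.0
    omega = math.sqrt(eigval * OMEGA2_PER_EIGVAL)  # rad/fs
    return omega / (2.0 * math.pi * C_CM_PER_FS)
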