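"""Physical constants and 511 keV-regime attenuation data.

Cross-section tables are coarse (six energies, log-log interpolation)
but adequate for relative design comparisons between scanner
configurations; they are not a replacement for a full photon
cross-section library.
"""

from __future__ import annotations

import numpy as np

#: speed of light in mm/ns
C_MM_PER_NS = 299.792458

#: speed of light in m/s (value used for TOF localisation arithmetic)
C_M_PER_S = 2.998e8

#: FWHM of a Gaussian per unit standard deviation, 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: annihilation photon energy, keV
E511 = 511.0

#: electron rest energy, keV (Compton kinematics)
ELECTRON_REST_KEV = 510.998950

#: tracking cutoff: photons below this energy are locally absorbed, keV
ENERGY_CUTOFF_KEV = 50.0

#: maximum number of scatters tracked per photon
MAX_SCATTERS = 5

# ---------------------------------------------------------------------------
# Attenuation tables: total linear attenuation mu (1/cm) and photoelectric
# fraction of interactions, tabulated at six energies (keV) and interpolated
# log-log in between.  Sources: NIST XCOM mass attenuation coefficients for
# water and polyethylene (rho = 0.95 g/cm3); LYSO values from published
# attenuation lengths (rho = 7.1 g/cm3, ~0.87/cm total at 511 keV,
# photofraction ~0.33).  Values rounded; accuracy ~few % which is second
# order for the design metrics computed here.
# ---------------------------------------------------------------------------

ATTEN_ENERGIES_KEV = np.array([50.0, 100.0, 170.0, 255.0, 340.0, 511.0])

# material codes used by the Monte Carlo kernels
MAT_AIR = 0
MAT_WATER = 1
MAT_POLYETHYLENE = 2
MAT_LYSO = 3

MATERIAL_NAMES = {
    MAT_AIR: "air",
    MAT_WATER: "water",
    MAT_POLYETHYLENE: "polyethylene",
    MAT_LYSO: "lyso",
}

# mu total (1/cm), rows: air, water, polyethylene, LYSO
MU_TOTAL_PER_CM = np.array(
    [
        [2.6e-4, 1.9e-4, 1.6e-4, 1.4e-4, 1.3e-4, 1.1e-4],  # air (negligible)
        [0.227, 0.171, 0.145, 0.126, 0.113, 0.0958],        # water
        [0.198, 0.163, 0.139, 0.121, 0.108, 0.0917],        # polyethylene
        [40.0, 22.0, 6.5, 2.6, 1.55, 0.87],                 # LYSO
    ]
)

# photoelectric fraction of interactions (rest treated as Compton)
PE_FRACTION = np.array(
    [
        [0.01, 0.002, 0.001, 0.0005, 0.0003, 0.0002],  # air
        [0.03, 0.006, 0.002, 0.001, 0.0005, 0.0002],   # water
        [0.015, 0.003, 0.001, 0.0005, 0.0003, 0.0001],  # polyethylene
        [0.95, 0.90, 0.72, 0.52, 0.41, 0.33],           # LYSO
    ]
)

_LOG_E = np.log(ATTEN_ENERGIES_KEV)
_LOG_MU = np.log(MU_TOTAL_PER_CM)


def mu_total(material: int, energy_kev) -> np.ndarray | float:
    """Total linear attenuation coefficient (1/cm), log-log interpolated."""
    e = np.clip(energy_kev, ATTEN_ENERGIES_KEV[0], ATTEN_ENERGIES_KEV[-1])
    return np.exp(np.interp(np.log(e), _LOG_E, _LOG_MU[material]))


def pe_fraction(material: int, energy_kev) -> np.ndarray | float:
    """Photoelectric fraction of interactions at the given energy."""
    e = np.clip(energy_kev, ATTEN_ENERGIES_KEV[0], ATTEN_ENERGIES_KEV[-1])
    return np.interp(np.log(e), _LOG_E, PE_FRACTION[material])


#: mu of water at 511 keV, 1/cm -- used in closed-form checks
MU_WATER_511 = float(MU_TOTAL_PER_CM[MAT_WATER, -1])

#: mu of LYSO at 511 keV, 1/cm
MU_LYSO_511 = float(MU_TOTAL_PER_CM[MAT_LYSO, -1])
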