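"""Physical constants and nuclear-data values used across the package.

All decay data are for ¹⁷⁷Lu. Energies in MeV, lengths in μm unless noted,
time in hours, dose in Gy, dose rate in mGy/h.
"""

import numpy as np

MEV_TO_J = 1.602176634e-13
ELECTRON_MASS_MEV = 0.51099895
FINE_STRUCTURE = 1.0 / 137.035999

#: Water: ratio of atomic number to mass number (mass-weighted) and mean
#: excitation energy, used by the Berger–Seltzer collision stopping power.
WATER_Z_OVER_A = 0.55509
WATER_I_MEV = 75e-6
#: Radiation length of water in cm (multiple-scattering scale).
WATER_X0_CM = 36.08
WATER_DENSITY_G_CM3 = 1.0

#: ¹⁷⁷Lu physical half-life, 6.647 d (standard nuclear data; needed to
#: separate biological clearance from physical decay when fitting).
LU177_HALF_LIFE_H = 6.647 * 24.0
LAMBDA_P_LU177 = np.log(2.0) / LU177_HALF_LIFE_H  # h^-1

#: β⁻ branches of ¹⁷⁷Lu: (intensity per decay, endpoint energy MeV).
LU177_BETA_BRANCHES = (
    (0.793, 0.4978),
    (0.090, 0.3848),
    (0.122, 0.1765),
)

#: Discrete electron emissions (conversion electrons; dominant K/L/M lines of
#: the 112.95 and 208.37 keV transitions): (energy MeV, nominal intensity).
#: Nominal intensities are rescaled so the discrete component carries
#: LU177_DISCRETE_ELECTRON_MEV per decay (see dose_engine.dpk).
LU177_CE_LINES = (
    (0.0476, 0.0528),
    (0.1023, 0.0362),
    (0.1108, 0.0083),
    (0.1430, 0.0055),
    (0.1977, 0.0043),
)

#: Evaluated mean electron energy per ¹⁷⁷Lu decay (β + conversion + Auger)
#: and its β-only part, from standard decay-data compilations.
LU177_ELECTRON_ENERGY_MEV = 0.1479
LU177_MEAN_BETA_MEV = 0.1333
LU177_DISCRETE_ELECTRON_MEV = LU177_ELECTRON_ENERGY_MEV - LU177_MEAN_BETA_MEV

#: Daughter nucleus charge (¹⁷⁷Hf) entering the Fermi Coulomb correction.
LU177_DAUGHTER_Z = 72
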