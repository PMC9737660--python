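"""Physical constants and water-target parameters.

All energies in MeV, lengths in cm unless a suffix says otherwise.
LET is stored in MeV/cm throughout; 1 keV/um = 10 MeV/cm.
"""

#: Electron rest energy, MeV.
ELECTRON_REST_MEV = 0.51099895

#: Atomic mass unit rest energy, MeV.  Used as the common mass-per-nucleon for
#: every species so that ions at equal kinetic energy per nucleon share the
#: same velocity exactly (this makes the Z^2 stopping-power scaling exact).
AMU_MEV = 931.49410242

#: 4 pi N_A r_e^2 m_e c^2, MeV cm^2 / mol.
BETHE_K = 0.307075

#: Z/A of liquid water (10 electrons / 18.0153 g/mol).
Z_OVER_A_WATER = 10.0 / 18.0153

#: Density of liquid water, g/cm^3.
RHO_WATER = 1.0

#: Density of liquid water, ug/cm^3 (for the Birks kB unit conversion).
RHO_WATER_UG_CM3 = 1.0e6

#: Mean excitation energy of liquid water, MeV.
I_WATER_MEV = 75.0e-6

#: Validity floor of the stopping-power formula, MeV/u.
ENERGY_CUTOFF_MEV_U = 1.0

#: Residual pathlength of a proton below the cutoff, mm of water
#: (constant tail; scaled by A/Z^2 for other ions).
SUBCUTOFF_RANGE_MM = 0.0246

#: MeV/cm per keV/um.
MEV_CM_PER_KEV_UM = 10.0

#: Default seed for every stochastic routine.
DEFAULT_SEED = 20221125
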