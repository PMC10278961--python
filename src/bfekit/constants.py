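"""Physical constants in the AMBER-compatible unit system.

Energies are kcal/mol, distances Angstrom, charges elementary charges,
masses amu, temperatures Kelvin.
"""

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: Coulomb constant, kcal Angstrom / (mol e^2)
COULOMB = 332.0637

#: Default interior/exterior dielectric constants
EPS_IN_DEFAULT = 1.0
EPS_OUT_DEFAULT = 80.0

#: Nonpolar solvation: gamma (kcal/(mol A^2)) and offset b (kcal/mol)
SASA_GAMMA = 0.0072
SASA_B = 0.0

#: Water probe radius, Angstrom
PROBE_RADIUS = 1.4

#: AMBER 1-4 scaling conventions
SCEE = 1.0 / 1.2   # electrostatic 1-4 scale
SCNB = 1.0 / 2.0   # Lennard-Jones 1-4 scale

#: GB(OBC, variant 1) rescaling parameters and intrinsic-radius offset (A)
OBC1_ALPHA = 0.8
OBC1_BETA = 0.0
OBC1_GAMMA = 2.909125
GB_OFFSET = 0.09

#: unit conversion: Hessian eigenvalue (kcal/mol/A^2/amu) -> omega^2 (s^-2)
#: 1 kcal/mol = 4184 J/mol; amu*A^2*N_A = 1e-23 kg m^2 / mol
EIG_TO_OMEGA2 = 4184.0 / 1.0e-23

#: Planck constant (J s), Boltzmann (J/K), gas constant (kcal/(mol K))
PLANCK_SI = 6.62607015e-34
KB_SI = 1.380649e-23
R_GAS = KB

#: standard atomic masses (amu) for toy elements
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "NA": 22.990, "BR": 79.904,
    "X": 12.0,
}
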