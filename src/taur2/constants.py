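"""Physical constants and unit conventions.

All internal computation uses Å, kcal/mol, elementary charges and ps.
Radius of gyration, end-to-end distance and SASA are converted to nm /
nm² only at the reporting layer (``EnsembleSeries``, TSV tables).
"""

#: Electrostatic conversion constant, kcal·Å/(mol·e²) (AMBER convention).
COULOMB_CONSTANT = 332.0637

#: Boltzmann constant, kcal/(mol·K).
BOLTZMANN_KCAL = 0.0019872

#: Simulation temperature of the study, K.
DEFAULT_TEMPERATURE = 310.0

#: Solvent probe radius for SASA, Å.
DEFAULT_PROBE_RADIUS = 1.4

#: Interior / exterior dielectric constants for generalized Born.
DEFAULT_DIELECTRIC_IN = 1.0
DEFAULT_DIELECTRIC_OUT = 78.5

#: Surface-tension coefficient for the nonpolar solvation term, kcal/mol/Å².
DEFAULT_NP_GAMMA = 0.0072
DEFAULT_NP_BETA = 0.0

#: Conversion used by AMBER parm7 files: internal charge / 18.2223 = e.
PRMTOP_CHARGE_SCALE = 18.2223

ANGSTROM_PER_NM = 10.0
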