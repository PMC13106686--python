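"""Physical constants and unit conventions.

The package uses GROMACS-style molecular units throughout:
length nm, time ps, mass amu, energy kJ/mol, charge in units of the
elementary charge, temperature K.  In these units the Boltzmann constant
is ``KB`` and masses in amu combine with kJ/mol and nm to give time in ps
without further conversion factors.
"""

# Boltzmann constant, kJ/mol/K (CODATA 2018 exact)
KB = 8.314462618e-3

# Coulomb prefactor e^2 N_A / (4 pi eps0), kJ mol^-1 nm e^-2; divide by the
# relative permittivity for a screened medium.
COULOMB = 138.935458

# SI constants used for the Debye length (the only place SI enters)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN_SI = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

# 1 amu/nm^3 expressed in mg/cm^3 (mass-concentration conversion)
AMU_PER_NM3_TO_MG_PER_CM3 = 1.66053907

# 1 kJ/mol/nm^3 expressed in bar (pressure conversion for the barostat)
KJ_PER_MOL_NM3_TO_BAR = 16.6054
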