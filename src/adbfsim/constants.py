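"""Unit system and physical constants.

All quantities in the package use a single internal unit system:
length in angstrom (A), time in femtosecond (fs), mass in atomic mass
units (amu), energy in kcal/mol.  In these units an acceleration obtained
from a force in kcal/mol/A divided by a mass in amu must be multiplied by
``ACC_PER_FORCE`` to land in A/fs^2.
"""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872042586408316

#: (kcal mol^-1 A^-1) / amu  ->  A fs^-2.
#: Exact given 1 cal = 4.184 J: 4184 J/mol/A / (g/mol) = 4.184e16 m/s^2.
ACC_PER_FORCE = 4.184e-4

#: amu A^2 fs^-2 -> kcal/mol (inverse of ACC_PER_FORCE).
KE_TO_KCAL = 1.0 / ACC_PER_FORCE
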