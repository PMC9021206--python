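"""Physical constants and unit conventions.

Units follow the GROMACS convention throughout the package: length in nm,
time in ps, energy in kJ mol^-1, mass in amu, charge in elementary charges.
Temperature in K.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.00831446261815324

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_ELEC = 138.935458

#: Common CG bead diameter sigma, nm (shared by every LJ pair in the models)
SIGMA = 0.47

#: Avogadro-derived conversion: number density in nm^-3 -> concentration in mol/L
NM3_TO_MOLAR = 1.0 / 0.6022140857
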