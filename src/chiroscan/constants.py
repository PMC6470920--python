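"""Physical constants and unit conventions.

Internal units throughout the package: kcal/mol (energy), Å (length),
ps (time), amu (mass), elementary charges (charge), rad (angle).
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872

#: Coulomb constant kappa, kcal·Å/(mol·e²) (AMBER convention).
COULOMB_K = 332.0522

#: Conversion factor kcal/mol -> amu·Å²/ps² (1 kcal = 4184 J; 1 amu·Å²/ps²
#: corresponds to 10 J/mol, so the factor is 418.4).
KCAL_TO_AKMA = 418.4
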