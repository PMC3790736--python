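"""Unit conventions and physical constants.

The package works in the AMBER-style unit system throughout:

* length        Å
* charge        elementary charge e
* energy        kcal/mol
* mass          g/mol (amu)
* time          fs (MD integration), ps (trajectory timestamps)

``COULOMB`` converts q_i q_j / r_ij (e²/Å) to kcal/mol.
"""

import math

#: Coulomb constant, kcal·Å/(mol·e²) — AMBER convention.
COULOMB: float = 332.06371

#: Boltzmann constant, kcal/(mol·K).
KB: float = 0.0019872041

#: kcal/mol per (amu·Å²/fs²); divides forces to get accelerations in Å/fs².
#: 1 amu·Å²/fs² = 1e7 J/mol / 4184 J/kcal.
MASS_ACC: float = 1.0e7 / 4184.0

SQRT_PI: float = math.sqrt(math.pi)
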