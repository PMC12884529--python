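"""Physical constants (CODATA 2018), centralized.

All modules import from here so that every energy, potential and
dimensionless-group computation uses one consistent constants table.
"""

from __future__ import annotations

#: Boltzmann constant [J/K]
K_B = 1.380649e-23
#: Avogadro constant [1/mol]
N_A = 6.02214076e23
#: Gas constant [J/(mol K)]
R_GAS = K_B * N_A
#: Elementary charge [C]
Q0 = 1.602176634e-19
#: Faraday constant [C/mol]
FARADAY = Q0 * N_A
#: Vacuum permittivity [F/m]
EPS0 = 8.8541878128e-12
#: Relative permittivity of water at room temperature (default solvent)
EPS_R_WATER = 78.5

CONSTANTS_VERSION = "codata-2018"
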