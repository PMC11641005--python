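"""Physical constants and unit conversions.

Public interfaces use nm, pN, pN·nm, mW and turn/s; electromagnetic internals
run in SI and convert at the boundary.
"""

# Thermal energy at 23 °C (296.15 K), in pN·nm.
KBT_ROOM_PNNM = 4.089

# Boltzmann constant, pN·nm/K.
KB_PNNM_PER_K = 1.380649e-2

ROOM_TEMPERATURE_K = 296.15

# Vacuum impedance (ohm), speed of light (m/s), vacuum permittivity (F/m).
Z0_OHM = 376.730313668
C_M_PER_S = 299792458.0
EPS0_F_PER_M = 8.8541878128e-12

# Unit conversions.
NM_TO_M = 1e-9
M_TO_NM = 1e9
N_TO_PN = 1e12
NM_TO_PNNM = 1e21  # newton·metre -> piconewton·nanometre
MW_TO_W = 1e-3

TWO_PI = 6.283185307179586


def kbt(temperature_k: float) -> float:
    """Thermal energy k_B*T in pN·nm at the given temperature (K)."""
    return KB_PNNM_PER_K * temperature_k
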