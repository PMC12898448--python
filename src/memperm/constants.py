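"""Physical constants and unit conversions.

Internal units are nm, ns, K and kcal/mol throughout the package; permeabilities
are converted to cm/s only at the reporting boundary (1 nm/ns = 100 cm/s).
"""

#: Boltzmann constant in kcal mol^-1 K^-1 (CODATA R / 4184).
KB_KCAL_PER_MOL_K = 1.987204259e-3

#: Avogadro's number, mol^-1.
AVOGADRO = 6.02214076e23

#: 1 nm/ns expressed in cm/s.
NM_PER_NS_TO_CM_PER_S = 100.0

#: Coordinate conversion at the trajectory-reader boundary (MDAnalysis uses A, ps).
ANGSTROM_PER_NM = 10.0
PS_PER_NS = 1000.0


def thermal_energy(temperature: float) -> float:
    """kB*T in kcal/mol for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
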