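"""Physical constants and unit conversions used across the package.

Internal unit conventions: temperatures in kelvin, densities in g/cm^3,
lengths in nm, times in ns, diffusivities in m^2/s, stresses/moduli in GPa,
molar energies in kJ/mol.
"""

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.015

#: Conversion factor: 1 nm^2/ns = 1e-9 m^2/s.
NM2_PER_NS_TO_M2_PER_S = 1e-9

#: Conversion factor: 1 nm^3 = 1e-21 cm^3.
NM3_TO_CM3 = 1e-21

#: Offset between Celsius and kelvin scales.
CELSIUS_OFFSET = 273.15

#: Atomic masses, g/mol (C, H, O are all the chain model needs).
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}


def celsius_to_kelvin(t_c):
    """Convert a temperature from degrees Celsius to kelvin."""
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    """Convert a temperature from kelvin to degrees Celsius."""
    return t_k - CELSIUS_OFFSET
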