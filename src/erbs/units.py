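"""Internal unit system: eV, Å, fs, amu, K.

With these base units, accelerations pick up a conversion factor because
1 eV/(Å·amu) is not 1 Å/fs².  ``ACC`` converts a force/mass ratio in
eV/(Å·amu) into Å/fs²; velocities squared in Å²/fs² divide by ``ACC`` to
come back to eV/amu.
"""

# Boltzmann constant, eV/K
KB = 8.617333e-5

# 1 eV/(Å·amu) expressed in Å/fs²
ACC = 9.64853322e-3

# kcal/mol -> eV
KCAL_MOL = 4.3364104e-2

# Coulomb constant e²/(4πε0) in eV·Å
COULOMB = 14.399645

# masses (amu) for the elements the toy systems use
MASSES = {
    1: 1.008, 2: 4.0026, 6: 12.011, 7: 14.007, 8: 15.999,
    9: 18.998, 10: 20.180, 15: 30.974, 16: 32.06, 17: 35.45,
    18: 39.948, 35: 79.904, 53: 126.90,
}

SYMBOLS = {
    1: "H", 2: "He", 6: "C", 7: "N", 8: "O", 9: "F", 10: "Ne",
    15: "P", 16: "S", 17: "Cl", 18: "Ar", 35: "Br", 53: "I",
}
NUMBERS = {v: k for k, v in SYMBOLS.items()}


def mass_of(z: int) -> float:
    try:
        return MASSES[int(z)]
    except KeyError:
        raise KeyError(f"no mass tabulated for atomic number {z}") from None
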