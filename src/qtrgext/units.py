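"""Unit conventions and physical constants.

The package works in a single consistent unit system:

* length       : Bohr
* time         : fs
* mass         : amu
* energy       : Hartree (the toy model's couplings are read as Hartree)
* charge       : elementary charge

The only non-trivial conversion is kinetic energy: with masses in amu and
velocities in Bohr/fs, ``E_kin = 0.5 * KINETIC_TO_HARTREE * m * v**2`` is in
Hartree.  All dynamics code funnels through the constants below so the unit
system is defined in exactly one place.
"""

from __future__ import annotations

#: Bohr per Angstrom (CODATA 2018 Bohr radius 0.529177210903 A).
BOHR_PER_ANGSTROM: float = 1.0 / 0.529177210903

#: Electron masses per amu.
AMU_TO_ELECTRON_MASS: float = 1822.888486209

#: Atomic time units per femtosecond.
ATU_PER_FS: float = 1.0 / 0.02418884326585747

#: (amu * Bohr^2 / fs^2) -> Hartree.
KINETIC_TO_HARTREE: float = AMU_TO_ELECTRON_MASS / ATU_PER_FS**2

#: Boltzmann constant in Hartree / K.
KB_HARTREE: float = 3.166811563e-6

# Elements supported by the XYZ reader (Z <= 54).
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca "
    "Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr "
    "Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe"
).split()

#: Element symbol -> nuclear charge, H through Xe.
ELEMENT_NUMBERS: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}

#: Nuclear charge -> element symbol.
ELEMENT_SYMBOLS: dict[int, str] = {z: s for s, z in ELEMENT_NUMBERS.items()}

#: Standard atomic weights (amu), H through Xe.
ATOMIC_MASSES: dict[str, float] = dict(
    zip(
        _SYMBOLS,
        [
            1.008, 4.0026, 6.94, 9.0122, 10.81, 12.011, 14.007, 15.999,
            18.998, 20.180, 22.990, 24.305, 26.982, 28.085, 30.974, 32.06,
            35.45, 39.948, 39.098, 40.078, 44.956, 47.867, 50.942, 51.996,
            54.938, 55.845, 58.933, 58.693, 63.546, 65.38, 69.723, 72.630,
            74.922, 78.971, 79.904, 83.798, 85.468, 87.62, 88.906, 91.224,
            92.906, 95.95, 97.0, 101.07, 102.91, 106.42, 107.87, 112.41,
            114.82, 118.71, 121.76, 127.60, 126.90, 131.29,
        ],
    )
)
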