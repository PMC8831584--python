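"""Unit conversions between atomic units and interface units.

All internal physics is done in Hartree atomic units (bohr, hartree,
a.u. dipoles); file and CLI interfaces use angstrom and eV.
"""

ANGSTROM_PER_BOHR = 0.52917721
EV_PER_HARTREE = 27.211386
DEBYE_PER_AU = 2.5417465


def angstrom_to_bohr(x):
    return x / ANGSTROM_PER_BOHR


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def hartree_to_ev(x):
    return x * EV_PER_HARTREE


def ev_to_hartree(x):
    return x / EV_PER_HARTREE


def au_to_debye(x):
    return x * DEBYE_PER_AU


def debye_to_au(x):
    return x / DEBYE_PER_AU
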