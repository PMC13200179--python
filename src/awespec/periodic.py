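"""Element symbols and atomic numbers, H through Og.

Atomic numbers serve as the default neighbor weights of the weighted
atom-centered symmetry functions, so the table lives here rather than being
pulled from a heavyweight structure library.
"""

_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og"
).split()

ATOMIC_NUMBERS: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}


def atomic_number(symbol: str) -> int:
    """Return Z for an element symbol; raises KeyError for unknown symbols."""
    return ATOMIC_NUMBERS[symbol]


def is_element(symbol: str) -> bool:
    return symbol in ATOMIC_NUMBERS
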