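"""Element inference from atom names, with masses and van der Waals radii.

GRO files carry neither masses nor radii, so both are assigned from the
atom name: the leading alphabetic characters are matched first against
two-letter element symbols (Cl, Na, Br, ...) and then against the first
letter. Per-name overrides take precedence over inference.

Masses in atomic mass units; radii in nm (Bondi-type table).
"""

from __future__ import annotations

from .errors import SelectionError

# symbol -> (mass / amu, vdW radius / nm)
ELEMENT_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.008, 0.120),
    "C": (12.011, 0.170),
    "N": (14.007, 0.155),
    "O": (15.999, 0.152),
    "F": (18.998, 0.147),
    "P": (30.974, 0.180),
    "S": (32.06, 0.180),
    "K": (39.098, 0.275),
    "Na": (22.990, 0.227),
    "Cl": (35.45, 0.175),
    "Br": (79.904, 0.185),
    "I": (126.904, 0.198),
    "Mg": (24.305, 0.173),
    "Ca": (40.078, 0.231),
    "Zn": (65.38, 0.139),
}

# Two-letter symbols eligible for prefix matching. "HO"/"CA"-style protein
# names would otherwise collide with holmium/calcium; only symbols that are
# unambiguous in lipid/water/ion systems are listed.
_TWO_LETTER = {"Na", "Cl", "Br", "Mg", "Ca", "Zn"}


def guess_element(atom_name: str) -> str:
    """Infer the element symbol from a GRO atom name.

    Leading digits are skipped (e.g. "1HW" -> H); the alphabetic prefix is
    tried as a two-letter symbol, then as a single letter.
    """
    alpha = ""
    started = False
    for ch in atom_name:
        if ch.isalpha():
            alpha += ch
            started = True
        elif started:
            break
    if not alpha:
        raise SelectionError(f"cannot infer element from atom name {atom_name!r}")
    two = alpha[:2].capitalize()
    if two in _TWO_LETTER:
        return two
    one = alpha[0].upper()
    if one in ELEMENT_TABLE:
        return one
    raise SelectionError(
        f"no element entry for atom name {atom_name!r} (inferred {one!r}); "
        "provide an override"
    )


def mass_of(element: str) -> float:
    try:
        return ELEMENT_TABLE[element][0]
    except KeyError:
        raise SelectionError(f"unknown element {element!r}") from None


def vdw_radius_of(element: str) -> float:
    try:
        return ELEMENT_TABLE[element][1]
    except KeyError:
        raise SelectionError(f"unknown element {element!r}") from None
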