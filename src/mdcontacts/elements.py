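"""Element masses and element inference for PDB atoms.

A small fixed table of standard atomic weights (daltons) covering the
elements that occur in protein heavy atoms plus hydrogen; anything outside
the table raises :class:`~mdcontacts.errors.ElementError` so that silent
mass errors cannot propagate into center-of-mass computations.
"""

from __future__ import annotations

from .errors import ElementError

# Standard atomic weights (IUPAC 2021), daltons.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
}


def mass_of(element: str, *, atom_label: str = "") -> float:
    """Look up the atomic mass for an element symbol.

    Raises ElementError naming the offending atom when the symbol is not
    in the internal table.
    """
    key = element.strip().upper()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        where = f" (atom {atom_label})" if atom_label else ""
        raise ElementError(
            f"cannot resolve element {element!r}{where}; known: "
            + ", ".join(sorted(ATOMIC_MASSES))
        ) from None


def infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Used when the element column is absent. Digits and primes are
    stripped; the leading letter(s) decide. In polymer context two-letter
    names such as ``CA``/``CB``/``CG`` are carbons, ``NE``/``ND`` nitrogens,
    etc., so a one-letter match is preferred over the two-letter metals.
    """
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if not stripped:
        raise ElementError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[0] in ATOMIC_MASSES:
        return stripped[0]
    if stripped[:2] in ATOMIC_MASSES:
        return stripped[:2]
    raise ElementError(f"cannot infer element from atom name {atom_name!r}")
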