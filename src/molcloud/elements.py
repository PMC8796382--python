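"""Per-element masses and van der Waals radii.

Covers the elements dominating protein/nucleic structures; anything else
falls back to mass 0 Da and a carbon-like 1.7 Å radius with a logged
warning, so nonstandard records degrade gracefully instead of aborting.
"""
from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

#: atomic mass, Da
MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: van der Waals radius, Å (Bondi-style values)
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

FALLBACK_MASS = 0.0
FALLBACK_RADIUS = 1.70

_warned: set[str] = set()


def mass_of(element: str) -> float:
    element = element.strip().upper()
    try:
        return MASSES[element]
    except KeyError:
        _warn_unknown(element)
        return FALLBACK_MASS


def vdw_radius_of(element: str) -> float:
    element = element.strip().upper()
    try:
        return VDW_RADII[element]
    except KeyError:
        _warn_unknown(element)
        return FALLBACK_RADIUS


def _warn_unknown(element: str) -> None:
    if element not in _warned:
        _warned.add(element)
        logger.warning(
            "unknown element %r: assigning mass %.1f Da, radius %.2f A",
            element, FALLBACK_MASS, FALLBACK_RADIUS,
        )


def guess_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Follows the usual column heuristics: a name starting in column 13
    (i.e. left-padded to width 4) carries the element in its first one or
    two characters; leading digits (as in ``1HB2``) are stripped.
    """
    name = atom_name.strip()
    name = name.lstrip("0123456789")
    if not name:
        return ""
    if len(name) >= 2 and name[:2].upper() in MASSES:
        # two-letter elements would land here; none in our table besides
        # these, so single letters win below
        pass
    return name[0].upper()
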