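"""Tooth notation (FDI and Haderup) and the era-specific index teeth.

The registry's original paper forms use the Danish Haderup notation; all
public interfaces of this package use two-digit FDI codes (quadrant digit
followed by position digit).  Quadrants 1–4 are the permanent dentition
(positions 1–8), quadrants 5–8 the primary dentition (positions 1–5).

Gingivitis and pocket registrations are made on a fixed set of *index
teeth*: four teeth per dentition under the 1972–1987 criteria, and twelve
permanent teeth (the incisors plus the first molars) from 1988 on.  When a
1972–1987 index tooth is missing, the examiner scores the nearest present
neighbour in the same quadrant instead.
"""

from __future__ import annotations

from typing import Collection, Iterable, Literal

from .eras import CriteriaEra

__all__ = [
    "ALL_FDI",
    "PERMANENT_FDI",
    "PRIMARY_FDI",
    "SURFACES",
    "UNSCORABLE",
    "Dentition",
    "fdi_to_haderup",
    "haderup_to_fdi",
    "index_teeth",
    "is_permanent",
    "is_primary",
    "is_valid_fdi",
    "position",
    "quadrant",
    "substitute_missing_index_tooth",
]

Dentition = Literal["temporary", "permanent"]

#: Tooth surfaces scored for caries: mesial, distal, buccal, lingual, occlusal.
SURFACES: tuple[str, ...] = ("M", "D", "B", "L", "O")

SURFACE_NAMES = {
    "M": "mesial",
    "D": "distal",
    "B": "buccal",
    "L": "lingual",
    "O": "occlusal",
}

PERMANENT_FDI: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)
)
PRIMARY_FDI: tuple[int, ...] = tuple(
    10 * q + p for q in (5, 6, 7, 8) for p in range(1, 6)
)
ALL_FDI: tuple[int, ...] = PERMANENT_FDI + PRIMARY_FDI

#: Sentinel returned when no tooth in the quadrant can stand in for a
#: missing index tooth.
UNSCORABLE = "unscorable"


def quadrant(fdi: int) -> int:
    return fdi // 10


def position(fdi: int) -> int:
    return fdi % 10


def is_valid_fdi(fdi: int) -> bool:
    q, p = divmod(fdi, 10)
    if q in (1, 2, 3, 4):
        return 1 <= p <= 8
    if q in (5, 6, 7, 8):
        return 1 <= p <= 5
    return False


def is_permanent(fdi: int) -> bool:
    return quadrant(fdi) <= 4


def is_primary(fdi: int) -> bool:
    return quadrant(fdi) >= 5


def _check_fdi(fdi: int) -> None:
    if not is_valid_fdi(fdi):
        raise ValueError(f"{fdi} is not a valid FDI tooth code")


# Haderup writes the position digit next to a +/- marking the arch, with the
# sign placed on the cheek side of the digit: upper right "6+", upper left
# "+6", lower left "-6", lower right "6-".  Primary teeth carry a leading
# zero: "05+", "+05", "-05", "05-".

_QUADRANT_STYLE = {
    1: ("", "+"),  # upper right: trailing +
    2: ("+", ""),  # upper left: leading +
    3: ("-", ""),  # lower left: leading -
    4: ("", "-"),  # lower right: trailing -
}


def fdi_to_haderup(fdi: int) -> str:
    """Convert a two-digit FDI code to its Haderup string."""
    _check_fdi(fdi)
    q, p = divmod(fdi, 10)
    primary = q >= 5
    prefix, suffix = _QUADRANT_STYLE[q - 4 if primary else q]
    digit = f"0{p}" if primary else str(p)
    return f"{prefix}{digit}{suffix}"


def haderup_to_fdi(haderup: str) -> int:
    """Convert a Haderup string back to its FDI code (inverse of
    :func:`fdi_to_haderup` on every valid tooth)."""
    s = haderup.strip()
    for quad_base, (prefix, suffix) in _QUADRANT_STYLE.items():
        if prefix and not s.startswith(prefix):
            continue
        if suffix and not s.endswith(suffix):
            continue
        digits = s[len(prefix): len(s) - len(suffix)]
        if not digits.isdigit():
            continue
        primary = digits.startswith("0")
        p = int(digits)
        q = quad_base + 4 if primary else quad_base
        fdi = 10 * q + p
        if is_valid_fdi(fdi):
            return fdi
    raise ValueError(f"{haderup!r} is not a valid Haderup tooth code")


_ERA1_INDEX: dict[Dentition, frozenset[int]] = {
    "temporary": frozenset({52, 55, 82, 85}),
    "permanent": frozenset({12, 16, 42, 46}),
}

#: Twelve permanent index teeth used from 1988 on: the eight incisors plus
#: the four first molars.
_ERA23_INDEX = frozenset({11, 12, 21, 22, 31, 32, 41, 42, 16, 26, 36, 46})


def index_teeth(era: CriteriaEra, dentition: Dentition) -> frozenset[int]:
    """Index teeth registered for gingivitis/pockets under an era's criteria.

    1972–1987 used four teeth per dentition (52/55/82/85 in the primary,
    12/16/42/46 in the permanent); 1988 onward uses the same twelve
    permanent teeth regardless of dentition.
    """
    if dentition not in ("temporary", "permanent"):
        raise ValueError(f"unknown dentition {dentition!r}")
    if era is CriteriaEra.ERA1:
        return _ERA1_INDEX[dentition]
    if era in (CriteriaEra.ERA2, CriteriaEra.ERA3):
        return _ERA23_INDEX
    raise ValueError(f"unknown era {era!r}")


def substitute_missing_index_tooth(
    era: CriteriaEra, tooth: int, present_teeth: Collection[int]
) -> int | str:
    """Resolve a 1972–1987 index tooth against the teeth actually present.

    Returns the tooth itself when present; otherwise the present tooth in
    the same quadrant with the smallest positional distance (ties broken
    toward the lower position number, a fixed deterministic rule).  When
    the quadrant holds no tooth at all, the sentinel :data:`UNSCORABLE` is
    returned — the registration cannot be made.
    """
    if era is not CriteriaEra.ERA1:
        raise ValueError("neighbour substitution applies only to the 1972–1987 criteria")
    _check_fdi(tooth)
    if tooth not in _ERA1_INDEX["temporary"] | _ERA1_INDEX["permanent"]:
        raise ValueError(f"tooth {tooth} is not a 1972–1987 index tooth")
    present = {t for t in present_teeth if is_valid_fdi(t)}
    if tooth in present:
        return tooth
    q = quadrant(tooth)
    candidates = sorted(t for t in present if quadrant(t) == q)
    if not candidates:
        return UNSCORABLE
    return min(candidates, key=lambda t: (abs(position(t) - position(tooth)), position(t)))
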