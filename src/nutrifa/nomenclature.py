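"""Shorthand fatty-acid nomenclature: parsing, formatting, classification.

Fatty acids (FAs) are written throughout the lipidomics literature in the
shorthand ``C:Dn-x`` form, where ``C`` is the number of acyl carbons, ``D``
the number of double bonds, and ``n-x`` (equivalently ``ω-x`` / ``omega-x``)
the position of the first double bond counted from the methyl end.  Branched
chains carry an ``i`` (iso) or ``ai`` (anteiso) prefix, e.g. ``ai15:0``.
Conjugated linoleic acid is written ``CLA`` (an 18:2 whose double bonds are
conjugated rather than methylene-interrupted).

This module provides a strict parser for that dialect family, a canonical
formatter (plain-hyphen ``C:Dn-x``), and a configurable classifier that maps
each FA to the class tags used in nutritional lipidomics: SFA / MUFA / PUFA
/ UFA, the omega families n-3 and n-6, the branched-and-odd overlay BFA, and
long-chain PUFA (LC-PUFA, >= 20 carbons).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "FattyAcid",
    "ClassificationScheme",
    "DEFAULT_SCHEME",
    "NomenclatureError",
    "parse_fa",
    "format_fa",
    "classify",
]

#: Omega (first double bond from methyl end) positions that occur in
#: ruminant tissues and forage plants; anything else is rejected as a typo.
_KNOWN_OMEGA = frozenset({3, 5, 6, 7, 9})

_BRANCHES = ("normal", "iso", "anteiso")


class NomenclatureError(ValueError):
    """Raised for malformed or chemically impossible FA shorthand."""


@dataclass(frozen=True, slots=True)
class FattyAcid:
    """Parsed identity of one acyl species.

    Parameters
    ----------
    carbons
        Number of acyl carbons (>= 2).
    double_bonds
        Number of carbon-carbon double bonds (>= 0, at most ``carbons // 2``).
    omega
        Position of the first double bond from the methyl end (3, 5, 6, 7
        or 9), or ``None`` when the FA is saturated or the position is
        unknown/ambiguous (branched monoenes, conjugated species).
    branch
        ``"normal"``, ``"iso"`` or ``"anteiso"``.
    conjugated
        ``True`` for conjugated linoleic acid (CLA, 18:2).
    """

    carbons: int
    double_bonds: int
    omega: int | None = None
    branch: str = "normal"
    conjugated: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise NomenclatureError(f"carbons must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise NomenclatureError("double_bonds must be >= 0")
        if self.double_bonds > self.carbons // 2:
            raise NomenclatureError(
                f"{self.carbons}:{self.double_bonds} is impossible: at most "
                f"{self.carbons // 2} double bonds fit on {self.carbons} carbons"
            )
        if self.omega is not None and self.omega not in _KNOWN_OMEGA:
            raise NomenclatureError(f"unknown omega position n-{self.omega}")
        if self.double_bonds == 0 and self.omega is not None:
            raise NomenclatureError("a saturated FA has no omega class")
        if self.branch not in _BRANCHES:
            raise NomenclatureError(f"unknown branch type {self.branch!r}")
        if self.conjugated:
            if (self.carbons, self.double_bonds) != (18, 2):
                raise NomenclatureError(
                    "only conjugated 18:2 (CLA) is supported"
                )
            if self.omega is not None:
                raise NomenclatureError("CLA carries no single omega class")

    @property
    def label(self) -> str:
        """Canonical shorthand label (see :func:`format_fa`)."""
        return format_fa(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


# -- parsing ----------------------------------------------------------------

_DASH_RE = re.compile("[‐‑‒–—−]")
_OMEGA_RE = re.compile(r"(omega|ω)\s*-?\s*", re.IGNORECASE)
_MAIN_RE = re.compile(r"(?P<branch>ai|i)?(?P<c>\d+):(?P<d>\d+)(?:\s*n\s*-?\s*(?P<x>\d+))?")
_GEOM_RE = re.compile(r"(?P<pos>(?:[ct]\d+,)*[ct]\d+)-(?P<c>\d+):(?P<d>\d+)", re.IGNORECASE)


def _normalize(label: str) -> str:
    s = _DASH_RE.sub("-", label.strip())
    s = _OMEGA_RE.sub("n-", s)
    return s


@lru_cache(maxsize=4096)
def _parse_cached(label: str, require_omega: bool) -> FattyAcid:
    s = _normalize(label)
    if not s:
        raise NomenclatureError("empty FA label")

    if s.upper() == "CLA":
        return FattyAcid(18, 2, None, "normal", True)

    if s.lower().startswith("isomers of "):
        # Fig-style pooled isomer tokens ("isomers of 17:1"): position unknown.
        return _parse_cached(s[11:], False)

    m = _GEOM_RE.fullmatch(s)
    if m is not None:
        positions = sorted(int(p) for p in re.findall(r"\d+", m.group("pos")))
        carbons, db = int(m.group("c")), int(m.group("d"))
        conjugated = any(b - a == 2 for a, b in zip(positions, positions[1:]))
        if conjugated:
            return FattyAcid(carbons, db, None, "normal", True)
        omega = carbons - positions[-1]
        if omega not in _KNOWN_OMEGA:
            raise NomenclatureError(
                f"{label!r}: double-bond positions imply unknown omega n-{omega}"
            )
        return FattyAcid(carbons, db, omega)

    m = _MAIN_RE.fullmatch(s)
    if m is None:
        raise NomenclatureError(f"malformed FA label {label!r}")
    branch = {"i": "iso", "ai": "anteiso", None: "normal"}[m.group("branch")]
    carbons, db = int(m.group("c")), int(m.group("d"))
    omega = int(m.group("x")) if m.group("x") else None
    if omega is None and db > 0 and branch == "normal" and require_omega:
        raise NomenclatureError(
            f"{label!r}: unsaturated FA without an omega position; "
            "write e.g. '18:1n-9', or parse with require_omega=False "
            "for ambiguous isomer pools"
        )
    return FattyAcid(carbons, db, omega, branch)


def parse_fa(label: str, *, require_omega: bool = True) -> FattyAcid:
    """Parse a shorthand FA label into a :class:`FattyAcid`.

    Accepted dialects: ``C:D``, ``C:Dn-x`` with hyphen, en-dash or any
    Unicode dash, ``ω-x`` / ``omega-x``, ``i``/``ai`` branch prefixes,
    the token ``CLA``, and geometry-prefixed forms such as ``c9,t11-18:2``
    (conjugated positions) or ``c9,c12-18:2`` (methylene-interrupted, the
    omega class is derived from the last position).

    By default an unsaturated straight-chain FA without an omega position
    is an error rather than a silent "unknown": real tables only omit the
    position for pooled isomer peaks, which you must opt into with
    ``require_omega=False``.
    """
    return _parse_cached(label, require_omega)


def format_fa(fa: FattyAcid) -> str:
    """Canonical shorthand for a :class:`FattyAcid` (plain-hyphen dialect).

    Branch prefix precedes the carbon count (``ai17:0``); conjugated 18:2
    is written ``CLA``; saturated and position-unknown species carry no
    omega suffix.  ``parse_fa(format_fa(x), require_omega=False) == x``.
    """
    if fa.conjugated:
        return "CLA"
    prefix = {"normal": "", "iso": "i", "anteiso": "ai"}[fa.branch]
    suffix = f"n-{fa.omega}" if fa.omega is not None else ""
    return f"{prefix}{fa.carbons}:{fa.double_bonds}{suffix}"


def canonical(label: str, *, require_omega: bool = False) -> str:
    """Canonical form of a label in any accepted dialect."""
    return format_fa(parse_fa(label, require_omega=require_omega))


# -- classification ---------------------------------------------------------


@dataclass(frozen=True, slots=True)
class ClassificationScheme:
    """Options for mapping FAs to class tags.

    ``bfa_in_sfa``
        Whether odd-chain and branched saturated FAs count inside SFA
        (they always receive the BFA overlay tag).  Tissue tables
        conventionally sum them into SFA; set ``False`` to keep them out
        of the SFA total and report them only under BFA.
    ``cla_in_pufa``
        Whether CLA counts toward PUFA.  Disabling this leaves CLA tagged
        UFA only, which breaks the SFA/MUFA/PUFA partition for that one
        species; the default preserves it.
    ``cla_in_n6``
        Whether CLA counts toward the n-6 family (excluded by default:
        its first double bond position is not a clean n-6).
    """

    bfa_in_sfa: bool = True
    cla_in_pufa: bool = True
    cla_in_n6: bool = False


DEFAULT_SCHEME = ClassificationScheme()


def classify(fa: FattyAcid, scheme: ClassificationScheme = DEFAULT_SCHEME) -> frozenset[str]:
    """Class tags for one FA.

    Tags are drawn from ``{SFA, MUFA, PUFA, UFA, n3, n6, BFA, LCPUFA}``.
    Under the default scheme every FA is exactly one of SFA / MUFA / PUFA,
    UFA is the union of MUFA and PUFA, and BFA (branched or odd-chain) is
    an overlay that can coexist with any saturation class.
    """
    tags: set[str] = set()
    if fa.double_bonds == 0:
        is_bfa = fa.branch != "normal" or fa.carbons % 2 == 1
        if not is_bfa or scheme.bfa_in_sfa:
            tags.add("SFA")
    else:
        tags.add("UFA")
        if fa.double_bonds == 1:
            tags.add("MUFA")
        elif fa.conjugated:
            if scheme.cla_in_pufa:
                tags.add("PUFA")
            if scheme.cla_in_n6:
                tags.add("n6")
        else:
            tags.add("PUFA")
            if fa.omega == 3:
                tags.add("n3")
            elif fa.omega == 6:
                tags.add("n6")
    if "PUFA" in tags and fa.carbons >= 20:
        tags.add("LCPUFA")
    if fa.branch != "normal" or fa.carbons % 2 == 1:
        tags.add("BFA")
    return frozenset(tags)
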