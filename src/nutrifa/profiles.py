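"""Per-sample fatty-acid profiles: bases, quantification, class summaries.

A :class:`FAProfile` holds one sample's FA measurements on a stated basis
(percent of total FA, mg per g dry weight, or mg per g wet weight).  Raw
gas-chromatography peak areas are turned into mg/g content by single-point
internal-standard quantification (:func:`quantify`): a known mass of an FA
absent from the samples (methyl nonadecanoate, 19:0, by convention) is
spiked in before extraction and every analyte mass is inferred from its
area ratio to that standard.

Amounts below the reporting threshold are carried as explicit *trace*
entries: they contribute zero to sums but survive round-trips through the
CSV readers/writers, mirroring how measurement tables print "trace" rather
than a number.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

from .nomenclature import (
    ClassificationScheme,
    DEFAULT_SCHEME,
    NomenclatureError,
    classify,
    parse_fa,
)

__all__ = [
    "Basis",
    "FAProfile",
    "PeakTable",
    "ClassSummary",
    "ProfileError",
    "BasisError",
    "QuantificationError",
    "quantify",
    "to_percent",
    "class_sums",
    "epa_dha",
]


class Basis(str, enum.Enum):
    """Measurement basis of a profile."""

    PERCENT = "percent"
    MG_PER_G_DW = "mg_per_g_dw"
    MG_PER_G_WW = "mg_per_g_ww"


class ProfileError(ValueError):
    """Invalid profile contents."""


class BasisError(ProfileError):
    """An operation was applied on the wrong measurement basis."""


class QuantificationError(ValueError):
    """Invalid internal-standard quantification inputs."""


def _canonical_values(values: dict[str, float]) -> dict[str, float]:
    out: dict[str, float] = {}
    bad: list[str] = []
    for label, amount in values.items():
        try:
            key = parse_fa(label, require_omega=False).label
        except NomenclatureError:
            bad.append(label)
            continue
        if key in out:
            raise ProfileError(f"duplicate FA after canonicalization: {key!r}")
        out[key] = float(amount)
    if bad:
        raise ProfileError(f"unparseable FA labels: {bad}")
    return out


@dataclass
class FAProfile:
    """One sample's FA measurements on a stated basis.

    ``values`` maps canonical FA labels to nonnegative amounts; labels are
    canonicalized on construction (any accepted dialect, en-dash included).
    ``traces`` names FAs reported below the detection threshold; they are
    kept in ``values`` with amount 0.0.
    """

    sample_id: str
    basis: Basis
    values: dict[str, float]
    tissue: str | None = None
    age_months: int | None = None
    traces: frozenset[str] = frozenset()
    trace_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.basis = Basis(self.basis)
        self.values = _canonical_values(self.values)
        negative = {k: v for k, v in self.values.items() if v < 0}
        if negative:
            raise ProfileError(f"negative amounts: {negative}")
        self.traces = frozenset(
            parse_fa(t, require_omega=False).label for t in self.traces
        )
        for t in self.traces:
            self.values.setdefault(t, 0.0)

    def total(self) -> float:
        """Sum of all amounts on the profile's basis."""
        return float(sum(self.values.values()))

    def get(self, label: str, default: float = 0.0) -> float:
        """Amount of one FA (any dialect), 0 for absent species."""
        return self.values.get(parse_fa(label, require_omega=False).label, default)


@dataclass(frozen=True)
class PeakTable:
    """Raw GC peak areas plus internal-standard bookkeeping for one sample."""

    areas: dict[str, float]
    istd_area: float
    istd_mass_mg: float
    sample_mass_g: float
    istd_label: str = "19:0"
    sample_basis: Basis = Basis.MG_PER_G_DW
    sample_id: str = ""
    tissue: str | None = None


@dataclass(frozen=True)
class ClassSummary:
    """SFA/MUFA/PUFA/UFA/BFA/n-3/n-6 totals for one profile."""

    sfa: float
    mufa: float
    pufa: float
    ufa: float
    bfa: float
    n3: float
    n6: float
    total: float
    basis: Basis

    def as_dict(self) -> dict[str, float]:
        return {
            "SFA": self.sfa,
            "MUFA": self.mufa,
            "PUFA": self.pufa,
            "UFA": self.ufa,
            "BFA": self.bfa,
            "n3": self.n3,
            "n6": self.n6,
            "total": self.total,
        }


def quantify(pt: PeakTable) -> FAProfile:
    """Internal-standard quantification of a peak table to mg/g content.

    Single-point formula: ``c_i = (A_i / A_istd) * m_istd / m_sample``,
    i.e. content is linear in each analyte area, inversely proportional to
    the standard's area and to the sample mass.  The internal standard
    itself is excluded from the output profile.
    """
    if pt.istd_area <= 0:
        raise QuantificationError("internal-standard area must be > 0")
    if pt.sample_mass_g <= 0:
        raise QuantificationError("sample mass must be > 0")
    istd_key = parse_fa(pt.istd_label, require_omega=False).label
    scale = pt.istd_mass_mg / (pt.istd_area * pt.sample_mass_g)
    values = {}
    for label, area in pt.areas.items():
        key = parse_fa(label, require_omega=False).label
        if key == istd_key:
            continue
        if area < 0:
            raise QuantificationError(f"negative peak area for {label!r}")
        values[key] = area * scale
    if pt.sample_basis not in (Basis.MG_PER_G_DW, Basis.MG_PER_G_WW):
        raise BasisError("sample_basis must be a mg/g basis")
    return FAProfile(
        sample_id=pt.sample_id,
        basis=pt.sample_basis,
        values=values,
        tissue=pt.tissue,
    )


def to_percent(p: FAProfile) -> FAProfile:
    """Convert a profile to the percent-of-total-FA basis (sums to 100).

    Idempotent up to renormalization; a percent-basis profile whose values
    already sum to 100 is returned value-identical.
    """
    total = p.total()
    if total <= 0:
        raise ProfileError(f"cannot normalize all-zero profile {p.sample_id!r}")
    values = {k: 100.0 * v / total for k, v in p.values.items()}
    return replace(p, basis=Basis.PERCENT, values=values, traces=p.traces)


def class_sums(p: FAProfile, scheme: ClassificationScheme = DEFAULT_SCHEME) -> ClassSummary:
    """Sum a profile's amounts into FA classes on the profile's own basis.

    Trace entries contribute 0.  Under the default scheme SFA + UFA equals
    the total and UFA = MUFA + PUFA; BFA is an overlay (branched or
    odd-chain species, any saturation).
    """
    acc = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0, "UFA": 0.0, "BFA": 0.0, "n3": 0.0, "n6": 0.0}
    for label, amount in p.values.items():
        tags = classify(parse_fa(label, require_omega=False), scheme)
        for t in tags & acc.keys():
            acc[t] += amount
    return ClassSummary(
        sfa=acc["SFA"],
        mufa=acc["MUFA"],
        pufa=acc["PUFA"],
        ufa=acc["UFA"],
        bfa=acc["BFA"],
        n3=acc["n3"],
        n6=acc["n6"],
        total=p.total(),
        basis=p.basis,
    )


_EPA = "20:5n-3"
_DHA = "22:6n-3"


def epa_dha(p: FAProfile) -> float:
    """EPA + DHA content in mg per g wet weight.

    The two physiologically key omega-3 LC-PUFAs, eicosapentaenoic
    (20:5n-3) and docosahexaenoic (22:6n-3) acid; absent species
    contribute 0.  Only meaningful on the wet-weight content basis, on
    which dietary intake recommendations are expressed.
    """
    if p.basis is not Basis.MG_PER_G_WW:
        raise BasisError(
            f"EPA+DHA content requires the mg/g wet-weight basis, got {p.basis.value}"
        )
    return p.values.get(_EPA, 0.0) + p.values.get(_DHA, 0.0)
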