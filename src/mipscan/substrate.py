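"""Substrate-specificity prediction from diagnostic residues.

Three complementary, independently reported lines of evidence:

* NPA motif typing — canonical Asn-Pro-Ala vs variant half-helix motifs.
* Froger-position classification — discriminates glycerol-transporting
  aquaglyceroporins (GlpF-like) from water-selective channels (AqpZ-like):
  aromatic P1, acidic P2, basic P3, proline at P4 followed by a
  non-aromatic P5 mark the glycerol type.
* SDP rule matching — the observed residues at the nine
  specificity-determining positions are compared against per-substrate
  allowed sets; a single deviating position flags a candidate novel
  transporter type, two or more reject the match.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import (
    FROGER_POSITIONS,
    MISSING,
    SDP_POSITIONS,
    AqpProfile,
    SubstrateRule,
)

AROMATIC = frozenset("FWY")
ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")


class MatchCategory(enum.IntEnum):
    """Ordered so that better matches sort first."""

    TYPICAL = 0
    NOVEL_CANDIDATE = 1
    NO_MATCH = 2
    INCOMPLETE = 3


class FrogerCallType(enum.Enum):
    WATER_TYPE = "WATER_TYPE"
    GLYCEROL_TYPE = "GLYCEROL_TYPE"
    MIXED = "MIXED"
    INCOMPLETE = "INCOMPLETE"


class PositionClass(enum.Enum):
    GLP_LIKE = "GLP_LIKE"
    AQP_LIKE = "AQP_LIKE"
    OTHER = "OTHER"


@dataclass
class MatchResult:
    """Outcome of matching observed SDP residues against one substrate rule."""

    substrate: str
    category: MatchCategory
    deviations: list = field(default_factory=list)  # (position, observed, allowed)
    n_missing: int = 0


@dataclass
class FrogerCall:
    call: FrogerCallType
    per_position: dict = field(default_factory=dict)


def npa_type(profile: AqpProfile) -> tuple:
    """Label each half-helix motif CANONICAL, VARIANT:<motif> or MISSING."""

    def label(motif):
        if motif is MISSING:
            return "MISSING"
        if len(motif) != 3:
            raise ValueError(
                f"{profile.protein_id}: NPA motif must have 3 residues"
            )
        return "CANONICAL" if motif == "NPA" else f"VARIANT:{motif}"

    return label(profile.npa_lb), label(profile.npa_le)


def _glp_like(pos: str, residue: str) -> bool:
    if pos == "P1":
        return residue in AROMATIC
    if pos == "P2":
        return residue in ACIDIC
    if pos == "P3":
        return residue in BASIC
    if pos == "P4":
        return residue == "P"
    if pos == "P5":
        return residue not in AROMATIC
    raise ValueError(pos)


def froger_class(profile: AqpProfile) -> FrogerCall:
    """Classify the five Froger positions; GLYCEROL_TYPE needs all five
    GLP-like, WATER_TYPE none, anything in between is MIXED."""
    residues = {p: profile.froger.get(p, MISSING) for p in FROGER_POSITIONS}
    if any(r is MISSING for r in residues.values()):
        per = {p: PositionClass.OTHER if r is MISSING
               else (PositionClass.GLP_LIKE if _glp_like(p, r)
                     else PositionClass.AQP_LIKE)
               for p, r in residues.items()}
        return FrogerCall(call=FrogerCallType.INCOMPLETE, per_position=per)
    per = {p: PositionClass.GLP_LIKE if _glp_like(p, r)
           else PositionClass.AQP_LIKE for p, r in residues.items()}
    n_glp = sum(1 for v in per.values() if v is PositionClass.GLP_LIKE)
    if n_glp == 0:
        call = FrogerCallType.WATER_TYPE
    elif n_glp == 5:
        call = FrogerCallType.GLYCEROL_TYPE
    else:
        call = FrogerCallType.MIXED
    return FrogerCall(call=call, per_position=per)


def match_sdp(profile_sdp: Mapping[str, Optional[str]], rule: SubstrateRule,
              max_novel_deviations: int = 1) -> MatchResult:
    """Match observed SDP residues against one substrate's allowed sets.

    MISSING positions are counted in ``n_missing`` and never create a
    deviation; a profile with deviations is NOVEL_CANDIDATE up to
    ``max_novel_deviations`` deviating positions and NO_MATCH beyond.
    """
    deviations = []
    n_missing = 0
    for pos in SDP_POSITIONS:
        observed = profile_sdp.get(pos, MISSING)
        if observed is MISSING:
            n_missing += 1
            continue
        allowed = rule.allowed[pos]
        if observed not in allowed:
            deviations.append((pos, observed, allowed))
    if not deviations:
        category = (MatchCategory.INCOMPLETE if n_missing > 0
                    else MatchCategory.TYPICAL)
    elif len(deviations) <= max_novel_deviations:
        category = MatchCategory.NOVEL_CANDIDATE
    else:
        category = MatchCategory.NO_MATCH
    return MatchResult(substrate=rule.substrate, category=category,
                       deviations=deviations, n_missing=n_missing)


def predict_substrates(profile: AqpProfile, rules: Sequence[SubstrateRule],
                       max_novel_deviations: int = 1) -> list:
    """One MatchResult per rule, best categories first, ties by substrate."""
    sdp = profile.sdp if profile.sdp is not None else {}
    results = [match_sdp(sdp, rule, max_novel_deviations) for rule in rules]
    results.sort(key=lambda m: (int(m.category), m.substrate))
    return results


def arr_report(profile: AqpProfile, typical_filters: Optional[dict] = None
               ) -> dict:
    """Dash-joined ar/R filter string plus a subfamily-typical flag.

    ``typical_filters`` maps subfamily label -> set of ar/R strings regarded
    as typical (defaults to the filters observed in the packaged reference
    family). The flag is None when the profile has no subfamily label.
    """
    residues = [profile.arr.get(p, MISSING) for p in
                ("H2", "H5", "LE1", "LE2")]
    text = "-".join("-" if r is MISSING else r for r in residues)
    typical = None
    if profile.subfamily:
        if typical_filters is None:
            typical_filters = _reference_filters()
        typical = text in typical_filters.get(profile.subfamily, set())
    return {"arr": text, "subfamily": profile.subfamily,
            "typical_for_subfamily": typical}


_REF_FILTERS = None


def _reference_filters() -> dict:
    """ar/R strings per subfamily observed in the packaged reference family."""
    global _REF_FILTERS
    if _REF_FILTERS is None:
        from .classify import assign_subfamily
        from .io import load_table2

        filters: dict = {}
        for prof in load_table2():
            label = assign_subfamily(prof).label
            text = "-".join(
                "-" if prof.arr.get(p) is MISSING else prof.arr[p]
                for p in ("H2", "H5", "LE1", "LE2")
            )
            filters.setdefault(label, set()).add(text)
        _REF_FILTERS = filters
    return _REF_FILTERS
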