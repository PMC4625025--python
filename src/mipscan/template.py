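"""Anchor query sequences to a reference template by global alignment.

Diagnostic residues (NPA half-helix motifs, ar/R filter, Froger positions,
SDPs, phosphosites) are defined as named 1-based coordinates on a template
sequence. Each query is aligned to the template with a Needleman–Wunsch
global alignment (BLOSUM62, affine gaps) and the residues at the mapped
coordinates are read off. Template columns that align to a gap in the query
yield :data:`ABSENT` / missing profile fields, which is how N- or
C-terminally truncated proteins (e.g. a protein retaining only the first
NPA motif) are handled.

The shipped template is a synthetic PIP-like backbone
(``data/template_synthetic.fasta``) with curated coordinates
(``data/positions.yaml``); both can be overridden together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .core import MISSING, ARR_POSITIONS, FROGER_POSITIONS, SDP_POSITIONS, \
    AqpProfile, ProteinRecord
from .io import data_path, read_fasta

#: Sentinel for a template position with no aligned query residue.
ABSENT = None

NPA_LB_POSITIONS = ("NPA_LB1", "NPA_LB2", "NPA_LB3")
NPA_LE_POSITIONS = ("NPA_LE1", "NPA_LE2", "NPA_LE3")
PHOS_POSITIONS = ("PHOS1", "PHOS2")

KNOWN_POSITION_NAMES = frozenset(
    NPA_LB_POSITIONS + NPA_LE_POSITIONS + ARR_POSITIONS + FROGER_POSITIONS
    + SDP_POSITIONS + PHOS_POSITIONS
)


@dataclass(frozen=True)
class PositionTable:
    """Named 1-based diagnostic residue coordinates on a template."""

    template_id: str
    named_positions: dict

    def __post_init__(self):
        seen = {}
        for name, idx in self.named_positions.items():
            if name not in KNOWN_POSITION_NAMES:
                raise ValueError(f"unknown position name: {name}")
            if not isinstance(idx, int) or idx < 1:
                raise ValueError(f"{name}: index must be a positive integer")
            if idx in seen:
                raise ValueError(
                    f"{name} and {seen[idx]} share template index {idx}"
                )
            seen[idx] = name

    def validate_against(self, template: ProteinRecord) -> None:
        too_far = {n: i for n, i in self.named_positions.items()
                   if i > len(template.residues)}
        if too_far:
            raise ValueError(
                f"positions beyond template length {len(template.residues)}: "
                f"{too_far}"
            )


@dataclass(frozen=True)
class AlignmentMap:
    """A global query/template alignment and its template→query index map."""

    query_id: str
    template_id: str
    aligned_template: str
    aligned_query: str
    score: float
    index_map: dict  # 1-based template index -> 1-based query index or ABSENT
    query_residues: str

    def residue_at(self, template_index: int):
        """Query residue aligned to a template position, or MISSING."""
        qi = self.index_map.get(template_index, ABSENT)
        if qi is ABSENT:
            return MISSING
        return self.query_residues[qi - 1]


def load_template(path=None) -> ProteinRecord:
    """Load the reference template (packaged synthetic backbone by default)."""
    return read_fasta(path or data_path("template_synthetic.fasta"))[0]


def load_positions(path=None) -> PositionTable:
    """Load a position table from YAML."""
    with open(path or data_path("positions.yaml")) as fh:
        raw = yaml.safe_load(fh)
    return PositionTable(template_id=raw["template_id"],
                         named_positions=dict(raw["named_positions"]))


def make_aligner(gap_open: float = 10.0, gap_extend: float = 0.5,
                 matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    """Global affine-gap aligner; a gap of length L costs open + extend*(L-1)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_to_template(query: ProteinRecord, template: ProteinRecord,
                      aligner: Optional[Align.PairwiseAligner] = None
                      ) -> AlignmentMap:
    """Optimal global alignment of a query against the template.

    Deterministic: the aligner's first-reported optimal alignment is used.
    """
    for rec in (query, template):
        if "-" in rec.residues:
            raise ValueError(f"{rec.id}: sequence contains gap characters")
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(template.residues, query.residues)
    best = alignments[0]
    gapped_t, gapped_q = str(best[0]), str(best[1])
    index_map = {}
    ti = qi = 0
    for ct, cq in zip(gapped_t, gapped_q):
        if ct != "-":
            ti += 1
        if cq != "-":
            qi += 1
        if ct != "-":
            index_map[ti] = qi if cq != "-" else ABSENT
    return AlignmentMap(
        query_id=query.id,
        template_id=template.id,
        aligned_template=gapped_t,
        aligned_query=gapped_q,
        score=float(best.score),
        index_map=index_map,
        query_residues=query.residues,
    )


def _motif(amap: AlignmentMap, positions: PositionTable, names) -> object:
    """3-letter motif at consecutive named positions, MISSING if any absent."""
    residues = []
    for name in names:
        idx = positions.named_positions.get(name)
        if idx is None:
            return MISSING
        r = amap.residue_at(idx)
        if r is MISSING:
            return MISSING
        residues.append(r)
    return "".join(residues)


def extract_profile(amap: AlignmentMap, positions: PositionTable) -> AqpProfile:
    """Read the query residues at every named template position.

    Returns a profile with residue fields only; positions absent from the
    alignment (or from the position table) come back as MISSING.
    """

    def res(name):
        idx = positions.named_positions.get(name)
        return MISSING if idx is None else amap.residue_at(idx)

    return AqpProfile(
        protein_id=amap.query_id,
        npa_lb=_motif(amap, positions, NPA_LB_POSITIONS),
        npa_le=_motif(amap, positions, NPA_LE_POSITIONS),
        arr={p: res(p) for p in ARR_POSITIONS},
        froger={p: res(p) for p in FROGER_POSITIONS},
        sdp={p: res(p) for p in SDP_POSITIONS},
    )


def flag_phosphosites(amap: AlignmentMap, positions: PositionTable) -> dict:
    """Conserved-phosphosite flags: True iff the mapped residue is S or T.

    A serine→threonine substitution at a phosphosite counts as conserved.
    """
    flags = {}
    for name in PHOS_POSITIONS:
        idx = positions.named_positions.get(name)
        residue = MISSING if idx is None else amap.residue_at(idx)
        flags[name] = residue in {"S", "T"}
    return flags
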