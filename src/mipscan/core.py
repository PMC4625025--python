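"""Core domain types shared across the pipeline.

Missing diagnostic residues are represented by :data:`MISSING` (``None``),
never by an empty string; fixture files encode them as ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Sentinel for an absent residue/motif. Fixtures encode it as "-".
MISSING = None

#: The 20 standard amino-acid one-letter codes.
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Letters accepted in protein sequences (X = unknown residue).
SEQ_LETTERS = AA_LETTERS | {"X"}

ARR_POSITIONS = ("H2", "H5", "LE1", "LE2")
FROGER_POSITIONS = ("P1", "P2", "P3", "P4", "P5")
SDP_POSITIONS = tuple(f"SDP{i}" for i in range(1, 10))

SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")
UNCLASSIFIED = "UNCLASSIFIED"
UNASSIGNED = "UNASSIGNED"


def is_missing(value) -> bool:
    return value is MISSING


def _check_residue(value, what: str) -> None:
    if value is MISSING:
        return
    if not (isinstance(value, str) and len(value) == 1 and value in AA_LETTERS):
        raise ValueError(f"{what}: invalid amino-acid residue {value!r}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: upper-case standard residues (plus X), no gaps."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - SEQ_LETTERS
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters in sequence: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """One locus: start-to-stop span, CDS length and intron bookkeeping.

    ``gene_len`` is the nucleotide distance from start to stop codon
    (introns included, UTRs excluded), so the total intron length is
    ``gene_len - cds_len``.
    """

    gene_id: str
    scaffold: str
    strand: str
    gene_len: int
    cds_len: int
    intron_count: int
    exon_coords: Optional[tuple] = None

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_len <= 0 or self.cds_len <= 0:
            raise ValueError(f"{self.gene_id}: lengths must be positive")
        if self.cds_len < 3:
            raise ValueError(f"{self.gene_id}: cds_len < 3")
        if self.cds_len > self.gene_len:
            raise ValueError(
                f"{self.gene_id}: cds_len {self.cds_len} exceeds "
                f"gene_len {self.gene_len}"
            )
        if self.intron_count < 0:
            raise ValueError(f"{self.gene_id}: negative intron count")
        if self.exon_coords is not None:
            if self.intron_count != len(self.exon_coords) - 1:
                raise ValueError(
                    f"{self.gene_id}: intron_count inconsistent with exons"
                )


@dataclass
class AqpProfile:
    """Diagnostic residues and physicochemical annotations of one protein.

    Residue-valued fields hold a single amino-acid letter or :data:`MISSING`.
    ``arr`` maps the ar/R constriction positions H2/H5/LE1/LE2; ``froger``
    maps the five Froger discriminant positions P1–P5; ``sdp`` (optional)
    maps the nine specificity-determining positions SDP1–SDP9.
    """

    protein_id: str
    subfamily: Optional[str] = None
    subgroup: Optional[str] = None
    length_aa: Optional[int] = None
    mw_kda: Optional[float] = None
    pi: Optional[float] = None
    tm_count: Optional[int] = None
    loc_annotations: list = field(default_factory=list)
    npa_lb: Optional[str] = MISSING
    npa_le: Optional[str] = MISSING
    arr: dict = field(default_factory=dict)
    froger: dict = field(default_factory=dict)
    sdp: Optional[dict] = None

    def __post_init__(self):
        for motif in (self.npa_lb, self.npa_le):
            if motif is not MISSING and len(motif) != 3:
                raise ValueError(
                    f"{self.protein_id}: NPA motif must be 3 letters, got {motif!r}"
                )
        for pos in ARR_POSITIONS:
            _check_residue(self.arr.get(pos, MISSING), f"{self.protein_id}.{pos}")
        for pos in FROGER_POSITIONS:
            _check_residue(self.froger.get(pos, MISSING), f"{self.protein_id}.{pos}")
        if self.sdp is not None:
            for pos in SDP_POSITIONS:
                _check_residue(self.sdp.get(pos, MISSING), f"{self.protein_id}.{pos}")
        if self.mw_kda is not None and self.mw_kda <= 0:
            raise ValueError(f"{self.protein_id}: mw_kda must be positive")
        if self.pi is not None and not (0 < self.pi < 14):
            raise ValueError(f"{self.protein_id}: pI out of (0, 14)")

    def has_diagnostic(self) -> bool:
        """True if at least one diagnostic residue field is present."""
        if self.npa_lb is not MISSING or self.npa_le is not MISSING:
            return True
        for mapping in (self.arr, self.froger, self.sdp or {}):
            if any(v is not MISSING for v in mapping.values()):
                return True
        return False


@dataclass(frozen=True)
class SubstrateRule:
    """Allowed residues at SDP1–SDP9 for a typical transporter of one substrate."""

    substrate: str
    allowed: dict

    def __post_init__(self):
        for pos in SDP_POSITIONS:
            residues = self.allowed.get(pos)
            if not residues:
                raise ValueError(
                    f"{self.substrate}: empty allowed set at {pos}"
                )
            for r in residues:
                _check_residue(r, f"{self.substrate}.{pos}")
        object.__setattr__(
            self,
            "allowed",
            {pos: frozenset(self.allowed[pos]) for pos in SDP_POSITIONS},
        )


def slugify(name: str) -> str:
    """File-name-safe form of a gene name (``RcXIP2;1`` -> ``RcXIP2-1``)."""
    return name.replace(";", "-").replace("/", "_").replace(" ", "_")
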