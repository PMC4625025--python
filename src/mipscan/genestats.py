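"""Gene-structure and protein-property statistics.

Per-gene metrics derive entirely from the start-to-stop span bookkeeping
(total intron length = span - CDS). Family summaries aggregate per
subfamily with presentation rounding done half-up at two decimals and full
precision kept internally. Molecular weight and isoelectric point are
computed from raw sequences: average residue masses plus one water, and
bisection on the Henderson–Hasselbalch net-charge equation with the
EMBOSS pKa set.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .core import AA_LETTERS, AqpProfile, GeneModel, ProteinRecord

# Average (isotope-abundance-weighted) residue masses, Da.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# EMBOSS pKa values (iep defaults).
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def gene_metrics(g: GeneModel) -> dict:
    """Span/CDS/intron metrics for one gene model.

    ``mean_intron_len`` is absent (None) for intronless genes.
    """
    total_intron = g.gene_len - g.cds_len
    return {
        "gene_id": g.gene_id,
        "gene_len": g.gene_len,
        "cds_len": g.cds_len,
        "intron_count": g.intron_count,
        "total_intron_len": total_intron,
        "mean_intron_len": (total_intron / g.intron_count
                            if g.intron_count > 0 else None),
    }


def _round2(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SubfamilyStats:
    label: str
    count: int
    length_aa_range: tuple
    mw_range: tuple
    pi_mean: float
    gene_len_range: tuple
    intron_histogram: dict


@dataclass
class FamilySummary:
    per_subfamily: dict
    total_genes: int
    gene_len_range: tuple
    length_aa_range: tuple
    mean_intron_len: Optional[float]  # total intron bp / total intron count


def family_summary(profiles: Sequence[AqpProfile],
                   gene_models: Sequence[GeneModel],
                   labels: Mapping[str, str]) -> FamilySummary:
    """Aggregate protein and gene-structure statistics per subfamily.

    ``labels`` maps every gene/protein id to its subfamily. Profile and
    gene id sets must coincide; pI means are reported half-up at two
    decimals.
    """
    prof_ids = {p.protein_id for p in profiles}
    gene_ids = {g.gene_id for g in gene_models}
    orphans = sorted(prof_ids ^ gene_ids)
    if orphans:
        raise ValueError(f"profile/gene id mismatch, orphans: {orphans}")
    unlabelled = sorted(prof_ids - set(labels))
    if unlabelled:
        raise ValueError(f"genes without a subfamily label: {unlabelled}")

    by_label: dict = {}
    genes_by_id = {g.gene_id: g for g in gene_models}
    for prof in profiles:
        by_label.setdefault(labels[prof.protein_id], []).append(prof)

    per_subfamily = {}
    for label in sorted(by_label):
        members = by_label[label]
        genes = [genes_by_id[p.protein_id] for p in members]
        pis = [Decimal(str(p.pi)) for p in members]
        hist: dict = {}
        for g in genes:
            hist[g.intron_count] = hist.get(g.intron_count, 0) + 1
        per_subfamily[label] = SubfamilyStats(
            label=label,
            count=len(members),
            length_aa_range=(min(p.length_aa for p in members),
                             max(p.length_aa for p in members)),
            mw_range=(min(p.mw_kda for p in members),
                      max(p.mw_kda for p in members)),
            pi_mean=_round2(sum(pis) / len(pis)),
            gene_len_range=(min(g.gene_len for g in genes),
                            max(g.gene_len for g in genes)),
            intron_histogram=dict(sorted(hist.items())),
        )

    total_introns = sum(g.intron_count for g in gene_models)
    total_intron_bp = sum(g.gene_len - g.cds_len for g in gene_models)
    return FamilySummary(
        per_subfamily=per_subfamily,
        total_genes=len(gene_models),
        gene_len_range=(min(g.gene_len for g in gene_models),
                        max(g.gene_len for g in gene_models)),
        length_aa_range=(min(p.length_aa for p in profiles),
                         max(p.length_aa for p in profiles)),
        mean_intron_len=(total_intron_bp / total_introns
                         if total_introns else None),
    )


def _net_charge(counts: dict, n: int, ph: float) -> float:
    """Net charge of a peptide at a given pH (Henderson–Hasselbalch)."""
    pos = 1.0 / (1.0 + 10 ** (ph - PKA_NTERM))
    for aa, pka in PKA_POSITIVE.items():
        pos += counts.get(aa, 0) / (1.0 + 10 ** (ph - pka))
    neg = 1.0 / (1.0 + 10 ** (PKA_CTERM - ph))
    for aa, pka in PKA_NEGATIVE.items():
        neg += counts.get(aa, 0) / (1.0 + 10 ** (pka - ph))
    return pos - neg


def protein_properties(seq: ProteinRecord, tol: float = 1e-4) -> tuple:
    """(molecular weight in kDa, isoelectric point) from the raw sequence.

    Mw is the sum of average residue masses plus one water. pI is the root
    of the net-charge equation on [0, 14], found by bisection to ``tol``.
    Unknown residues (X) are rejected.
    """
    bad = set(seq.residues) - AA_LETTERS
    if bad:
        raise ValueError(
            f"{seq.id}: cannot compute properties with residues {sorted(bad)}"
        )
    counts: dict = {}
    for aa in seq.residues:
        counts[aa] = counts.get(aa, 0) + 1
    mw = sum(RESIDUE_MASS[aa] * n for aa, n in counts.items()) + WATER_MASS

    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(counts, len(seq.residues), mid) > 0:
            lo = mid
        else:
            hi = mid
    return mw / 1000.0, 0.5 * (lo + hi)
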