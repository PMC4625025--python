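"""Synthetic MIP families, gene models and count matrices with known truth.

Every generator takes one integer seed and derives an independent,
documented random stream per artifact type (via ``numpy`` SeedSequence
spawn keys), so regeneration is byte-identical and adding a generator
never perturbs the others.

What the generators emulate (and what they do not): protein sequences are
the reference template backbone with subfamily diagnostic signatures
planted at the template coordinates and uniform random substitutions
elsewhere — realistic membrane-protein composition and indels are
deliberately out of scope. Gene models mirror the family's subfamily-
specific intron architectures (PIPs three introns, most TIPs two, most
NIPs four, ...). Count matrices plant dominant isoforms per subfamily and
strictly tissue-specific genes on a negative-binomial noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, ProteinRecord
from .expression import ExpressionSet
from .template import load_positions, load_template

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Planted diagnostic signatures per subfamily (drawn from the canonical
#: filters of the reference family: PIP F-H-T-R + NPA/NPA etc.).
SUBFAMILY_SIGNATURES = {
    "PIP": {"H2": "F", "H5": "H", "LE1": "T", "LE2": "R",
            "NPA_LB": "NPA", "NPA_LE": "NPA",
            "P1": "E", "P2": "S", "P3": "A", "P4": "F", "P5": "W",
            "SDP": "HPFFLPGGN", "subgroup": "UNASSIGNED"},
    "TIP": {"H2": "H", "H5": "I", "LE1": "A", "LE2": "V",
            "NPA_LB": "NPA", "NPA_LE": "NPA",
            "P1": "T", "P2": "S", "P3": "A", "P4": "Y", "P5": "W",
            "SDP": "HPFFLAGSN", "subgroup": "UNASSIGNED"},
    "NIP": {"H2": "W", "H5": "V", "LE1": "A", "LE2": "R",
            "NPA_LB": "NPA", "NPA_LE": "NPA",
            "P1": "F", "P2": "S", "P3": "A", "P4": "Y", "P5": "I",
            "SDP": "FKFTADLET", "subgroup": "NIP I"},
    "SIP": {"H2": "V", "H5": "V", "LE1": "P", "LE2": "N",
            "NPA_LB": "NPT", "NPA_LE": "NPA",
            "P1": "E", "P2": "A", "P3": "A", "P4": "Y", "P5": "W",
            "SDP": "HPFALPGSN", "subgroup": "UNASSIGNED"},
    "XIP": {"H2": "V", "H5": "F", "LE1": "V", "LE2": "R",
            "NPA_LB": "SPT", "NPA_LE": "NPA",
            "P1": "M", "P2": "C", "P3": "A", "P4": "F", "P5": "W",
            "SDP": "AGLVIHFVP", "subgroup": "XIP1"},
}

#: Subfamily-specific intron-count mixtures of the reference family.
DEFAULT_ARCHITECTURE_MIX = {0: 0.10, 1: 0.17, 2: 0.30, 3: 0.22, 4: 0.21}

_STREAMS = {"family": 1, "genes": 2, "counts": 3}


@dataclass
class TruthTable:
    """Planted ground truth for one synthetic artifact."""

    seed: int
    proteins: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


def _signature_residues(signature: dict, positions) -> dict:
    """Expand a signature to {position name: residue}."""
    out = {}
    for i, ch in enumerate(signature["NPA_LB"], start=1):
        out[f"NPA_LB{i}"] = ch
    for i, ch in enumerate(signature["NPA_LE"], start=1):
        out[f"NPA_LE{i}"] = ch
    for name in ("H2", "H5", "LE1", "LE2", "P1", "P2", "P3", "P4", "P5"):
        out[name] = signature[name]
    for i, ch in enumerate(signature["SDP"], start=1):
        out[f"SDP{i}"] = ch
    out["PHOS1"] = "S"
    out["PHOS2"] = "S"
    return {name: res for name, res in out.items()
            if name in positions.named_positions}


def gen_family(n_per_subfamily: int = 2, mutation_rate: float = 0.0,
               seed: int = 0, subfamilies: Optional[Sequence[str]] = None,
               template: Optional[ProteinRecord] = None,
               positions=None) -> tuple:
    """Synthetic protein family with planted subfamily signatures.

    Sequences are the template backbone with the subfamily's diagnostic
    residues planted at the named coordinates; every non-diagnostic column
    is substituted with probability ``mutation_rate`` (uniform over the
    other 19 residues). Diagnostic columns are never mutated, and neither
    is a two-residue flank around each of them: in real aquaporins the
    diagnostic positions sit inside structurally conserved motifs (the NPA
    half-helices, the pore constriction), and the conserved context is what
    anchors them in an alignment.
    """
    if not (0 <= mutation_rate < 0.5):
        raise ValueError("mutation_rate must be in [0, 0.5)")
    template = template or load_template()
    positions = positions or load_positions()
    subfamilies = list(subfamilies or SUBFAMILY_SIGNATURES)
    rng = _rng(seed, "family")
    diagnostic_cols = set()
    for idx in positions.named_positions.values():
        diagnostic_cols.update(range(idx - 2, idx + 3))

    records = []
    truth = TruthTable(seed=seed)
    for subfamily in subfamilies:
        signature = SUBFAMILY_SIGNATURES[subfamily]
        planted = _signature_residues(signature, positions)
        for k in range(1, n_per_subfamily + 1):
            seq = list(template.residues)
            for name, residue in planted.items():
                seq[positions.named_positions[name] - 1] = residue
            for col in range(len(seq)):
                if (col + 1) in diagnostic_cols:
                    continue
                if rng.random() < mutation_rate:
                    current = seq[col]
                    choices = [a for a in AA if a != current]
                    seq[col] = choices[rng.integers(len(choices))]
            pid = f"SYN_{subfamily}_{k:03d}"
            records.append(ProteinRecord(
                id=pid, residues="".join(seq),
                description=f"synthetic {subfamily} family member",
            ))
            truth.proteins[pid] = {
                "subfamily": subfamily,
                "subgroup": signature["subgroup"],
                "residues": dict(planted),
            }
    return records, truth


def gen_gene_models(n: int, architecture_mix: Optional[Mapping[int, float]] = None,
                    seed: int = 0) -> tuple:
    """Synthetic gene models; intron counts drawn from ``architecture_mix``.

    Intron lengths are log-normal (median ~250 bp) clipped to the 46–3360 bp
    range observed in real family introns, so gene_len = cds_len + sum of
    sampled intron lengths by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(architecture_mix or DEFAULT_ARCHITECTURE_MIX)
    counts = sorted(mix)
    probs = np.array([mix[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    rng = _rng(seed, "genes")

    models = []
    truth = TruthTable(seed=seed)
    for k in range(1, n + 1):
        intron_count = int(rng.choice(counts, p=probs))
        cds_len = 3 * int(rng.integers(209, 311))
        intron_lens = [int(np.clip(rng.lognormal(5.5, 0.9), 46, 3360))
                       for _ in range(intron_count)]
        gene_id = f"SYNG_{k:04d}"
        models.append(GeneModel(
            gene_id=gene_id, scaffold=f"scaf{k:04d}",
            strand="+" if rng.random() < 0.5 else "-",
            gene_len=cds_len + sum(intron_lens),
            cds_len=cds_len,
            intron_count=intron_count,
        ))
        truth.genes[gene_id] = {"intron_count": intron_count,
                                "intron_lens": intron_lens,
                                "cds_len": cds_len}
    return models, truth


def gen_counts(gene_labels: Mapping[str, str],
               tissues: Sequence[str],
               transcript_len: Optional[Mapping[str, int]] = None,
               lib_size: int = 1_000_000,
               dominance: Optional[Mapping[str, Mapping[str, float]]] = None,
               specificity: Optional[Mapping[str, str]] = None,
               noise: float = 0.0,
               seed: int = 0,
               subfamily_rpkm_total: float = 1000.0) -> tuple:
    """Synthetic count matrix with planted dominance and tissue specificity.

    ``dominance`` maps subfamily -> {gene: share of the subfamily's RPKM
    total}; remaining members split the leftover equally. ``specificity``
    maps a gene to its sole expressing tissue (zero counts elsewhere).
    ``noise`` is the negative-binomial dispersion alpha (variance
    mu + alpha*mu^2); zero gives deterministic rounded means.
    """
    genes = list(gene_labels)
    tissues = list(tissues)
    dominance = dominance or {}
    specificity = specificity or {}
    if transcript_len is None:
        transcript_len = {g: 900 for g in genes}
    for subfamily, shares in dominance.items():
        if sum(shares.values()) > 1.0 + 1e-9:
            raise ValueError(f"{subfamily}: dominance shares sum above 1")
    rng = _rng(seed, "counts")

    by_label: dict = {}
    for g, lab in gene_labels.items():
        by_label.setdefault(lab, []).append(g)

    # planted per-gene expression level on the RPKM scale
    level = {}
    for lab, members in by_label.items():
        shares = dict(dominance.get(lab, {}))
        rest = [g for g in members if g not in shares]
        leftover = max(0.0, 1.0 - sum(shares.values()))
        for g in rest:
            shares[g] = leftover / len(rest) if rest else 0.0
        for g in members:
            level[g] = shares[g] * subfamily_rpkm_total

    counts = np.zeros((len(genes), len(tissues)))
    for i, g in enumerate(genes):
        for j, t in enumerate(tissues):
            if g in specificity and specificity[g] != t:
                continue
            mu = level[g] * transcript_len[g] * lib_size / 1e9
            if noise <= 0:
                counts[i, j] = round(mu)
            elif mu > 0:
                size = 1.0 / noise
                p = size / (size + mu)
                counts[i, j] = rng.negative_binomial(size, p)
    es = ExpressionSet(
        counts=pd.DataFrame(counts.astype(int), index=genes, columns=tissues),
        transcript_len=pd.Series({g: transcript_len[g] for g in genes}),
        lib_size=pd.Series({t: lib_size for t in tissues}),
    )
    truth = TruthTable(seed=seed)
    truth.expression = {
        "labels": dict(gene_labels),
        "level_rpkm": level,
        "dominance": {k: dict(v) for k, v in dominance.items()},
        "specificity": dict(specificity),
        "noise": noise,
    }
    return es, truth
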