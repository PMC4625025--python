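"""Subfamily/subgroup assignment and distance-based placement support.

Subfamily calls come from a deterministic ordered cascade of residue rules
over the diagnostic profile (configured in ``data/rules.yaml``); subgroup
calls use ar/R-filter nomenclature where the literature defines one (the
NIP I/II/III and XIP1/2/3 schemes). Numbered subgroups inside PIP/TIP
(PIP1 vs PIP2 etc.) are phylogenetic constructs and are only reported via
nearest-reference identity voting when a labelled reference set is given.

Placement support: pairwise-identity distance matrices and a canonical
neighbor-joining tree builder with deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from skbio import DistanceMatrix, TreeNode

from .core import (
    ARR_POSITIONS,
    MISSING,
    UNASSIGNED,
    UNCLASSIFIED,
    AqpProfile,
    ProteinRecord,
)
from .io import data_path
from .template import align_to_template, make_aligner


# ---------------------------------------------------------------------------
# Rule cascade

@dataclass
class RuleTrace:
    """Outcome of the subfamily cascade: label, fired rule and evidence."""

    label: str
    fired_rule: Optional[str] = None
    evidence: list = field(default_factory=list)


def load_rules(path=None) -> dict:
    """Load the cascade + subgroup rule configuration."""
    with open(path or data_path("rules.yaml")) as fh:
        return yaml.safe_load(fh)


def _eval_predicate(pred: dict, profile: AqpProfile):
    """Evaluate one predicate; returns evidence list or None if it fails.

    MISSING residues never satisfy a predicate.
    """
    kind = pred["type"]
    if kind == "any":
        for clause in pred["clauses"]:
            ev = _eval_predicate(clause, profile)
            if ev is not None:
                return ev
        return None
    if kind == "all":
        evidence = []
        for clause in pred["clauses"]:
            ev = _eval_predicate(clause, profile)
            if ev is None:
                return None
            evidence.extend(ev)
        return evidence
    if kind == "arr_equals":
        expected = list(pred["value"])
        observed = [profile.arr.get(p, MISSING) for p in ARR_POSITIONS]
        if observed == expected:
            return list(zip(ARR_POSITIONS, observed))
        return None
    if kind == "arr_in":
        pos = pred["position"]
        residue = profile.arr.get(pos, MISSING)
        if residue is not MISSING and residue in set(pred["value"]):
            return [(pos, residue)]
        return None
    if kind == "froger_in":
        pos = pred["position"]
        residue = profile.froger.get(pos, MISSING)
        if residue is not MISSING and residue in set(pred["value"]):
            return [(pos, residue)]
        return None
    if kind == "npa_lb_startswith":
        motif = profile.npa_lb
        if motif is not MISSING and motif.startswith(pred["value"]):
            return [("NPA_LB", motif)]
        return None
    if kind == "npa_lb_in":
        motif = profile.npa_lb
        if motif is not MISSING and motif in set(pred["value"]):
            return [("NPA_LB", motif)]
        return None
    raise ValueError(f"unknown predicate type: {kind}")


def assign_subfamily(profile: AqpProfile, rules: Optional[dict] = None
                     ) -> RuleTrace:
    """First matching rule of the ordered cascade assigns the subfamily.

    An all-MISSING profile yields UNCLASSIFIED with an empty trace (not an
    exception).
    """
    if rules is None:
        rules = _default_rules()
    if not profile.has_diagnostic():
        return RuleTrace(label=UNCLASSIFIED)
    for rule in rules["subfamily_cascade"]:
        evidence = _eval_predicate(rule["predicate"], profile)
        if evidence is not None:
            return RuleTrace(label=rule["label"], fired_rule=rule["name"],
                             evidence=evidence)
    return RuleTrace(label=UNCLASSIFIED)


_RULES_CACHE = None


def _default_rules() -> dict:
    global _RULES_CACHE
    if _RULES_CACHE is None:
        _RULES_CACHE = load_rules()
    return _RULES_CACHE


def _arr_tuple(profile: AqpProfile):
    return [profile.arr.get(p, MISSING) for p in ARR_POSITIONS]


def _compatible(observed, pattern) -> bool:
    """MISSING-tolerant match: every observed residue equals the pattern's."""
    return all(o is MISSING or o == p for o, p in zip(observed, pattern))


def assign_subgroup(profile: AqpProfile, subfamily: Optional[str] = None,
                    rules: Optional[dict] = None) -> str:
    """ar/R-based subgroup label within NIP (I/II/III) and XIP (1/2/3).

    Other subfamilies return UNASSIGNED at profile level; their numbered
    subgroups require a reference set (see assign_numbered_subgroup).
    """
    if rules is None:
        rules = _default_rules()
    if subfamily is None:
        subfamily = profile.subfamily
    if subfamily in (None, UNCLASSIFIED):
        raise ValueError(
            f"{profile.protein_id}: cannot assign a subgroup without a "
            "subfamily"
        )
    observed = _arr_tuple(profile)
    if subfamily == "XIP":
        for label, pattern in rules["xip_arr_patterns"].items():
            if _compatible(observed, pattern):
                return label
        return UNASSIGNED
    if subfamily == "NIP":
        for entry in rules["nip_subgroups"]:
            if "arr_any_of" in entry:
                if any(observed == list(p) for p in entry["arr_any_of"]):
                    return entry["label"]
            else:
                motifs = {profile.npa_lb, profile.npa_le} - {MISSING}
                if motifs & set(entry.get("npa_any_of", [])):
                    return entry["label"]
                h2 = profile.arr.get("H2", MISSING)
                if h2 is not MISSING and h2 in set(entry.get("h2_any_of", [])):
                    return entry["label"]
        return UNASSIGNED
    return UNASSIGNED


def assign_numbered_subgroup(query: ProteinRecord,
                             references: Sequence[ProteinRecord],
                             reference_labels: dict,
                             min_identity: float = 0.55) -> str:
    """Nearest-reference vote for phylogenetic subgroups (PIP1, TIP2, ...).

    Returns the label of the most similar reference if its fractional
    identity reaches ``min_identity``, else UNASSIGNED.
    """
    aligner = make_aligner()
    best_label, best_ident = UNASSIGNED, -1.0
    for ref in sorted(references, key=lambda r: r.id):
        ident = _fractional_identity(query, ref, aligner)
        if ident > best_ident:
            best_ident = ident
            best_label = reference_labels[ref.id]
    return best_label if best_ident >= min_identity else UNASSIGNED


# ---------------------------------------------------------------------------
# Identity distance matrix

def _fractional_identity(a: ProteinRecord, b: ProteinRecord, aligner) -> float:
    amap = align_to_template(a, b, aligner)
    matches = columns = 0
    for ca, cb in zip(amap.aligned_query, amap.aligned_template):
        if ca == "-" and cb == "-":
            continue
        columns += 1
        if ca == cb and ca != "-":
            matches += 1
    return matches / columns


def identity_matrix(records: Sequence[ProteinRecord],
                    aligner=None) -> DistanceMatrix:
    """Pairwise global-alignment identity distances (1 - fractional identity).

    Identity is matches over alignment columns (dual-gap columns excluded).
    """
    if len(records) < 2:
        raise ValueError("identity_matrix needs at least 2 sequences")
    if aligner is None:
        aligner = make_aligner()
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = _fractional_identity(records[i], records[j], aligner)
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(d, ids=[r.id for r in records])


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining (Saitou–Nei Q-criterion).

    Deterministic: ties in Q are broken by the lexicographically smallest
    (id, id) pair, where an internal node inherits the smallest leaf id
    beneath it. Negative branch lengths are clamped to zero with the
    deficit moved to the sister branch. Returns an unrooted tree (trifurcate
    root) for >= 4 taxa, a star for 3.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # will raise on asymmetry
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("nj_tree needs at least 3 taxa")

    # working state: node sort-keys, TreeNodes, and a distance dict
    nodes = {key: TreeNode(name=key) for key in ids}
    keys = sorted(ids)
    dist = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            dist[frozenset((a, b))] = dm[a, b]

    def d(a, b):
        return dist[frozenset((a, b))]

    while len(keys) > 3:
        n = len(keys)
        r = {k: sum(d(k, other) for other in keys if other != k) for k in keys}
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                q = (n - 2) * d(a, b) - r[a] - r[b]
                cand = (q, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = d(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode()
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = float(la), float(lb)
        parent.extend([child_a, child_b])
        new_key = min(a, b)
        for k in keys:
            if k in (a, b):
                continue
            dist[frozenset((new_key, k))] = 0.5 * (d(a, k) + d(b, k) - d(a, b))
        keys = sorted(set(keys) - {a, b} | {new_key})
        nodes[new_key] = parent

    a, b, c = keys
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = TreeNode()
    for key, length in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(key)
        child.length = float(max(length, 0.0))
        root.append(child)
    return root


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
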