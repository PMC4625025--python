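"""Readers and writers for the formats the pipeline touches.

FASTA goes through Bio.SeqIO, GFF3 through gffutils, tabular fixtures
through pandas. Packaged reference tables (the 37-gene castor-bean family
and the substrate SDP rules) are exposed via ``load_table*`` helpers.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO

from .core import (
    AA_LETTERS,
    ARR_POSITIONS,
    FROGER_POSITIONS,
    MISSING,
    SDP_POSITIONS,
    AqpProfile,
    GeneModel,
    ProteinRecord,
    SubstrateRule,
)

PathLike = Union[str, Path]

_TABLE2_RESIDUE_COLS = list(ARR_POSITIONS) + ["NPA_LB", "NPA_LE"] + list(
    FROGER_POSITIONS
)


def data_path(name: str) -> Path:
    """Path to a packaged data file."""
    return Path(resources.files("mipscan.data") / name)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read protein records; residues are upper-cased, '*' stops stripped."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if "*" in residues:
            warnings.warn(
                f"{rec.id}: stripping '*' stop character(s)", stacklevel=2
            )
            residues = residues.replace("*", "")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(id=rec.id, residues=residues,
                          description=rec.description[len(rec.id):].strip())
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike,
                width: int = 60) -> None:
    """Write records with a fixed line width (stable byte-level output)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Diagnostic-feature profiles (table2 dialect)

def _parse_residue(value: str, row: str, col: str):
    if value == "-":
        return MISSING
    if len(value) == 1 and value in AA_LETTERS:
        return value
    raise ValueError(f"row {row!r}, column {col!r}: bad residue {value!r}")


def _parse_motif(value: str, row: str, col: str):
    if value == "-":
        return MISSING
    if len(value) == 3 and set(value) <= AA_LETTERS:
        return value
    raise ValueError(f"row {row!r}, column {col!r}: bad motif {value!r}")


def load_profiles(path: PathLike) -> list[AqpProfile]:
    """Load diagnostic-feature profiles from a table2-dialect TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["name", "length_aa", "mw_kda", "pi"] + _TABLE2_RESIDUE_COLS
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory column(s): {missing_cols}")
    profiles = []
    for _, row in df.iterrows():
        name = row["name"]
        locs = [row[c] for c in ("loc_wolf_psort", "loc_plant_mploc")
                if c in df.columns and pd.notna(row.get(c))]
        profiles.append(AqpProfile(
            protein_id=name,
            length_aa=int(row["length_aa"]),
            mw_kda=float(row["mw_kda"]),
            pi=float(row["pi"]),
            tm_count=int(row["tm"]) if "tm" in df.columns else None,
            loc_annotations=locs,
            npa_lb=_parse_motif(row["NPA_LB"], name, "NPA_LB"),
            npa_le=_parse_motif(row["NPA_LE"], name, "NPA_LE"),
            arr={p: _parse_residue(row[p], name, p) for p in ARR_POSITIONS},
            froger={p: _parse_residue(row[p], name, p)
                    for p in FROGER_POSITIONS},
        ))
    return profiles


# ---------------------------------------------------------------------------
# Gene models (tabular dialect or GFF3)

def _gene_models_from_tsv(path: PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    models = []
    for _, row in df.iterrows():
        models.append(GeneModel(
            gene_id=row["name"],
            scaffold=str(row["scaffold"]),
            strand=row["strand"],
            gene_len=int(row["gene_len"]),
            cds_len=int(row["cds_len"]),
            intron_count=int(row["intron_count"]),
        ))
    return models


def _gene_models_from_gff3(path: PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(db.children(gene, featuretype="exon"),
                       key=lambda f: f.start)
        cds = list(db.children(gene, featuretype="CDS"))
        if exons:
            exon_coords = tuple((f.start, f.end) for f in exons)
            gene_len = exons[-1].end - exons[0].start + 1
        else:
            exon_coords = None
            gene_len = gene.end - gene.start + 1
        cds_len = sum(f.end - f.start + 1 for f in cds)
        intron_count = len(exons) - 1 if exons else 0
        models.append(GeneModel(
            gene_id=gene.id,
            scaffold=gene.seqid,
            strand=gene.strand if gene.strand in "+-" else "+",
            gene_len=gene_len,
            cds_len=cds_len,
            intron_count=intron_count,
            exon_coords=exon_coords,
        ))
    return models


def load_gene_models(path: PathLike) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/exon/CDS features) or the TSV dialect."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _gene_models_from_gff3(path)
    return _gene_models_from_tsv(path)


# ---------------------------------------------------------------------------
# Substrate SDP rules and per-protein SDP observations

def load_substrate_rules(path: PathLike) -> list[SubstrateRule]:
    """Load substrate rules: one row per substrate, slash-separated sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    rules = []
    for _, row in df.iterrows():
        allowed = {}
        for pos in SDP_POSITIONS:
            cell = row[pos]
            if not isinstance(cell, str) or not cell.strip():
                raise ValueError(f"{row['substrate']}: empty set at {pos}")
            residues = [r for r in cell.split("/") if r]
            if not residues:
                raise ValueError(f"{row['substrate']}: empty set at {pos}")
            allowed[pos] = frozenset(
                _parse_residue(r, row["substrate"], pos) for r in residues
            )
        rules.append(SubstrateRule(substrate=row["substrate"], allowed=allowed))
    return rules


def load_sdp_observations(path: PathLike) -> list[tuple]:
    """Load per-(protein, substrate) observed SDP residues.

    Returns a list of ``(protein_id, substrate, {SDP1..SDP9: residue})``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for _, row in df.iterrows():
        sdp = {pos: _parse_residue(row[pos], row["protein"], pos)
               for pos in SDP_POSITIONS}
        rows.append((row["protein"], row["substrate"], sdp))
    return rows


# ---------------------------------------------------------------------------
# Packaged fixture shortcuts

def load_table1() -> list[GeneModel]:
    """The packaged 37-gene castor-bean aquaporin gene-model table."""
    return load_gene_models(data_path("table1.tsv"))


def load_table2() -> list[AqpProfile]:
    """The packaged 37-protein diagnostic-feature table."""
    return load_profiles(data_path("table2.tsv"))


def load_table3_rules() -> list[SubstrateRule]:
    """The packaged six-substrate SDP rule table."""
    return load_substrate_rules(data_path("table3_rules.tsv"))


def load_table3_profiles() -> list[tuple]:
    """The packaged per-(protein, substrate) observed SDP residues."""
    return load_sdp_observations(data_path("table3_profiles.tsv"))
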