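"""Read QC, RPKM normalization and tissue-level expression summaries.

The read filter mirrors common RNA-seq cleaning: adaptor trimming (a read
left empty is dropped), removal of reads whose ambiguous-base fraction
exceeds 10%, and removal of low-quality reads with more than 50% of bases
at Phred quality <= 5 — both thresholds strict inequalities, applied in
that order so each read is counted in exactly one category.

RPKM is reads x 10^9 / (library size x transcript length in bp); detection
defaults to RPKM > 0. Subfamily transcript shares (the dominant-isoform
structure) are computed on RPKM, not raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


@dataclass
class ExpressionSet:
    """Gene x tissue read counts with transcript lengths and library sizes.

    Library sizes are totals per library (they may exceed the column sums,
    since most reads map outside the gene family).
    """

    counts: pd.DataFrame          # genes x tissues, non-negative ints
    transcript_len: pd.Series     # bp per gene
    lib_size: pd.Series           # total reads per tissue

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        if not self.transcript_len.index.equals(self.counts.index):
            self.transcript_len = self.transcript_len.reindex(self.counts.index)
        if self.transcript_len.isna().any():
            raise ValueError("missing transcript length for some genes")
        if (self.transcript_len <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if not self.lib_size.index.equals(self.counts.columns):
            self.lib_size = self.lib_size.reindex(self.counts.columns)
        if self.lib_size.isna().any():
            raise ValueError("missing library size for some tissues")


@dataclass
class ReadFilterReport:
    kept: int = 0
    removed_adaptor: int = 0
    removed_n_rate: int = 0
    removed_low_quality: int = 0

    @property
    def total(self) -> int:
        return (self.kept + self.removed_adaptor + self.removed_n_rate
                + self.removed_low_quality)


def filter_reads(fastq_path, out_path, adaptor: str = "",
                 max_n_rate: float = 0.10, max_low_q_rate: float = 0.50,
                 low_q: int = 5) -> ReadFilterReport:
    """Clean a FASTQ file; order-preserving, each read counted once.

    A read is removed if (a) it is empty after adaptor trimming, then
    (b) its N fraction exceeds ``max_n_rate`` strictly, then (c) its
    fraction of bases with quality <= ``low_q`` exceeds ``max_low_q_rate``
    strictly.
    """
    report = ReadFilterReport()
    kept_records = []
    try:
        records = list(SeqIO.parse(str(fastq_path), "fastq"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record in {fastq_path}: {exc}")
    for rec in records:
        seq = str(rec.seq)
        quals = rec.letter_annotations["phred_quality"]
        if adaptor:
            pos = seq.find(adaptor)
            if pos != -1:
                seq = seq[:pos]
                quals = quals[:pos]
        if len(seq) == 0:
            report.removed_adaptor += 1
            continue
        if seq.upper().count("N") / len(seq) > max_n_rate:
            report.removed_n_rate += 1
            continue
        if sum(1 for q in quals if q <= low_q) / len(seq) > max_low_q_rate:
            report.removed_low_quality += 1
            continue
        trimmed = rec[:len(seq)]
        kept_records.append(trimmed)
        report.kept += 1
    SeqIO.write(kept_records, str(out_path), "fastq")
    return report


def rpkm(es: ExpressionSet) -> pd.DataFrame:
    """Reads per kilobase of transcript per million library reads."""
    if (es.lib_size <= 0).any():
        raise ValueError("library sizes must be positive")
    scale = np.outer(1.0 / es.transcript_len.values,
                     1.0 / es.lib_size.values) * 1e9
    return pd.DataFrame(es.counts.values * scale,
                        index=es.counts.index, columns=es.counts.columns)


@dataclass
class ExpressionSummary:
    detected_per_tissue: pd.Series      # tissue -> number of detected genes
    subfamily_totals: pd.DataFrame      # subfamily x tissue RPKM sums
    shares: pd.DataFrame                # gene x tissue share of its subfamily
    max_tissue: pd.Series               # gene -> tissue of maximal RPKM
    tissue_specific: dict = field(default_factory=dict)  # gene -> sole tissue


def expression_summary(rpkm_matrix: pd.DataFrame,
                       labels: Mapping[str, str],
                       detect_threshold: float = 0.0) -> ExpressionSummary:
    """Detection counts, per-subfamily totals/shares and expression maxima.

    A gene is detected in a tissue when its RPKM exceeds
    ``detect_threshold`` strictly. Shares divide each gene's RPKM by its
    subfamily's total in that tissue (NaN where the total is zero).
    """
    missing = sorted(set(rpkm_matrix.index) - set(labels))
    if missing:
        raise ValueError(f"genes without a subfamily label: {missing}")
    label_series = pd.Series({g: labels[g] for g in rpkm_matrix.index})

    detected = (rpkm_matrix > detect_threshold)
    detected_per_tissue = detected.sum(axis=0)

    subfamily_totals = rpkm_matrix.groupby(label_series).sum()
    denominator = subfamily_totals.reindex(label_series.values)
    denominator.index = rpkm_matrix.index
    shares = rpkm_matrix / denominator.replace(0.0, np.nan)

    max_tissue = rpkm_matrix.idxmax(axis=1)

    tissue_specific = {}
    for gene in rpkm_matrix.index:
        tissues = detected.columns[detected.loc[gene]].tolist()
        if len(tissues) == 1:
            tissue_specific[gene] = tissues[0]

    return ExpressionSummary(
        detected_per_tissue=detected_per_tissue,
        subfamily_totals=subfamily_totals,
        shares=shares,
        max_tissue=max_tissue,
        tissue_specific=tissue_specific,
    )


def top_contributors(summary: ExpressionSummary, tissue: str, subfamily: str,
                     labels: Mapping[str, str], n: Optional[int] = None
                     ) -> list:
    """Genes of one subfamily ranked by share in a tissue (descending)."""
    shares = summary.shares[tissue]
    members = [g for g in shares.index if labels[g] == subfamily]
    ranked = sorted(members, key=lambda g: (-shares.fillna(0.0)[g], g))
    return ranked[:n] if n else ranked


def log_heatmap_matrix(rpkm_matrix: pd.DataFrame, pseudocount: float = 1.0,
                       cluster_rows: bool = False) -> pd.DataFrame:
    """log10(RPKM + pseudocount) matrix for heatmap-style display.

    With ``cluster_rows`` the rows are reordered by average-linkage
    hierarchical clustering on Euclidean distances of the log values.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    mat = np.log10(rpkm_matrix + pseudocount)
    if cluster_rows and len(mat) > 2:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import pdist

        order = leaves_list(average(pdist(mat.values)))
        mat = mat.iloc[order]
    return mat


# ---------------------------------------------------------------------------
# TSV round-trip for count matrices

def write_counts(es: ExpressionSet, path) -> None:
    """Counts TSV: lib-size header row, then genes x tissues with a length column."""
    with open(path, "w") as fh:
        fh.write("#lib_size\t-\t" +
                 "\t".join(str(int(v)) for v in es.lib_size.values) + "\n")
        fh.write("gene\tlength\t" + "\t".join(es.counts.columns) + "\n")
        for gene in es.counts.index:
            row = "\t".join(str(int(v)) for v in es.counts.loc[gene].values)
            fh.write(f"{gene}\t{int(es.transcript_len[gene])}\t{row}\n")


def read_counts(path) -> ExpressionSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#lib_size":
            raise ValueError("counts file must start with a #lib_size row")
        lib_values = [int(v) for v in header[2:]]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    tissues = df.columns[1:]
    return ExpressionSet(
        counts=df[tissues].astype(int),
        transcript_len=df["length"].astype(int),
        lib_size=pd.Series(lib_values, index=tissues),
    )
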