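"""Gene-level read counting, FPKM and translational efficiency (TE).

FPKM = count * 1e9 / (feature_length * total_mapped). Ribosome-footprint
(RIBO) counts are taken over the CDS using the 5'-end rule; RNA-seq counts
use any overlap with the exonic span. TE is the ratio of RIBO FPKM to RNA
FPKM, computed only for genes whose FPKM reaches a floor (default 1) in
both assays, and log2 TE partitions genes into the four conventional
groups G1 (<= -1), G2 (-1, 0], G3 (0, 1], G4 (> 1).

Gene-level quantities use the longest annotated transcript per gene; the
mapped-read total that normalizes FPKM is the number of reads counted to
genes for that assay/sample (self-consistent within the pipeline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignedFootprint, CountTable, TranscriptModel

TE_GROUP_BOUNDS = (-1.0, 0.0, 1.0)


@dataclass
class ExpressionRecord:
    gene_id: str
    assay: str
    condition: str
    replicate: int
    fpkm: float


@dataclass
class TERecord:
    gene_id: str
    condition: str
    te: float
    log2_te: float
    te_group: str


def compute_fpkm(count: int, feature_length: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0:
        raise ValueError(f"feature_length must be positive, got {feature_length}")
    if total_mapped <= 0:
        raise ValueError(f"total_mapped must be positive, got {total_mapped}")
    return count * 1e9 / (feature_length * total_mapped)


def te_group(log2_te: float) -> str:
    """G1..G4 from log2 TE: half-open partition at -1, 0, 1."""
    if log2_te <= TE_GROUP_BOUNDS[0]:
        return "G1"
    if log2_te <= TE_GROUP_BOUNDS[1]:
        return "G2"
    if log2_te <= TE_GROUP_BOUNDS[2]:
        return "G3"
    return "G4"


def compute_te(
    ribo_fpkm: float, rna_fpkm: float, gene_id: str = "", condition: str = "",
    min_fpkm: float = 1.0,
) -> TERecord | None:
    """TE record, or None when either FPKM is below the qualifying floor."""
    if ribo_fpkm < 0 or rna_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    if ribo_fpkm < min_fpkm or rna_fpkm < min_fpkm:
        return None
    te = ribo_fpkm / rna_fpkm
    log2_te = math.log2(te)
    return TERecord(gene_id, condition, te, log2_te, te_group(log2_te))


def longest_transcripts(models: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Representative (longest; ties by transcript id) transcript per gene."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None or (m.length, m.transcript_id) > (cur.length, cur.transcript_id):
            best[m.gene_id] = m
    return best


def count_gene_reads(
    footprints: Sequence[AlignedFootprint],
    models: Iterable[TranscriptModel],
    assay: str,
    condition: str = "",
    replicate: int = 0,
) -> CountTable:
    """Assign reads to genes and count.

    RIBO: a footprint counts for a gene when its 5' end lies inside the
    representative transcript's CDS (strand-matched). RNA: a read counts
    when its aligned span overlaps the exonic span of the representative
    transcript (strand ignored — libraries are treated as unstranded).
    Each read is counted for at most one gene; overlap ties go to the
    lexicographically smallest gene id.
    """
    reps = longest_transcripts(models)
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gid, m in reps.items():
        region = "CDS" if assay == "RIBO" else "exon"
        for s, e in m.genomic_intervals(region):
            trees.setdefault(m.chromosome, IntervalTree()).addi(s, e, (gid, m.strand))
    counts = {gid: 0 for gid in reps}
    for fp in footprints:
        tree = trees.get(fp.chromosome)
        if tree is None:
            continue
        if assay == "RIBO":
            hits = [
                d for _, _, d in tree[fp.five_prime_pos] if d[1] == fp.strand
            ]
        else:
            if fp.strand == "+":
                a, b = fp.five_prime_pos, fp.five_prime_pos + fp.length
            else:
                a, b = fp.five_prime_pos - fp.length + 1, fp.five_prime_pos + 1
            hits = [d for _, _, d in tree[a:b]]
        if hits:
            counts[min(h[0] for h in hits)] += 1
    return CountTable(assay, condition, replicate, counts)


def feature_lengths(models: Iterable[TranscriptModel], assay: str) -> dict[str, int]:
    """FPKM feature length per gene: CDS for RIBO, exonic length for RNA."""
    reps = longest_transcripts(models)
    if assay == "RIBO":
        return {g: m.cds_length for g, m in reps.items()}
    return {g: m.length for g, m in reps.items()}


def fpkm_table(
    tables: Sequence[CountTable], lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Long FPKM DataFrame from count tables.

    ``total_mapped`` per library is the sum of its gene-assigned counts.
    Genes with zero feature length are dropped (no denominator).
    """
    rows = []
    for t in tables:
        total = t.total()
        for gid, c in t.counts.items():
            L = lengths.get(gid, 0)
            if L <= 0:
                continue
            rows.append(
                {
                    "gene_id": gid,
                    "assay": t.assay,
                    "condition": t.condition,
                    "replicate": t.replicate,
                    "count": c,
                    "fpkm": compute_fpkm(c, L, total),
                }
            )
    return pd.DataFrame(rows)


def mean_fpkm(fpkms: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean FPKM over replicates (gene x assay x condition)."""
    return (
        fpkms.groupby(["gene_id", "assay", "condition"])["fpkm"]
        .mean()
        .reset_index()
    )


def te_table(
    fpkms: pd.DataFrame, min_fpkm: float = 1.0
) -> pd.DataFrame:
    """TE per gene per condition from a long FPKM table.

    The qualifying floor is applied to the per-condition mean FPKM over
    replicates. Genes failing the floor in either assay are excluded.
    """
    means = mean_fpkm(fpkms)
    wide = means.pivot_table(
        index=["gene_id", "condition"], columns="assay", values="fpkm"
    ).reset_index()
    if "RIBO" not in wide or "RNA" not in wide:
        raise ValueError("need both RIBO and RNA fpkm records")
    wide = wide.dropna(subset=["RIBO", "RNA"])
    rows = []
    for _, r in wide.iterrows():
        rec = compute_te(
            r["RIBO"], r["RNA"], gene_id=r["gene_id"], condition=r["condition"],
            min_fpkm=min_fpkm,
        )
        if rec is not None:
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "condition": rec.condition,
                    "te": rec.te,
                    "log2_te": rec.log2_te,
                    "te_group": rec.te_group,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "condition", "te", "log2_te", "te_group"])
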