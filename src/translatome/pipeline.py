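"""End-to-end run on synthetic data, scored against the planted truth.

Chains the full analysis — simulated counts -> two-level DE -> quadrant
classification, TE and TE-change calls, footprint QC, and uORF discovery
with translated calls — and reports recovery metrics against the
generator's truth table. This is the package's own acceptance surface:
real libraries enter through the same io_formats interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import differential, quantification, regulation_classes, ribo_qc, uorf_analysis
from .io_formats import AlignedFootprint, CountTable, TranscriptModel
from .synthetic_data import SimConfig, SimTruth, generate_genome, simulate_counts, simulate_footprints


def counts_frame(tables: Sequence[CountTable], assay: str, condition: str) -> pd.DataFrame:
    """Genes x replicates DataFrame for one assay/condition."""
    subs = [t for t in tables if t.assay == assay and t.condition == condition]
    if not subs:
        raise ValueError(f"no count tables for {assay}/{condition}")
    genes = sorted(subs[0].counts)
    return pd.DataFrame(
        {f"rep{t.replicate}": [t.counts[g] for g in genes] for t in sorted(subs, key=lambda t: t.replicate)},
        index=pd.Index(genes, name="gene_id"),
    )


def footprint_transcript_positions(
    footprints: Sequence[AlignedFootprint], models: Sequence[TranscriptModel]
) -> dict[str, list[int]]:
    """Transcript-coordinate 5'-end positions per transcript id."""
    reps = quantification.longest_transcripts(models)
    index = ribo_qc.FeatureIndex(models)
    out: dict[str, list[int]] = {}
    for fp in footprints:
        _, gid = index.lookup(fp)
        if gid is None:
            continue
        m = reps[gid]
        t = m.to_transcript(fp.five_prime_pos)
        if t is not None:
            out.setdefault(m.transcript_id, []).append(t)
    return out


@dataclass
class PipelineResult:
    labels: pd.DataFrame
    summary: dict[str, float]
    de_tx: pd.DataFrame
    de_tl: pd.DataFrame
    te: pd.DataFrame
    te_change: pd.DataFrame
    uorfs: list = field(default_factory=list)
    qc: dict[str, float] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)


def run_pipeline(config: SimConfig | None = None) -> PipelineResult:
    """Generate, analyze, and score one synthetic experiment."""
    cfg = config or SimConfig()
    models, genome, truth = generate_genome(cfg)
    tables = simulate_counts(truth, cfg)
    ctrl, trt = cfg.conditions

    rna_a = counts_frame(tables, "RNA", ctrl)
    rna_b = counts_frame(tables, "RNA", trt)
    ribo_a = counts_frame(tables, "RIBO", ctrl)
    ribo_b = counts_frame(tables, "RIBO", trt)

    de_tx = differential.de_test(rna_a, rna_b)
    de_tl = differential.de_test(ribo_a, ribo_b)
    labels = regulation_classes.classify_table(de_tx, de_tl)
    summary = regulation_classes.quadrant_summary(
        labels, de_tx["log2fc"].to_dict(), de_tl["log2fc"].to_dict()
    )
    te_change = differential.te_change_test(rna_a, rna_b, ribo_a, ribo_b)

    # FPKM / TE from the count tables
    lengths_ribo = quantification.feature_lengths(models, "RIBO")
    lengths_rna = quantification.feature_lengths(models, "RNA")
    fpkms = pd.concat(
        [
            quantification.fpkm_table([t for t in tables if t.assay == "RNA"], lengths_rna),
            quantification.fpkm_table([t for t in tables if t.assay == "RIBO"], lengths_ribo),
        ]
    )
    te = quantification.te_table(fpkms)

    # footprints: QC + uORFs (control condition)
    fps = simulate_footprints(truth, models, cfg)
    kept, _ = ribo_qc.filter_rpf_lengths(fps, *cfg.rpf_length_range)
    qc = {
        "modal_length": max(ribo_qc.length_histogram(kept).items(), key=lambda kv: kv[1])[0],
        "frame0_fraction": ribo_qc.cds_frame_fractions(kept, models)[0],
    }
    qc.update(
        {f"prop_{k}": v for k, v in ribo_qc.feature_proportions(kept, models).items()}
    )

    eligible = uorf_analysis.eligible_5utrs(models, genome)
    uorfs = []
    for m, utr in eligible:
        found, _ = uorf_analysis.scan_uorfs(utr, gene_id=m.gene_id, transcript_id=m.transcript_id)
        uorfs.extend(found)
    tpos = footprint_transcript_positions(kept, models)
    ribo_total = quantification.count_gene_reads(kept, models, "RIBO").total()
    uorfs = uorf_analysis.call_translated(uorfs, tpos, ribo_total)

    metrics = score_against_truth(truth, labels, de_tx, de_tl, te_change, uorfs)
    return PipelineResult(labels, summary, de_tx, de_tl, te, te_change, uorfs, qc, metrics)


def score_against_truth(
    truth: SimTruth,
    labels: pd.DataFrame,
    de_tx: pd.DataFrame,
    de_tl: pd.DataFrame,
    te_change: pd.DataFrame,
    uorfs: Sequence,
) -> dict[str, float]:
    """Recovery metrics: quadrant accuracy, DE/TE-change calibration,
    translated-uORF recall and false positives."""
    true_q = truth.quadrants()
    agree = sum(labels.loc[g, "quadrant"] == true_q[g] for g in labels.index)
    metrics = {"quadrant_recovery": agree / len(labels) if len(labels) else np.nan}

    for name, de, effect in (
        ("tx", de_tx, lambda t: t.tx_log2fc),
        ("tl", de_tl, lambda t: t.tx_log2fc + t.tl_log2fc),
    ):
        called = de.index[de["status"] != "unchanged"]
        null = {g for g, t in truth.genes.items() if effect(t) == 0}
        nonnull = {g for g, t in truth.genes.items() if effect(t) != 0}
        false_calls = sum(g in null for g in called)
        metrics[f"de_{name}_empirical_fdr"] = false_calls / max(len(called), 1)
        correct = sum(
            (de.loc[g, "status"] == "up") == (effect(truth.genes[g]) > 0)
            for g in de.index
            if g in nonnull and de.loc[g, "status"] != "unchanged"
        )
        metrics[f"de_{name}_recall"] = (
            correct / len(nonnull) if nonnull else np.nan
        )

    sig = te_change.index[te_change["significant"]]
    te_null = {g for g, t in truth.genes.items() if t.tl_log2fc == 0}
    te_nonnull = {g for g, t in truth.genes.items() if t.tl_log2fc != 0}
    metrics["te_change_empirical_fdr"] = sum(g in te_null for g in sig) / max(len(sig), 1)
    metrics["te_change_recall"] = (
        sum(g in sig for g in te_nonnull) / len(te_nonnull) if te_nonnull else np.nan
    )

    # translated-uORF calls vs planted flags (scanner output is keyed by
    # transcript + start; every scanned uORF is planted by construction)
    planted: dict[tuple[str, int], bool] = {}
    for g, t in truth.genes.items():
        for u in t.uorfs:
            planted[(f"{g}.1", u.start)] = u.translated
    n_true = sum(planted.values())
    tp = fp_ = 0
    seen_true = 0
    for u in uorfs:
        key = (u.transcript_id, u.start)
        if key not in planted:
            continue
        if planted[key]:
            seen_true += 1
            if u.translated:
                tp += 1
        elif u.translated:
            fp_ += 1
    metrics["uorf_translated_recall"] = tp / seen_true if seen_true else np.nan
    metrics["uorf_translated_false_positives"] = fp_
    metrics["n_uorfs_scanned"] = len(uorfs)
    return metrics
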