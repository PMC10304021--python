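"""Genome-wide uORF discovery in 5'UTRs and translated-uORF analysis.

An upstream ORF (uORF) is an AUG-initiated, stop-terminated reading frame
that starts and ends within a transcript's 5'UTR. uORFs can repress (or
occasionally tune) initiation at the downstream main ORF, so their
presence, ribosome occupancy and start-codon (Kozak) context are the
features of interest here.

Scanning rules: every AUG in the 5'UTR opens at most one uORF, terminated
at the first in-frame stop codon (UAA/UAG/UGA) that still lies entirely
within the UTR. Overlapping and nested uORFs are all reported. AUGs whose
first in-frame stop falls beyond the UTR (reading into the main ORF) are
returned separately as overlapping-ORF candidates and excluded from uORF
statistics. Translation is called from ribosome-footprint FPKM over the
uORF span: FPKM >= 1 (inclusive) marks a uORF as translated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import compute_fpkm
from .sequence_features import FoldingEngine, NussinovEngine

STOPS = {"TAA", "TAG", "TGA"}

UTR5_MIN_LENGTH = 60
UTR5_MAX_LENGTH = 460


@dataclass
class UORFRecord:
    """One AUG-initiated ORF contained in a 5'UTR.

    ``start``/``end`` are transcript coordinates (0-based half-open; the
    5'UTR begins at transcript coordinate 0, so they double as UTR-local
    offsets). ``end`` is exclusive, just past the stop codon; ``length``
    includes the stop and is a multiple of 3. The Kozak context covers
    positions -6..+4 around the AUG, where the A of AUG is +1 (there is no
    position 0).
    """

    gene_id: str
    transcript_id: str
    utr5_length: int
    start: int
    end: int
    length: int = 0
    fpkm: float = float("nan")
    translated: bool | None = None
    kozak_context: str | None = None
    nmfe: float = float("nan")
    norm_dist_to_cds: float = field(init=False, default=float("nan"))
    norm_dist_to_tss: float = field(init=False, default=float("nan"))

    def __post_init__(self) -> None:
        self.length = self.end - self.start
        if self.utr5_length > 0:
            self.norm_dist_to_cds = (self.utr5_length - self.end) / self.utr5_length
            self.norm_dist_to_tss = self.start / self.utr5_length


def eligible_5utrs(
    models: Iterable,
    genome: Mapping[str, str],
    min_length: int = UTR5_MIN_LENGTH,
    max_length: int = UTR5_MAX_LENGTH,
) -> list[tuple[object, str]]:
    """Transcripts whose annotated 5'UTR length is within [min, max]
    (inclusive bounds), paired with the 5'UTR sequence."""
    out = []
    for m in models:
        if min_length <= m.utr5_length <= max_length:
            seq = m.sequence(genome)[m.utr5_span[0] : m.utr5_span[1]]
            out.append((m, seq))
    return out


def scan_uorfs(
    utr_seq: str, gene_id: str = "", transcript_id: str = ""
) -> tuple[list[UORFRecord], list[int]]:
    """Find all uORFs in a 5'UTR sequence.

    Returns ``(uorfs, overlapping_starts)``: one record per AUG whose first
    in-frame stop lies inside the UTR, plus the start offsets of AUGs that
    never hit an in-frame stop before the UTR ends (candidate
    CDS-overlapping ORFs, excluded from uORF statistics).
    """
    s = utr_seq.upper().replace("U", "T")
    n = len(s)
    uorfs: list[UORFRecord] = []
    overlapping: list[int] = []
    i = s.find("ATG")
    while i != -1:
        stop_end = None
        for j in range(i + 3, n - 2, 3):
            if s[j : j + 3] in STOPS:
                stop_end = j + 3
                break
        if stop_end is not None:
            uorfs.append(
                UORFRecord(
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    utr5_length=n,
                    start=i,
                    end=stop_end,
                )
            )
        else:
            overlapping.append(i)
        i = s.find("ATG", i + 1)
    return uorfs, overlapping


def validate_uorf(rec: UORFRecord, utr_seq: str) -> None:
    """Re-check the grammatical invariants of a reported uORF."""
    s = utr_seq.upper().replace("U", "T")
    if s[rec.start : rec.start + 3] != "ATG":
        raise ValueError(f"uORF at {rec.start} does not start with AUG")
    if s[rec.end - 3 : rec.end] not in STOPS:
        raise ValueError(f"uORF at {rec.start} does not end with a stop codon")
    if rec.end > rec.utr5_length:
        raise ValueError("uORF extends past the 5'UTR")
    if rec.length % 3 != 0 or rec.length < 6:
        raise ValueError(f"invalid uORF length {rec.length}")
    for j in range(rec.start + 3, rec.end - 3, 3):
        if s[j : j + 3] in STOPS:
            raise ValueError("internal in-frame stop codon")


def call_translated(
    uorfs: Sequence[UORFRecord],
    transcript_positions: Mapping[str, Sequence[int]],
    total_mapped: int,
    min_fpkm: float = 1.0,
) -> list[UORFRecord]:
    """Attach footprint FPKM and the translated flag to each uORF.

    ``transcript_positions`` maps transcript_id -> transcript coordinates
    of footprint 5' ends on that transcript. A footprint supports a uORF
    when its 5' end lies within [start, end). FPKM uses the uORF length as
    feature length and the same mapped-read total as gene-level RIBO
    quantification; translated iff FPKM >= ``min_fpkm``.
    """
    out = []
    for rec in uorfs:
        pos = transcript_positions.get(rec.transcript_id, ())
        count = sum(1 for p in pos if rec.start <= p < rec.end)
        fpkm = compute_fpkm(count, rec.length, total_mapped)
        rec.fpkm = fpkm
        rec.translated = fpkm >= min_fpkm
        out.append(rec)
    return out


def annotate_uorfs(
    uorfs: Sequence[UORFRecord],
    transcript_seqs: Mapping[str, str],
    engine: FoldingEngine | None = None,
    kozak_up: int = 6,
    kozak_down: int = 4,
) -> list[UORFRecord]:
    """Fill Kozak context and NMFE for each uORF from transcript sequences."""
    eng = engine or NussinovEngine()
    for rec in uorfs:
        seq = transcript_seqs[rec.transcript_id]
        a, b = rec.start - kozak_up, rec.start + kozak_down
        rec.kozak_context = seq[a:b] if a >= 0 and b <= len(seq) else None
        body = seq[rec.start : rec.end]
        rec.nmfe = eng.mfe(body) / len(body)
    return list(uorfs)


def uorf_summary(uorfs: Sequence[UORFRecord]) -> dict[str, float]:
    """Headline numbers: total uORFs, genes carrying >= 1, mean per such
    gene, and median uORF length (nt)."""
    n = len(uorfs)
    genes = {u.gene_id for u in uorfs}
    return {
        "n_uorfs": n,
        "n_genes": len(genes),
        "mean_per_gene": n / len(genes) if genes else float("nan"),
        "median_length": float(np.median([u.length for u in uorfs])) if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# Kozak position-frequency matrices
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyMatrix:
    """Base frequencies around a start codon; A of AUG is position +1.

    ``positions`` run -up..-1 then +1..+down (no 0); columns with data sum
    to 1 over A/C/G/U.
    """

    positions: list[int]
    freqs: pd.DataFrame  # index: base AUGC-ish, columns: positions
    n_sequences: int

    def consensus(self) -> str:
        return "".join(self.freqs[p].idxmax() if self.freqs[p].sum() > 0 else "N"
                       for p in self.positions)


def kozak_matrix(
    contexts: Iterable[str | None], up: int = 6, down: int = 4
) -> PositionFrequencyMatrix:
    """Column-normalized PFM from fixed-width context windows.

    Windows must be ``up + down`` wide; None/short entries are skipped.
    """
    width = up + down
    positions = list(range(-up, 0)) + list(range(1, down + 1))
    counts = np.zeros((4, width), dtype=float)
    bases = "ACGU"
    idx = {b: i for i, b in enumerate(bases)}
    n = 0
    for ctx in contexts:
        if ctx is None or len(ctx) != width:
            continue
        n += 1
        for col, ch in enumerate(ctx.upper().replace("T", "U")):
            if ch in idx:
                counts[idx[ch], col] += 1
    sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(sums > 0, counts / sums, 0.0)
    df = pd.DataFrame(freqs, index=list(bases), columns=positions)
    return PositionFrequencyMatrix(positions, df, n)


def morf_kozak_contexts(
    models: Iterable, genome: Mapping[str, str], up: int = 6, down: int = 4
) -> list[str | None]:
    """Kozak windows around the main-ORF start codon of each transcript."""
    out: list[str | None] = []
    for m in models:
        if m.cds_length <= 0:
            continue
        seq = m.sequence(genome)
        a, b = m.cds_span[0] - up, m.cds_span[0] + down
        out.append(seq[a:b] if a >= 0 and b <= len(seq) else None)
    return out


# ---------------------------------------------------------------------------
# uORF / mORF relationships
# ---------------------------------------------------------------------------

def te_by_uorf_class(
    te_records: Mapping[str, float], uorfs: Sequence[UORFRecord]
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Compare mORF TE among genes with no, one, or multiple translated uORFs.

    ``te_records`` maps gene_id -> log2 TE. Genes enter the comparison only
    if they carry >= 1 predicted uORF (so "none" means none *translated*).
    Returns the per-class log2-TE arrays and pairwise two-sample KS tests;
    pairs involving a class with < 2 genes are skipped and flagged.
    """
    n_translated: dict[str, int] = {}
    for u in uorfs:
        n_translated.setdefault(u.gene_id, 0)
        if u.translated:
            n_translated[u.gene_id] += 1
    classes: dict[str, list[float]] = {"none": [], "one": [], "multiple": []}
    for gid, k in n_translated.items():
        if gid not in te_records:
            continue
        label = "none" if k == 0 else ("one" if k == 1 else "multiple")
        classes[label].append(te_records[gid])
    arrays = {k: np.asarray(v, dtype=float) for k, v in classes.items()}
    rows = []
    from itertools import combinations

    for g1, g2 in combinations(["none", "one", "multiple"], 2):
        a, b = arrays[g1], arrays[g2]
        if len(a) < 2 or len(b) < 2:
            rows.append({"group1": g1, "group2": g2, "D": np.nan, "pvalue": np.nan,
                         "skipped": True})
            continue
        res = stats.ks_2samp(a, b)
        rows.append({"group1": g1, "group2": g2, "D": float(res.statistic),
                     "pvalue": float(res.pvalue), "skipped": False})
    return arrays, pd.DataFrame(rows)


def uorf_feature_tests(
    translated: Sequence[UORFRecord], untranslated: Sequence[UORFRecord]
) -> pd.DataFrame:
    """Welch two-tailed t-tests comparing translated vs untranslated uORFs.

    Features: uORF length, host 5'UTR length, NMFE, normalized distance to
    the CDS start and to the TSS.
    """
    if not translated or not untranslated:
        raise ValueError("both uORF sets must be non-empty")
    feats = {
        "uorf_length": lambda u: u.length,
        "utr5_length": lambda u: u.utr5_length,
        "nmfe": lambda u: u.nmfe,
        "norm_dist_to_cds": lambda u: u.norm_dist_to_cds,
        "norm_dist_to_tss": lambda u: u.norm_dist_to_tss,
    }
    rows = []
    for name, get in feats.items():
        a = np.asarray([get(u) for u in translated], dtype=float)
        b = np.asarray([get(u) for u in untranslated], dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "feature": name,
                "mean_translated": float(a.mean()),
                "mean_untranslated": float(b.mean()),
                "t": float(t),
                "pvalue": float(p),
            }
        )
    return pd.DataFrame(rows)


def uorfs_to_frame(uorfs: Sequence[UORFRecord]) -> pd.DataFrame:
    """One row per uORF with every UORFRecord field (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "gene_id": u.gene_id,
                "transcript_id": u.transcript_id,
                "utr5_length": u.utr5_length,
                "start": u.start,
                "end": u.end,
                "length": u.length,
                "fpkm": u.fpkm,
                "translated": u.translated,
                "norm_dist_to_cds": u.norm_dist_to_cds,
                "norm_dist_to_tss": u.norm_dist_to_tss,
                "nmfe": u.nmfe,
                "kozak_context": u.kozak_context,
            }
            for u in uorfs
        ]
    )
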