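"""Ribosome-footprint quality characterization.

Three standard checks that a Ribo-seq library behaves like ribosome
footprints rather than degraded RNA: (1) the read-length distribution
(plant RPFs cluster near 33 nt), (2) the genomic-feature assignment of
footprint 5' ends (CDS-dominated, ~80% in a good library), and (3) the
3-nucleotide periodicity of 5' ends over coding regions, summarized as a
metagene profile anchored at the start or stop codon.

No P-site offsetting is applied anywhere: reading frame is defined
directly from the footprint 5' end, offset modulo 3 from the CDS start.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AlignedFootprint, TranscriptModel
from .quantification import longest_transcripts

FEATURE_LABELS = ("CDS", "5UTR", "3UTR", "intron", "intergenic")
# on overlap, a 5' end is credited to the highest-priority feature
_PRIORITY = {"CDS": 0, "5UTR": 1, "3UTR": 2, "intron": 3}


def filter_rpf_lengths(
    footprints: Sequence[AlignedFootprint], min_len: int = 25, max_len: int = 35
) -> tuple[list[AlignedFootprint], int]:
    """Keep footprints with min <= length <= max; also return #removed."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = [fp for fp in footprints if min_len <= fp.length <= max_len]
    return kept, len(footprints) - len(kept)


def length_histogram(footprints: Iterable[AlignedFootprint]) -> dict[int, int]:
    """Footprint length -> count."""
    return dict(sorted(Counter(fp.length for fp in footprints).items()))


class FeatureIndex:
    """Strand-aware genomic interval index for footprint feature lookup.

    Built from the representative (longest) transcript of each gene.
    Overlap ties resolve CDS > 5UTR > 3UTR > intron, then lexicographic
    gene id.
    """

    def __init__(self, models: Iterable[TranscriptModel]):
        from intervaltree import IntervalTree

        self._trees: dict[tuple[str, str], "IntervalTree"] = {}
        for m in longest_transcripts(models).values():
            tree = self._trees.setdefault((m.chromosome, m.strand), IntervalTree())
            for region in ("CDS", "5UTR", "3UTR", "intron"):
                for s, e in m.genomic_intervals(region):
                    if e > s:
                        tree.addi(s, e, (region, m.gene_id))

    def lookup(self, fp: AlignedFootprint) -> tuple[str, str | None]:
        """(feature label, gene id or None) for a footprint's 5' end."""
        tree = self._trees.get((fp.chromosome, fp.strand))
        if tree is None:
            return "intergenic", None
        hits = [iv.data for iv in tree[fp.five_prime_pos]]
        if not hits:
            return "intergenic", None
        region, gid = min(hits, key=lambda d: (_PRIORITY[d[0]], d[1]))
        return region, gid


def assign_feature(
    fp: AlignedFootprint, index: FeatureIndex
) -> str:
    """Feature label of one footprint (5'-end rule)."""
    return index.lookup(fp)[0]


def feature_proportions(
    footprints: Sequence[AlignedFootprint], models: Iterable[TranscriptModel]
) -> dict[str, float]:
    """Fraction of footprints per feature label; sums to 1 over all reads."""
    index = FeatureIndex(models)
    counts = Counter(index.lookup(fp)[0] for fp in footprints)
    total = sum(counts.values())
    return {lab: counts.get(lab, 0) / total if total else 0.0 for lab in FEATURE_LABELS}


@dataclass
class MetageneProfile:
    """5'-end counts by offset relative to a codon anchor.

    ``offsets`` run symmetrically -window..window-1 around the anchor
    (the first base of the start codon, or the first base of the stop
    codon). ``frame_totals`` aggregate in-window counts by offset mod 3.
    """

    anchor: str  # 'start_codon' | 'stop_codon'
    window: int
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def offsets(self) -> list[int]:
        return list(range(-self.window, self.window))

    @property
    def frame_totals(self) -> tuple[int, int, int]:
        totals = [0, 0, 0]
        for off, n in self.counts.items():
            totals[off % 3] += n
        return tuple(totals)

    def frame_fractions(self) -> tuple[float, float, float]:
        t = self.frame_totals
        s = sum(t)
        return tuple(x / s for x in t) if s else (0.0, 0.0, 0.0)


def metagene(
    footprints: Sequence[AlignedFootprint],
    models: Iterable[TranscriptModel],
    window: int = 30,
) -> dict[str, MetageneProfile]:
    """Metagene profiles of 5' ends around start and stop codons.

    Offsets are computed in transcript coordinates relative to the CDS
    start (or the first base of the stop codon); frame = offset mod 3.
    Transcripts without a CDS, or flagged as frame-broken, are skipped.
    """
    reps = [
        m for m in longest_transcripts(models).values()
        if m.cds_length > 0 and m.cds_frame_ok
    ]
    by_loc: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in reps:
        by_loc.setdefault((m.chromosome, m.strand), []).append(m)

    profiles = {
        "start_codon": MetageneProfile("start_codon", window),
        "stop_codon": MetageneProfile("stop_codon", window),
    }
    from intervaltree import IntervalTree

    span_trees: dict[tuple[str, str], IntervalTree] = {}
    for key, ms in by_loc.items():
        tree = IntervalTree()
        for m in ms:
            s, e = m.genomic_span()
            tree.addi(s, e, m)
        span_trees[key] = tree

    for fp in footprints:
        tree = span_trees.get((fp.chromosome, fp.strand))
        if tree is None:
            continue
        for iv in tree[fp.five_prime_pos]:
            m: TranscriptModel = iv.data
            t = m.to_transcript(fp.five_prime_pos)
            if t is None:
                continue
            for anchor, a in (
                ("start_codon", m.cds_span[0]),
                ("stop_codon", m.cds_span[1] - 3),
            ):
                off = t - a
                if -window <= off < window:
                    prof = profiles[anchor]
                    prof.counts[off] = prof.counts.get(off, 0) + 1
            break  # credit each read to one transcript
    return profiles


def cds_frame_fractions(
    footprints: Sequence[AlignedFootprint], models: Iterable[TranscriptModel]
) -> tuple[float, float, float]:
    """Fraction of CDS-assigned 5' ends in frames 0/1/2 over the whole CDS.

    Frame is (transcript offset from the CDS start) mod 3; this is the
    periodicity figure of merit for a library.
    """
    reps = {
        m.gene_id: m for m in longest_transcripts(models).values()
        if m.cds_length > 0 and m.cds_frame_ok
    }
    index = FeatureIndex(reps.values())
    totals = [0, 0, 0]
    for fp in footprints:
        region, gid = index.lookup(fp)
        if region != "CDS" or gid not in reps:
            continue
        m = reps[gid]
        t = m.to_transcript(fp.five_prime_pos)
        if t is None:
            continue
        totals[(t - m.cds_span[0]) % 3] += 1
    s = sum(totals)
    if s == 0:
        return (0.0, 0.0, 0.0)
    return tuple(x / s for x in totals)
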