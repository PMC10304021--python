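"""Shared genome/transcript data model and readers/writers for external formats.

All internal coordinates are 0-based half-open. GFF3 and SAM use 1-based
conventions; conversion happens at the format boundary and nowhere else.

A :class:`TranscriptModel` carries the exon structure of one mRNA plus the
transcript-coordinate spans of its 5'UTR, CDS and 3'UTR, and provides the
genomic<->transcript coordinate maps every downstream stage relies on
(footprint feature assignment, metagene profiles, uORF coordinates).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import gffutils
import pysam


class GFF3ParseError(ValueError):
    """Raised when the annotation hierarchy is malformed."""


class AlignedFootprint(NamedTuple):
    """One aligned read reduced to its biological 5' end.

    ``five_prime_pos`` is the 0-based genomic coordinate of the 5'-most
    base of the *read* — the leftmost aligned base on '+', the rightmost
    on '-'.
    """

    chromosome: str
    strand: str
    five_prime_pos: int
    length: int


@dataclass
class CountTable:
    """Per-gene integer counts for one assay/condition/replicate library."""

    assay: str  # "RNA" or "RIBO"
    condition: str
    replicate: int
    counts: dict[str, int]

    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class TranscriptModel:
    """Exon/CDS/UTR structure of one transcript with coordinate maps.

    ``exons`` are genomic 0-based half-open intervals sorted 5'->3' in
    *transcript* orientation (decreasing genomic position on '-').
    ``cds_span``/``utr5_span``/``utr3_span`` are transcript-coordinate
    intervals; transcript coordinate 0 is the transcription start site.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int]
    utr5_span: tuple[int, int]
    utr3_span: tuple[int, int]
    cds_frame_ok: bool = True
    _cumlen: list[int] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        cum = [0]
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon {(s, e)} in {self.transcript_id}")
            cum.append(cum[-1] + (e - s))
        self._cumlen = cum

    @property
    def length(self) -> int:
        return self._cumlen[-1]

    @property
    def utr5_length(self) -> int:
        return self.utr5_span[1] - self.utr5_span[0]

    @property
    def cds_length(self) -> int:
        return self.cds_span[1] - self.cds_span[0]

    @property
    def utr3_length(self) -> int:
        return self.utr3_span[1] - self.utr3_span[0]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        starts = sorted(s for s, _ in self.exons)
        ends = sorted(e for _, e in self.exons)
        for (_, e_prev), (s_next, _) in zip(
            sorted(self.exons), sorted(self.exons)[1:]
        ):
            if s_next < e_prev:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        del starts, ends
        if self.utr5_span != (0, self.cds_span[0]):
            raise ValueError(f"utr5/cds spans do not abut in {self.transcript_id}")
        if self.utr3_span != (self.cds_span[1], self.length):
            raise ValueError(f"cds/utr3 spans do not abut in {self.transcript_id}")
        if self.utr5_length + self.cds_length + self.utr3_length != self.length:
            raise ValueError(f"region lengths do not tile {self.transcript_id}")
        if self.cds_length > 0 and self.cds_frame_ok and self.cds_length % 3 != 0:
            raise ValueError(f"CDS length not a multiple of 3 in {self.transcript_id}")

    # ---- coordinate maps -------------------------------------------------

    def to_genome(self, t: int) -> int:
        """Genomic position of transcript coordinate ``t``."""
        if not 0 <= t < self.length:
            raise IndexError(f"transcript coordinate {t} out of range")
        # exons are few; linear scan is fine and branch-predictable
        for i, (s, e) in enumerate(self.exons):
            if t < self._cumlen[i + 1]:
                off = t - self._cumlen[i]
                return s + off if self.strand == "+" else e - 1 - off
        raise AssertionError("unreachable")

    def to_transcript(self, g: int) -> int | None:
        """Transcript coordinate of genomic position ``g``; None if intronic
        or outside the transcript."""
        for i, (s, e) in enumerate(self.exons):
            if s <= g < e:
                off = g - s if self.strand == "+" else e - 1 - g
                return self._cumlen[i] + off
        return None

    def genomic_span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def region_of(self, t: int) -> str:
        """Region label ('5UTR'/'CDS'/'3UTR') of transcript coordinate t."""
        if self.utr5_span[0] <= t < self.utr5_span[1]:
            return "5UTR"
        if self.cds_span[0] <= t < self.cds_span[1]:
            return "CDS"
        return "3UTR"

    def genomic_intervals(self, region: str) -> list[tuple[int, int]]:
        """Genomic half-open intervals covered by a transcript region.

        ``region`` is one of '5UTR', 'CDS', '3UTR', 'exon', 'intron'.
        """
        if region == "intron":
            out = []
            for (s1, e1), (s2, e2) in zip(sorted(self.exons), sorted(self.exons)[1:]):
                out.append((e1, s2))
            return out
        if region == "exon":
            span = (0, self.length)
        else:
            span = {"5UTR": self.utr5_span, "CDS": self.cds_span, "3UTR": self.utr3_span}[region]
        t0, t1 = span
        if t1 <= t0:
            return []
        out = []
        for i, (s, e) in enumerate(self.exons):
            lo = max(t0, self._cumlen[i])
            hi = min(t1, self._cumlen[i + 1])
            if lo >= hi:
                continue
            if self.strand == "+":
                g0 = s + (lo - self._cumlen[i])
                g1 = s + (hi - self._cumlen[i])
            else:
                g1 = e - (lo - self._cumlen[i])
                g0 = e - (hi - self._cumlen[i])
            out.append((g0, g1))
        return sorted(out)

    def sequence(self, genome: dict[str, str]) -> str:
        """Spliced transcript sequence (5'->3') from a chromosome dict."""
        chrom = genome[self.chromosome]
        parts = []
        for s, e in self.exons:
            seg = chrom[s:e]
            parts.append(_revcomp(seg) if self.strand == "-" else seg)
        return "".join(parts)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def parse_gff3(path: str) -> list[TranscriptModel]:
    """Parse a GFF3 annotation into TranscriptModels.

    Requires gene -> mRNA -> exon/CDS hierarchy; five_prime_UTR and
    three_prime_UTR features are optional (UTR spans are derived from the
    exon - CDS set difference when absent). GFF3 1-based inclusive
    coordinates are converted to 0-based half-open.

    A transcript whose CDS length is not a multiple of 3 is kept but
    flagged (``cds_frame_ok=False``) and a warning is emitted; codon-level
    analyses skip such transcripts.
    """
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_ids:
            line = _find_line(path, mrna.id)
            raise GFF3ParseError(
                f"mRNA {mrna.id!r} has no parent gene (line {line}): "
                f"Parent={parents!r}"
            )
        gene_id = parents[0]
        exons_g = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons_g:
            exons_g = [(mrna.start - 1, mrna.end)]
        cds_g = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        strand = mrna.strand
        exons = exons_g if strand == "+" else exons_g[::-1]
        model = _assemble(mrna.id, gene_id, mrna.seqid, strand, exons, cds_g)
        # explicit UTR features win over the exon-CDS derivation
        utr5_g = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="five_prime_UTR")
        ]
        utr3_g = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="three_prime_UTR")
        ]
        if utr5_g or utr3_g:
            e5 = sum(e - s for s, e in utr5_g) if utr5_g else model.utr5_length
            e3 = sum(e - s for s, e in utr3_g) if utr3_g else model.utr3_length
            if (e5, e3) != (model.utr5_length, model.utr3_length):
                warnings.warn(
                    f"{mrna.id}: explicit UTR lengths ({e5}, {e3}) disagree with "
                    f"exon-CDS derivation ({model.utr5_length}, {model.utr3_length}); "
                    "using the explicit annotation"
                )
                model.utr5_span = (0, e5)
                model.cds_span = (e5, model.length - e3)
                model.utr3_span = (model.length - e3, model.length)
        if model.cds_length % 3 != 0:
            warnings.warn(
                f"{mrna.id}: CDS length {model.cds_length} is not a multiple of 3; "
                "transcript flagged and excluded from codon-level analyses"
            )
            model.cds_frame_ok = False
        models.append(model)
    return models


def _assemble(tid, gid, chrom, strand, exons, cds_g) -> TranscriptModel:
    m = TranscriptModel(tid, gid, chrom, strand, exons, (0, 0), (0, 0), (0, 0))
    if cds_g:
        tpos = []
        for s, e in cds_g:
            a = m.to_transcript(s)
            b = m.to_transcript(e - 1)
            if a is None or b is None:
                raise GFF3ParseError(f"CDS interval {(s, e)} of {tid} outside exons")
            tpos.extend((a, b))
        c0, c1 = min(tpos), max(tpos) + 1
    else:
        c0 = c1 = m.length  # non-coding: empty CDS at the 3' end, all 5'UTR
    m.cds_span = (c0, c1)
    m.utr5_span = (0, c0)
    m.utr3_span = (c1, m.length)
    return m


def _find_line(path: str, feature_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if feature_id in line and not line.startswith("#"):
                return i
    return -1


def write_gff3(models: Iterable[TranscriptModel], path: str) -> None:
    """Serialize TranscriptModels back to GFF3 (gene/mRNA/exon/CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[TranscriptModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gid in sorted(by_gene):
            txs = by_gene[gid]
            g0 = min(m.genomic_span()[0] for m in txs)
            g1 = max(m.genomic_span()[1] for m in txs)
            chrom, strand = txs[0].chromosome, txs[0].strand
            fh.write(
                f"{chrom}\ttranslatome\tgene\t{g0 + 1}\t{g1}\t.\t{strand}\t.\tID={gid}\n"
            )
            for m in txs:
                s0, s1 = m.genomic_span()
                fh.write(
                    f"{chrom}\ttranslatome\tmRNA\t{s0 + 1}\t{s1}\t.\t{strand}\t.\t"
                    f"ID={m.transcript_id};Parent={gid}\n"
                )
                for s, e in sorted(m.exons):
                    fh.write(
                        f"{chrom}\ttranslatome\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"Parent={m.transcript_id}\n"
                    )
                for s, e in m.genomic_intervals("CDS"):
                    fh.write(
                        f"{chrom}\ttranslatome\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                        f"Parent={m.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Footprints
# ---------------------------------------------------------------------------

def read_footprints(path: str, format: str = "tsv") -> list[AlignedFootprint]:
    """Read aligned footprints from a 4-column TSV or a SAM file.

    TSV columns: chromosome, strand, five_prime_pos (0-based), length; a
    header row is recognised and skipped. Records with an unknown strand
    symbol are rejected and their count reported via a warning.
    """
    if format == "tsv":
        return _read_footprints_tsv(path)
    if format == "sam":
        return _read_footprints_sam(path)
    raise ValueError(f"unknown footprint format {format!r}")


def _read_footprints_tsv(path: str) -> list[AlignedFootprint]:
    out: list[AlignedFootprint] = []
    rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "chromosome":  # header
                continue
            chrom, strand, pos, length = fields[:4]
            if strand not in "+-":
                rejected += 1
                continue
            out.append(AlignedFootprint(chrom, strand, int(pos), int(length)))
    if rejected:
        warnings.warn(f"{rejected} footprint records rejected (unknown strand)")
    return out


def _read_footprints_sam(path: str) -> list[AlignedFootprint]:
    out: list[AlignedFootprint] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped:
                continue
            length = read.query_length or read.infer_query_length() or 0
            if length <= 0:
                continue
            if read.is_reverse:
                five = read.reference_end - 1  # rightmost aligned base
                strand = "-"
            else:
                five = read.reference_start
                strand = "+"
            out.append(AlignedFootprint(read.reference_name, strand, five, length))
    return out


def write_footprints_tsv(footprints: Iterable[AlignedFootprint], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\tstrand\tfive_prime_pos\tlength\n")
        for fp in footprints:
            fh.write(f"{fp.chromosome}\t{fp.strand}\t{fp.five_prime_pos}\t{fp.length}\n")


def write_bedgraph(footprints: Sequence[AlignedFootprint], path: str) -> None:
    """Write per-position 5'-end counts as bedGraph, sorted by chrom, start."""
    if not footprints:
        raise ValueError("no footprints to export")
    counts = Counter((fp.chromosome, fp.five_prime_pos) for fp in footprints)
    with open(path, "w") as fh:
        for (chrom, pos), n in sorted(counts.items()):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{n}\n")


# ---------------------------------------------------------------------------
# FASTA and count tables
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Chromosome/sequence dict from a FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_count_tables(tables: Sequence[CountTable], path: str) -> None:
    """Wide TSV: gene_id plus one `<assay>_<condition>_<rep>` column per library."""
    import pandas as pd

    genes = sorted(set().union(*(t.counts for t in tables)))
    data = {"gene_id": genes}
    for t in tables:
        col = f"{t.assay}_{t.condition}_{t.replicate}"
        data[col] = [t.counts.get(g, 0) for g in genes]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_count_tables(path: str) -> list[CountTable]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    tables = []
    for col in df.columns:
        if col == "gene_id":
            continue
        assay, condition, rep = col.rsplit("_", 2)
        tables.append(
            CountTable(assay, condition, int(rep), dict(zip(df["gene_id"], df[col].astype(int))))
        )
    return tables
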