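"""Synthetic genome, count and footprint generator with a known truth table.

The generator emulates the statistical structure of a two-condition,
two-replicate Ribo-seq + RNA-seq experiment so that every downstream stage
has a ground truth to be scored against:

* single-exon (optionally multi-exon) protein-coding genes with 5'UTR,
  CDS and 3'UTR whose lengths are drawn from realistic plant ranges
  (5'UTRs 60-460 nt);
* negative-binomial counts per gene/assay/condition/replicate, with
  planted transcription-only, translation-only and accordant log2
  fold-change effects that realize each of the nine regulatory quadrants;
* ribosome footprints 25-35 nt with mode 33 nt whose 5' ends show frame-0
  periodicity over the CDS at a controllable rate, distributed over
  CDS/3'UTR/5'UTR at controllable proportions;
* AUG-initiated uORFs planted at recorded 5'UTR positions — the
  background 5'UTR is AUG-free, so a scanner must find exactly the
  planted set — with ribosome occupancy given only to uORFs flagged
  translated.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AlignedFootprint, CountTable, TranscriptModel, _revcomp

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")

# quadrant -> (transcriptional log2fc, translational-level log2fc), in units
# of the planted effect size; the TE component is their difference
QUADRANT_EFFECTS: dict[str, tuple[int, int]] = {
    "A": (-1, +1), "B": (0, +1), "C": (+1, +1),
    "D": (-1, 0), "E": (0, 0), "F": (+1, 0),
    "G": (-1, -1), "H": (0, -1), "I": (+1, -1),
}

# footprint length pmf support 25..35, mode at 33
_LENGTH_WEIGHTS = {
    25: 2, 26: 2, 27: 3, 28: 4, 29: 5, 30: 6, 31: 8, 32: 12, 33: 30, 34: 10, 35: 6,
}


@dataclass
class SimConfig:
    n_genes: int = 2000
    utr5_length_range: tuple[int, int] = (60, 460)
    cds_length_range: tuple[int, int] = (300, 1500)
    utr3_length_range: tuple[int, int] = (100, 400)
    conditions: tuple[str, str] = ("CK", "S")
    replicates: int = 2
    rpf_length_mode: int = 33
    rpf_length_range: tuple[int, int] = (25, 35)
    p0: float = 0.9
    region_weights: tuple[float, float, float] = (0.80, 0.11, 0.09)  # CDS/3UTR/5UTR
    nb_dispersion: float = 0.01
    base_expression_range: tuple[float, float] = (200.0, 2000.0)
    effect_log2fc: float = 2.0
    quadrant_probs: dict[str, float] = field(
        default_factory=lambda: {
            "E": 0.70, "C": 0.05, "G": 0.05, "B": 0.04, "D": 0.04,
            "F": 0.04, "H": 0.04, "A": 0.02, "I": 0.02,
        }
    )
    uorf_gene_fraction: float = 0.5
    max_uorfs_per_gene: int = 3
    uorf_length_range: tuple[int, int] = (9, 90)  # nt incl. stop, multiples of 3
    uorf_translated_fraction: float = 0.5
    uorf_occupancy_margin: float = 2.0
    n_footprints: int = 150_000
    library_scale_sigma: float = 0.0  # lognormal per-library depth jitter
    morf_kozak_minus3_bias: float = 0.85  # P(A/G at -3)
    morf_kozak_plus4_bias: float = 0.7  # P(G at +4)
    multi_exon_prob: float = 0.0
    intron_length_range: tuple[int, int] = (60, 200)
    genes_per_chromosome: int = 200
    intergenic_gap_range: tuple[int, int] = (150, 400)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        lo, hi = self.cds_length_range
        if (hi // 3) * 3 < lo:
            raise ValueError("cds_length_range contains no multiple of 3")
        if abs(sum(self.quadrant_probs.values()) - 1.0) > 1e-9:
            raise ValueError("quadrant_probs must sum to 1")


@dataclass
class PlantedUORF:
    start: int  # transcript coords (5'UTR starts at 0), 0-based half-open
    end: int
    translated: bool


@dataclass
class GeneTruth:
    tx_log2fc: float
    tl_log2fc: float
    true_quadrant: str
    base_expression: float
    dispersion: float
    uorfs: list[PlantedUORF] = field(default_factory=list)


@dataclass
class SimTruth:
    genes: dict[str, GeneTruth]

    def quadrants(self) -> dict[str, str]:
        return {g: t.true_quadrant for g, t in self.genes.items()}


# ---------------------------------------------------------------------------
# sequence assembly helpers
# ---------------------------------------------------------------------------

def _seq_no_atg(rng: np.random.Generator, n: int, prev: str) -> str:
    """Random DNA of length n that never completes an ATG trigram, given
    the two preceding characters ``prev``."""
    out: list[str] = []
    tail = prev[-2:] if len(prev) >= 2 else prev
    for _ in range(n):
        choices = "ACGT"
        if tail.endswith("AT"):
            choices = "ACT"  # a G would complete ATG
        ch = choices[rng.integers(len(choices))]
        out.append(ch)
        tail = (tail + ch)[-2:]
    return "".join(out)


def _uorf_body(rng: np.random.Generator, length: int) -> str:
    """AUG + sense codons + stop, with no internal ATG trigram in any frame
    and no ATG completed across the trailing junction."""
    n_inner = length // 3 - 2
    while True:
        inner = "".join(
            SENSE_CODONS[rng.integers(len(SENSE_CODONS))] for _ in range(n_inner)
        )
        stop = _STOPS[rng.integers(3)]
        body = "ATG" + inner + stop
        if body.find("ATG", 1) == -1:
            return body


def _plant_uorfs(
    rng: np.random.Generator, utr_len: int, cfg: SimConfig
) -> list[PlantedUORF]:
    """Choose non-overlapping uORF intervals inside a 5'UTR, leaving the
    last 3 bases free for the mORF Kozak context."""
    n = int(rng.integers(1, cfg.max_uorfs_per_gene + 1))
    lo, hi = cfg.uorf_length_range
    placed: list[PlantedUORF] = []
    usable_end = utr_len - 3
    for _ in range(n):
        for _attempt in range(20):
            max_len = min(hi, usable_end)
            if max_len < max(lo, 9):
                break
            length = int(rng.integers(max(lo, 9) // 3, max_len // 3 + 1)) * 3
            start = int(rng.integers(0, usable_end - length + 1))
            end = start + length
            if all(end + 1 <= u.start or start >= u.end + 1 for u in placed):
                placed.append(
                    PlantedUORF(start, end, bool(rng.random() < cfg.uorf_translated_fraction))
                )
                break
    return sorted(placed, key=lambda u: u.start)


def _build_utr5(
    rng: np.random.Generator, utr_len: int, uorfs: Sequence[PlantedUORF],
    cfg: SimConfig,
) -> str:
    parts: list[str] = []
    cursor = 0
    seq = ""
    for u in uorfs:
        seq += _seq_no_atg(rng, u.start - cursor, seq)
        seq += _uorf_body(rng, u.end - u.start)
        cursor = u.end
    seq += _seq_no_atg(rng, utr_len - cursor, seq)
    # mORF Kozak bias at -3 (A/G), outside every uORF by construction
    if utr_len >= 3 and rng.random() < cfg.morf_kozak_minus3_bias:
        base = "AG"[rng.integers(2)]
        pos = utr_len - 3
        cand = seq[:pos] + base + seq[pos + 1 :]
        if _atg_positions(cand) == {u.start for u in uorfs}:
            seq = cand
    assert len(seq) == utr_len
    return seq


def _atg_positions(seq: str) -> set[int]:
    out, i = set(), seq.find("ATG")
    while i != -1:
        out.add(i)
        i = seq.find("ATG", i + 1)
    return out


def _build_cds(rng: np.random.Generator, cds_len: int, cfg: SimConfig) -> str:
    n_inner = cds_len // 3 - 2
    codons = ["ATG"]
    for k in range(n_inner):
        if k == 0 and rng.random() < cfg.morf_kozak_plus4_bias:
            g_codons = [c for c in SENSE_CODONS if c[0] == "G"]
            codons.append(g_codons[rng.integers(len(g_codons))])
        else:
            codons.append(SENSE_CODONS[rng.integers(len(SENSE_CODONS))])
    codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# generate_genome
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimConfig | None = None,
) -> tuple[list[TranscriptModel], dict[str, str], SimTruth]:
    """Build annotation, genome sequence and truth table.

    Deterministic given ``config.seed``. The set of AUG trigrams in each
    5'UTR equals exactly the planted uORF starts (verified at build time),
    and each planted uORF's first in-frame stop is its recorded end.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    quadrant_names = list(cfg.quadrant_probs)
    quadrant_p = np.array([cfg.quadrant_probs[q] for q in quadrant_names])

    models: list[TranscriptModel] = []
    chroms: dict[str, list[str]] = {}
    truth: dict[str, GeneTruth] = {}
    chrom_cursor: dict[str, int] = {}

    lo_b, hi_b = cfg.base_expression_range
    for i in range(cfg.n_genes):
        gid = f"G{i:05d}"
        tid = f"{gid}.1"
        chrom = f"chr{i // cfg.genes_per_chromosome + 1}"
        utr5_len = int(rng.integers(cfg.utr5_length_range[0], cfg.utr5_length_range[1] + 1))
        c_lo, c_hi = cfg.cds_length_range
        cds_len = int(rng.integers(math.ceil(c_lo / 3), c_hi // 3 + 1)) * 3
        utr3_len = int(rng.integers(cfg.utr3_length_range[0], cfg.utr3_length_range[1] + 1))

        q = quadrant_names[rng.choice(len(quadrant_names), p=quadrant_p)]
        sx, sl = QUADRANT_EFFECTS[q]
        tx_lfc = sx * cfg.effect_log2fc
        ribo_lfc = sl * cfg.effect_log2fc
        base = float(np.exp(rng.uniform(np.log(lo_b), np.log(hi_b))))

        uorfs = (
            _plant_uorfs(rng, utr5_len, cfg)
            if rng.random() < cfg.uorf_gene_fraction
            else []
        )
        utr5 = _build_utr5(rng, utr5_len, uorfs, cfg)
        _verify_planted(utr5, uorfs, tid)
        cds = _build_cds(rng, cds_len, cfg)
        utr3 = _random_seq(rng, utr3_len)
        tx_seq = utr5 + cds + utr3
        L = len(tx_seq)

        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        start = chrom_cursor.get(chrom, 0) + gap

        if rng.random() < cfg.multi_exon_prob and L > 40:
            k = int(rng.integers(20, L - 20))
            il = int(rng.integers(*cfg.intron_length_range))
            pre = tx_seq[:k] + _random_seq(rng, il) + tx_seq[k:]
            exons_pre = [(0, k), (k + il, L + il)]
        else:
            pre = tx_seq
            exons_pre = [(0, L)]
        pre_len = len(pre)
        if strand == "+":
            gseq = pre
            exons_g = [(start + a, start + b) for a, b in exons_pre]
            exons = sorted(exons_g)
        else:
            gseq = _revcomp(pre)
            exons_g = [(start + pre_len - b, start + pre_len - a) for a, b in exons_pre]
            exons = sorted(exons_g, reverse=True)  # 5'->3' transcript order

        m = TranscriptModel(
            tid, gid, chrom, strand, exons,
            cds_span=(utr5_len, utr5_len + cds_len),
            utr5_span=(0, utr5_len),
            utr3_span=(utr5_len + cds_len, L),
        )
        m.validate()
        models.append(m)
        chroms.setdefault(chrom, [])
        pad = start - chrom_cursor.get(chrom, 0)
        chroms[chrom].append(_random_seq(rng, pad) + gseq)
        chrom_cursor[chrom] = start + pre_len

        truth[gid] = GeneTruth(
            tx_log2fc=tx_lfc,
            tl_log2fc=ribo_lfc - tx_lfc,
            true_quadrant=q,
            base_expression=base,
            dispersion=cfg.nb_dispersion,
            uorfs=uorfs,
        )

    genome = {c: "".join(parts) for c, parts in chroms.items()}
    # sanity: the spliced transcript sequence round-trips
    for m in models[: min(5, len(models))]:
        gid = m.gene_id
        seq = m.sequence(genome)
        assert _atg_positions(seq[: m.utr5_length]) == {
            u.start for u in truth[gid].uorfs
        }
    return models, genome, SimTruth(truth)


def _verify_planted(utr5: str, uorfs: Sequence[PlantedUORF], tid: str) -> None:
    if _atg_positions(utr5) != {u.start for u in uorfs}:
        raise AssertionError(f"{tid}: stray or missing AUG in synthetic 5'UTR")
    for u in uorfs:
        stop_end = None
        for j in range(u.start + 3, len(utr5) - 2, 3):
            if utr5[j : j + 3] in _STOPS:
                stop_end = j + 3
                break
        if stop_end != u.end:
            raise AssertionError(f"{tid}: planted uORF stop mismatch")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    truth: SimTruth, config: SimConfig | None = None, seed: int | None = None
) -> list[CountTable]:
    """NB count tables for both assays, both conditions, all replicates.

    Expected RNA count in the treated condition is base * 2^tx_log2fc;
    expected RIBO count is base * 2^(tx_log2fc + tl_log2fc). Setting
    ``library_scale_sigma`` > 0 adds lognormal per-library depth jitter to
    exercise normalization downstream.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genes = sorted(truth.genes)
    base = np.array([truth.genes[g].base_expression for g in genes])
    tx = np.array([truth.genes[g].tx_log2fc for g in genes])
    tl = np.array([truth.genes[g].tl_log2fc for g in genes])
    disp = np.array([truth.genes[g].dispersion for g in genes])
    ctrl, trt = cfg.conditions
    tables = []
    for assay in ("RNA", "RIBO"):
        for cond in cfg.conditions:
            lfc = np.zeros_like(base)
            if cond == trt:
                lfc = tx if assay == "RNA" else tx + tl
            mu_gene = base * np.power(2.0, lfc)
            for rep in range(1, cfg.replicates + 1):
                lib_scale = (
                    float(np.exp(rng.normal(0.0, cfg.library_scale_sigma)))
                    if cfg.library_scale_sigma > 0
                    else 1.0
                )
                mu = mu_gene * lib_scale
                counts = _nb_draw(rng, mu, disp)
                tables.append(
                    CountTable(assay, cond, rep, dict(zip(genes, counts.tolist())))
                )
    return tables


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    out = np.empty(len(mu), dtype=np.int64)
    tiny = disp < 1e-8
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    if big.any():
        n = 1.0 / disp[big]
        p = n / (n + mu[big])
        out[big] = rng.negative_binomial(n, p)
    return out


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

def simulate_footprints(
    truth: SimTruth,
    models: Sequence[TranscriptModel],
    config: SimConfig | None = None,
    condition: str | None = None,
    seed: int | None = None,
) -> list[AlignedFootprint]:
    """Ribosome footprints for one condition (default: control).

    CDS footprints put their 5' end on a codon start with probability p0
    (remainder split evenly over frames 1 and 2); regions follow
    ``region_weights`` (CDS, 3'UTR, 5'UTR); lengths follow a fixed pmf
    with mode ``rpf_length_mode``. 5'UTR background footprints avoid all
    planted uORF intervals; each translated uORF additionally receives
    enough reads for its FPKM to clear the translated threshold by
    ``uorf_occupancy_margin``; untranslated uORFs receive none.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    cond = condition or cfg.conditions[0]
    treated = cond == cfg.conditions[1]
    by_gene = {m.gene_id: m for m in models}
    genes = sorted(g for g in by_gene if g in truth.genes)
    ribo_lfc = np.array(
        [
            truth.genes[g].tx_log2fc + truth.genes[g].tl_log2fc if treated else 0.0
            for g in genes
        ]
    )
    w = np.array([truth.genes[g].base_expression for g in genes]) * np.power(2.0, ribo_lfc)
    w = w / w.sum()

    lengths = np.array(sorted(_LENGTH_WEIGHTS))
    lw = np.array([_LENGTH_WEIGHTS[l] for l in lengths], dtype=float)
    lw /= lw.sum()

    out: list[AlignedFootprint] = []

    # dedicated occupancy for translated uORFs
    total_cds_approx = int(cfg.n_footprints * cfg.region_weights[0])
    for g in genes:
        m = by_gene[g]
        for u in truth.genes[g].uorfs:
            if not u.translated:
                continue
            need = max(
                1,
                math.ceil(
                    cfg.uorf_occupancy_margin
                    * (u.end - u.start)
                    * total_cds_approx
                    / 1e9
                ),
            )
            for _ in range(need):
                t = int(rng.integers(u.start, u.end))
                out.append(_fp(m, t, int(rng.choice(lengths, p=lw))))

    n_bg = cfg.n_footprints
    gene_idx = rng.choice(len(genes), size=n_bg, p=w)
    region_idx = rng.choice(3, size=n_bg, p=np.asarray(cfg.region_weights))
    len_draw = rng.choice(lengths, size=n_bg, p=lw)
    frames = np.where(
        rng.random(n_bg) < cfg.p0, 0, np.where(rng.random(n_bg) < 0.5, 1, 2)
    )
    for gi, ri, ln, fr in zip(gene_idx, region_idx, len_draw, frames):
        g = genes[gi]
        m = by_gene[g]
        if ri == 0:  # CDS
            n_codons = m.cds_length // 3
            codon = int(rng.integers(0, max(n_codons - 1, 1)))
            t = m.cds_span[0] + 3 * codon + int(fr)
        elif ri == 1:  # 3'UTR
            if m.utr3_length == 0:
                continue
            t = int(rng.integers(m.utr3_span[0], m.utr3_span[1]))
        else:  # 5'UTR, outside planted uORFs
            allowed = _utr5_background_positions(m, truth.genes[g].uorfs)
            if len(allowed) == 0:
                continue
            t = int(allowed[rng.integers(len(allowed))])
        out.append(_fp(m, t, int(ln)))
    return out


def _utr5_background_positions(m: TranscriptModel, uorfs: Sequence[PlantedUORF]) -> np.ndarray:
    mask = np.ones(m.utr5_length, dtype=bool)
    for u in uorfs:
        mask[u.start : u.end] = False
    return np.flatnonzero(mask)


def _fp(m: TranscriptModel, t: int, length: int) -> AlignedFootprint:
    g = m.to_genome(t)
    return AlignedFootprint(m.chromosome, m.strand, g, length)
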