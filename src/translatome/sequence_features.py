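"""Region-level sequence features and their association with translation.

Features are the three the field routinely relates to translational
efficiency: sequence length, GC content, and the normalized minimal free
energy (NMFE) of the predicted RNA secondary structure — the MFE divided by
sequence length, so that long and short regions are comparable.

Folding is pluggable. The built-in :class:`NussinovEngine` maximizes
Watson-Crick + G:U pairs (-1 per pair, minimum hairpin loop of 3 unpaired
bases) by dynamic programming; it is deterministic, dependency-free and
exactly testable against exhaustive structure enumeration. When the
ViennaRNA python bindings are installed, :class:`ViennaEngine` provides
thermodynamic MFEs instead. NMFE comparisons within one engine are
meaningful; values are not comparable across engines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_VALID = set("ACGTU")
_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


@dataclass
class RegionFeatures:
    gene_id: str
    region: str  # '5UTR' | 'CDS' | '3UTR'
    length: int
    gc: float
    nmfe: float


def gc_content(seq: str) -> float:
    """(#G + #C) / length over a DNA or RNA sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise ValueError(f"invalid character {ch!r} at position {i}")
    return (s.count("G") + s.count("C")) / len(s)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


class FoldingEngine(Protocol):
    def mfe(self, seq: str) -> float: ...


class NussinovEngine:
    """Base-pair-maximization folding: MFE = -(max pairs), min loop 3."""

    def mfe(self, seq: str) -> float:
        s = seq.upper().replace("T", "U")
        n = len(s)
        if n < MIN_LOOP + 2:
            return 0.0
        # M[i][j] = max pairs in s[i..j]
        M = np.zeros((n, n), dtype=np.int32)
        for span in range(MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = M[i, j - 1]  # j unpaired
                for k in range(i, j - MIN_LOOP):
                    if _can_pair(s[k], s[j]):
                        left = M[i, k - 1] if k > i else 0
                        cand = left + 1 + (M[k + 1, j - 1] if k + 1 <= j - 1 else 0)
                        if cand > best:
                            best = cand
                M[i, j] = best
        return -float(M[0, n - 1])


class ViennaEngine:
    """Thermodynamic MFE via the ViennaRNA python bindings (optional)."""

    def __init__(self) -> None:
        import RNA  # deferred: optional backend

        self._RNA = RNA

    def mfe(self, seq: str) -> float:
        _, e = self._RNA.fold(seq.upper().replace("T", "U"))
        return float(e)


def get_engine(name: str = "nussinov") -> FoldingEngine:
    if name == "nussinov":
        return NussinovEngine()
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown folding engine {name!r}")


def nmfe(seq: str, engine: FoldingEngine | None = None) -> float:
    """Minimum free energy divided by sequence length (<= 0)."""
    if not seq:
        raise ValueError("empty sequence")
    eng = engine or NussinovEngine()
    return eng.mfe(seq) / len(seq)


def enumerate_structures(seq: str) -> list[frozenset[tuple[int, int]]]:
    """All valid secondary structures of a short sequence, as pair sets.

    A structure is any set of base pairs that is pairwise non-crossing,
    uses each base at most once, pairs only WC/GU partners, and encloses a
    hairpin loop of at least MIN_LOOP unpaired bases. Exponential —
    intended for sequences <= ~14 nt (oracle use only).
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_LOOP + 1, n)
        if _can_pair(s[i], s[j])
    ]

    def compatible(p: tuple[int, int], q: tuple[int, int]) -> bool:
        (a, b), (c, d) = p, q
        if len({a, b, c, d}) < 4:
            return False
        # non-crossing: nested or disjoint
        return (c > b) or (d < a) or (a < c and d < b) or (c < a and b < d)

    structures: list[frozenset[tuple[int, int]]] = []

    def extend(chosen: list[tuple[int, int]], start: int) -> None:
        structures.append(frozenset(chosen))
        for idx in range(start, len(candidates)):
            p = candidates[idx]
            if all(compatible(p, q) for q in chosen):
                chosen.append(p)
                extend(chosen, idx + 1)
                chosen.pop()

    extend([], 0)
    return structures


def enumerate_structures_mfe(seq: str) -> float:
    """Exhaustive MFE oracle: -1 per pair, minimum over all structures."""
    return -float(max(len(st) for st in enumerate_structures(seq)))


def region_features(
    models: Iterable,
    genome: Mapping[str, str],
    engine: FoldingEngine | None = None,
    regions: Sequence[str] = ("5UTR", "CDS", "3UTR"),
) -> pd.DataFrame:
    """Per-gene, per-region length/GC/NMFE table from TranscriptModels."""
    eng = engine or NussinovEngine()
    rows = []
    for m in models:
        seq = m.sequence(genome)
        spans = {"5UTR": m.utr5_span, "CDS": m.cds_span, "3UTR": m.utr3_span}
        for region in regions:
            a, b = spans[region]
            sub = seq[a:b]
            if not sub:
                continue
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "region": region,
                    "length": len(sub),
                    "gc": gc_content(sub),
                    "nmfe": eng.mfe(sub) / len(sub),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "region", "length", "gc", "nmfe"])


# ---------------------------------------------------------------------------
# Association with TE groups / accordance classes
# ---------------------------------------------------------------------------

def features_by_te_group(
    features: pd.DataFrame, te_groups: Mapping[str, str], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries and pairwise Welch t-tests of features across TE groups.

    ``te_groups`` maps gene_id -> group label (G1..G4). Returns
    (summary, tests): per group/region/feature means and medians, and for
    each group pair a two-tailed Welch t-test p-value with significance
    letters at ``alpha`` (no family-wise correction; raw pairwise p).
    Groups with fewer than 2 members are excluded from tests.
    """
    df = features.copy()
    df["group"] = df["gene_id"].map(te_groups)
    df = df.dropna(subset=["group"])
    summaries = (
        df.groupby(["region", "group"])[["length", "gc", "nmfe"]]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
    rows = []
    for region, sub in df.groupby("region"):
        for feat in ("length", "gc", "nmfe"):
            groups = {
                g: s[feat].to_numpy()
                for g, s in sub.groupby("group")
                if len(s) >= 2
            }
            for g1, g2 in combinations(sorted(groups), 2):
                t, p = stats.ttest_ind(groups[g1], groups[g2], equal_var=False)
                rows.append(
                    {
                        "region": region,
                        "feature": feat,
                        "group1": g1,
                        "group2": g2,
                        "t": float(t),
                        "pvalue": float(p),
                        "significant": bool(p < alpha),
                    }
                )
    return summaries, pd.DataFrame(
        rows,
        columns=["region", "feature", "group1", "group2", "t", "pvalue", "significant"],
    )


def significance_letters(
    groups: Sequence[str], pvalues: Mapping[tuple[str, str], float], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different at ``alpha`` (greedy insert-and-absorb assignment)."""
    order = list(groups)
    differ = {
        frozenset(pair) for pair, p in pvalues.items() if p < alpha
    }
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) not in differ for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    out: dict[str, str] = {g: "" for g in order}
    for s, letter in zip(letter_sets, "abcdefghijklmnopqrstuvwxyz"):
        for g in sorted(s, key=order.index):
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def accordance_feature_test(
    accordant: pd.DataFrame, discordant: pd.DataFrame
) -> pd.DataFrame:
    """KS comparison of features between accordantly and discordantly
    regulated genes, per region per feature, with empirical CDFs.

    Returns a long DataFrame with KS statistic D, p-value, and sorted
    sample arrays (for cumulative-curve plotting).
    """
    if accordant.empty or discordant.empty:
        raise ValueError("both accordant and discordant sets must be non-empty")
    rows = []
    for region in sorted(set(accordant["region"]) & set(discordant["region"])):
        a_sub = accordant[accordant["region"] == region]
        d_sub = discordant[discordant["region"] == region]
        for feat in ("length", "gc", "nmfe"):
            a = a_sub[feat].to_numpy()
            d = d_sub[feat].to_numpy()
            res = stats.ks_2samp(a, d)
            rows.append(
                {
                    "region": region,
                    "feature": feat,
                    "D": float(res.statistic),
                    "pvalue": float(res.pvalue),
                    "n_accordant": len(a),
                    "n_discordant": len(d),
                    "ecdf_accordant": np.sort(a),
                    "ecdf_discordant": np.sort(d),
                }
            )
    return pd.DataFrame(rows)
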