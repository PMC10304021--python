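"""Nine-quadrant transcription x translation regulatory classification.

Each gene carries a status (up/down/unchanged) at the transcriptional
level (RNA-seq DE) and the translational level (Ribo-seq DE). The 3x3
grid of joint statuses defines quadrants A-I:

    A = (tx down,      tl up)        B = (tx unchanged, tl up)
    C = (tx up,        tl up)        D = (tx down,      tl unchanged)
    E = (tx unchanged, tl unchanged) F = (tx up,        tl unchanged)
    G = (tx down,      tl down)      H = (tx unchanged, tl down)
    I = (tx up,        tl down)

C and G are "accordant" (same direction at both levels), E is doubly
unchanged, and the remaining six quadrants are "discordant". Summary
statistics mirror the usual reporting: per-quadrant counts and
percentages, shared-DEG Venn overlap as a percentage of the DEG union,
and the Pearson R^2 between fold changes at the two levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

QUADRANTS: dict[tuple[str, str], str] = {
    ("down", "up"): "A",
    ("unchanged", "up"): "B",
    ("up", "up"): "C",
    ("down", "unchanged"): "D",
    ("unchanged", "unchanged"): "E",
    ("up", "unchanged"): "F",
    ("down", "down"): "G",
    ("unchanged", "down"): "H",
    ("up", "down"): "I",
}

ACCORDANT = frozenset({"C", "G"})


@dataclass
class QuadrantLabel:
    gene_id: str
    tx_status: str
    tl_status: str
    quadrant: str
    accordance: str  # 'accordant' | 'discordant' | 'unchanged'


def classify_gene(gene_id: str, tx_status: str, tl_status: str) -> QuadrantLabel:
    """Quadrant label from the per-level statuses (total on the 3x3 grid)."""
    key = (tx_status, tl_status)
    if key not in QUADRANTS:
        raise ValueError(f"invalid status pair {key!r}")
    q = QUADRANTS[key]
    acc = "unchanged" if q == "E" else ("accordant" if q in ACCORDANT else "discordant")
    return QuadrantLabel(gene_id, tx_status, tl_status, q, acc)


def classify_table(tx: pd.DataFrame, tl: pd.DataFrame) -> pd.DataFrame:
    """Join two DE result frames (status column, gene index) into labels.

    Genes present at only one level are excluded; the count of exclusions
    is attached as ``frame.attrs['n_excluded']``.
    """
    common = tx.index.intersection(tl.index)
    n_excluded = len(tx.index.symmetric_difference(tl.index))
    labels = [
        classify_gene(g, tx.loc[g, "status"], tl.loc[g, "status"]) for g in common
    ]
    df = pd.DataFrame(
        {
            "gene_id": [l.gene_id for l in labels],
            "tx_status": [l.tx_status for l in labels],
            "tl_status": [l.tl_status for l in labels],
            "quadrant": [l.quadrant for l in labels],
            "accordance": [l.accordance for l in labels],
        }
    ).set_index("gene_id")
    df.attrs["n_excluded"] = n_excluded
    return df


def quadrant_fractions(labels: pd.DataFrame) -> dict[str, float]:
    """Per-quadrant counts and the unchanged/accordant/discordant split.

    Percentages share one denominator: the number of classified genes.
    """
    if labels.empty:
        raise ValueError("no labels to summarize")
    counts = labels["quadrant"].value_counts().to_dict()
    total = len(labels)
    e = counts.get("E", 0)
    acc = counts.get("C", 0) + counts.get("G", 0)
    disc = total - e - acc
    out = {f"n_{q}": counts.get(q, 0) for q in "ABCDEFGHI"}
    out.update(
        {
            "total": total,
            "pct_unchanged": 100.0 * e / total,
            "pct_accordant": 100.0 * acc / total,
            "pct_discordant": 100.0 * disc / total,
        }
    )
    return out


def shared_deg_stats(
    tx_up: int, tx_down: int, tl_up: int, tl_down: int,
    shared_up: int, shared_down: int,
) -> float:
    """Shared DEGs as a percentage of the DEG union, from Venn counts."""
    if shared_up > min(tx_up, tl_up) or shared_down > min(tx_down, tl_down):
        raise ValueError("shared counts exceed their set sizes")
    union = tx_up + tx_down + tl_up + tl_down - shared_up - shared_down
    if union < 0:
        raise ValueError("negative DEG union")
    if union == 0:
        return 0.0
    return 100.0 * (shared_up + shared_down) / union


def shared_deg_stats_from_sets(
    tx_up: set, tx_down: set, tl_up: set, tl_down: set
) -> float:
    """Set-based entry point for the same statistic.

    Sharing is direction-matched (up at both levels, or down at both);
    the denominator is the union of the up-regulated Venn plus the union
    of the down-regulated Venn, matching the count-based formula.
    """
    n_shared = len(tx_up & tl_up) + len(tx_down & tl_down)
    union = len(tx_up | tl_up) + len(tx_down | tl_down)
    if union == 0:
        return 0.0
    return 100.0 * n_shared / union


def fold_change_correlation(
    tx_log2fc: Sequence[float], tl_log2fc: Sequence[float]
) -> float:
    """Pearson R^2 between the two levels' log2 fold changes."""
    x = np.asarray(tx_log2fc, dtype=float)
    y = np.asarray(tl_log2fc, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the fold-change vectors")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def quadrant_summary(
    labels: pd.DataFrame,
    tx_log2fc: Mapping[str, float] | None = None,
    tl_log2fc: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Full summary: fractions, shared-DEG percentage and fold-change R^2."""
    out = quadrant_fractions(labels)
    tx_up = set(labels.index[labels["tx_status"] == "up"])
    tx_down = set(labels.index[labels["tx_status"] == "down"])
    tl_up = set(labels.index[labels["tl_status"] == "up"])
    tl_down = set(labels.index[labels["tl_status"] == "down"])
    out["shared_up"] = len(tx_up & tl_up)
    out["shared_down"] = len(tx_down & tl_down)
    out["pct_shared_of_union"] = shared_deg_stats_from_sets(tx_up, tx_down, tl_up, tl_down)
    if tx_log2fc is not None and tl_log2fc is not None:
        genes = [g for g in labels.index if g in tx_log2fc and g in tl_log2fc]
        out["r_squared"] = fold_change_correlation(
            [tx_log2fc[g] for g in genes], [tl_log2fc[g] for g in genes]
        )
    return out


def plot_quadrants(
    labels: pd.DataFrame,
    tx_log2fc: Mapping[str, float],
    tl_log2fc: Mapping[str, float],
    path: str,
) -> None:
    """Scatter of tx vs tl log2 fold change, colored by quadrant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = dict(zip("ABCDEFGHI", plt.cm.tab10.colors))
    fig, ax = plt.subplots(figsize=(5, 5))
    for q, sub in labels.groupby("quadrant"):
        xs = [tx_log2fc[g] for g in sub.index if g in tx_log2fc]
        ys = [tl_log2fc[g] for g in sub.index if g in tl_log2fc]
        ax.scatter(xs, ys, s=4, label=q, color=cmap[q], alpha=0.6)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("transcriptional log2 fold change")
    ax.set_ylabel("translational log2 fold change")
    ax.legend(markerscale=3, fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
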