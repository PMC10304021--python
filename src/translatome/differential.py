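"""Differential expression and differential translational efficiency.

The DE caller is a negative-binomial Wald test in the DESeq tradition:
median-of-ratios library normalization, a method-of-moments per-gene
dispersion estimate shrunk toward a genome-wide mean-dispersion trend, and
a Wald z on the log fold change. It is not a re-implementation of any
published caller; externally computed (log2fc, p) tables can be supplied
instead via :func:`de_results_from_table`, and only the thresholding
contract downstream depends on them. Calls at each level use
|log2 fold change| >= 1 and BH FDR < 0.05.

Differential TE is tested per gene on the 2x2 table of summed normalized
counts (assay x condition) with a Pearson chi-square interaction test plus
an effect-size floor |delta log2 TE| >= 1; the construction is this
package's own (see docs/methods.md).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LFC_THRESHOLD = 1.0
ALPHA = 0.05
_PSEUDO = 0.5


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors (columns = libraries)."""
    k = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.mean(np.log(k), axis=1)  # -inf where any zero
    ok = np.isfinite(log_geo)
    if not np.any(ok):
        raise ValueError("no gene has positive counts in every library")
    ratios = np.log(k[ok]) - log_geo[ok, None]
    return np.exp(np.median(ratios, axis=0))


def _status(log2fc: np.ndarray, fdr: np.ndarray,
            lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA) -> np.ndarray:
    up = (log2fc >= lfc_threshold) & (fdr < alpha)
    down = (log2fc <= -lfc_threshold) & (fdr < alpha)
    return np.where(up, "up", np.where(down, "down", "unchanged"))


def de_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    norm_factors: np.ndarray | None = None,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    prior_df: float = 6.0,
) -> pd.DataFrame:
    """NB Wald differential test, B (treatment) vs A (control).

    ``counts_a``/``counts_b`` are genes x replicates integer DataFrames
    sharing the same index. Returns a DataFrame indexed by gene with
    base_mean, log2fc, lfc_se, pvalue, fdr and status (up/down/unchanged
    per the |log2fc| >= 1 and FDR < 0.05 contract).
    """
    if not counts_a.index.equals(counts_b.index):
        missing = set(counts_a.index) ^ set(counts_b.index)
        raise ValueError(f"gene sets differ between conditions: {sorted(missing)[:5]} ...")
    ka = counts_a.to_numpy(dtype=float)
    kb = counts_b.to_numpy(dtype=float)
    na, nb = ka.shape[1], kb.shape[1]
    all_counts = np.hstack([ka, kb])
    sf = size_factors(all_counts) if norm_factors is None else np.asarray(norm_factors, float)
    sfa, sfb = sf[:na], sf[na:]
    xa = ka / sfa
    xb = kb / sfb
    mu_a = xa.mean(axis=1)
    mu_b = xb.mean(axis=1)
    base_mean = np.hstack([xa, xb]).mean(axis=1)

    disp = _dispersions(xa, xb, base_mean, prior_df=prior_df)

    log2fc = np.log2(mu_b + _PSEUDO) - np.log2(mu_a + _PSEUDO)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_ln = (1.0 / (mu_a + _PSEUDO) + disp) / na + (1.0 / (mu_b + _PSEUDO) + disp) / nb
        se_ln = np.sqrt(var_ln)
        z = (np.log(mu_b + _PSEUDO) - np.log(mu_a + _PSEUDO)) / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.where(np.isfinite(pvalue), pvalue, 1.0)
    fdr = bh_adjust(pvalue)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "lfc_se": se_ln / math.log(2),
            "dispersion": disp,
            "pvalue": pvalue,
            "fdr": fdr,
            "status": _status(log2fc, fdr, lfc_threshold, alpha),
        },
        index=counts_a.index,
    )


def _dispersions(
    xa: np.ndarray, xb: np.ndarray, base_mean: np.ndarray, prior_df: float
) -> np.ndarray:
    """Method-of-moments NB dispersions shrunk toward a 1/mean trend.

    Per-gene: d = (pooled within-condition variance - mean) / mean^2,
    floored at 0. Trend: least-squares fit of d ~ a0 + a1/mean over genes
    with informative estimates. Shrinkage: log-space weighted average with
    residual-df weight df/(df + prior_df).
    """
    na, nb = xa.shape[1], xb.shape[1]
    df_res = max(na - 1, 0) + max(nb - 1, 0)
    mu = np.maximum(base_mean, 1e-8)
    if df_res == 0:
        return np.full(mu.shape, 0.1)
    var_a = xa.var(axis=1, ddof=1) if na > 1 else np.zeros(len(mu))
    var_b = xb.var(axis=1, ddof=1) if nb > 1 else np.zeros(len(mu))
    wa = max(na - 1, 0)
    wb = max(nb - 1, 0)
    pooled_var = (wa * var_a + wb * var_b) / df_res
    raw = (pooled_var - mu) / mu**2
    raw = np.clip(raw, 0.0, 10.0)

    informative = (mu > 1) & (raw > 0)
    if informative.sum() >= 10:
        X = np.column_stack([np.ones(informative.sum()), 1.0 / mu[informative]])
        coef, *_ = np.linalg.lstsq(X, raw[informative], rcond=None)
        a0, a1 = max(coef[0], 1e-6), max(coef[1], 0.0)
    else:
        a0, a1 = max(float(np.median(raw[raw > 0])) if np.any(raw > 0) else 0.01, 1e-6), 0.0
    trend = a0 + a1 / mu
    w = df_res / (df_res + prior_df)
    log_d = w * np.log(np.maximum(raw, 1e-8)) + (1 - w) * np.log(trend)
    return np.exp(log_d)


def de_results_from_table(
    table: pd.DataFrame, lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA
) -> pd.DataFrame:
    """Apply the thresholding contract to an externally computed DE table.

    ``table`` needs columns gene_id (or index), log2fc and pvalue; fdr is
    recomputed by BH if absent.
    """
    df = table.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    if "fdr" not in df.columns:
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    df["status"] = _status(
        df["log2fc"].to_numpy(float), df["fdr"].to_numpy(float), lfc_threshold, alpha
    )
    return df


# ---------------------------------------------------------------------------
# Differential TE
# ---------------------------------------------------------------------------

def te_change_test(
    rna_a: pd.DataFrame,
    rna_b: pd.DataFrame,
    ribo_a: pd.DataFrame,
    ribo_b: pd.DataFrame,
    delta_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    sf_rna: np.ndarray | None = None,
    sf_ribo: np.ndarray | None = None,
) -> pd.DataFrame:
    """Chi-square interaction test for TE change, B vs A, per gene.

    Libraries are normalized per assay with median-of-ratios factors and
    summed over replicates, giving a 2x2 table (assay x condition) per
    gene. delta_log2_te = log2[(ribo_b/rna_b) / (ribo_a/rna_a)].
    Significant iff FDR < ``alpha`` and |delta| >= ``delta_threshold``.
    Genes with a zero margin are excluded and flagged in the 'excluded'
    column of the returned frame.
    """
    for df in (rna_b, ribo_a, ribo_b):
        if not rna_a.index.equals(df.index):
            raise ValueError("all four count tables must share the same gene index")
    if sf_rna is None:
        sf_rna = size_factors(np.hstack([rna_a.to_numpy(float), rna_b.to_numpy(float)]))
    if sf_ribo is None:
        sf_ribo = size_factors(np.hstack([ribo_a.to_numpy(float), ribo_b.to_numpy(float)]))
    na = rna_a.shape[1]
    ra = (rna_a.to_numpy(float) / sf_rna[:na]).sum(axis=1)
    rb = (rna_b.to_numpy(float) / sf_rna[na:]).sum(axis=1)
    nb_ = ribo_a.shape[1]
    ba = (ribo_a.to_numpy(float) / sf_ribo[:nb_]).sum(axis=1)
    bb = (ribo_b.to_numpy(float) / sf_ribo[nb_:]).sum(axis=1)

    n = len(ra)
    delta = np.full(n, np.nan)
    chi2 = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    excluded = np.zeros(n, dtype=bool)
    for i in range(n):
        tab = np.array([[ba[i], bb[i]], [ra[i], rb[i]]])
        if tab.sum(axis=0).min() <= 0 or tab.sum(axis=1).min() <= 0:
            excluded[i] = True
            continue
        delta[i] = math.log2((bb[i] / rb[i]) / (ba[i] / ra[i])) if ba[i] > 0 and bb[i] > 0 else np.nan
        if not np.isfinite(delta[i]):
            excluded[i] = True
            continue
        c, p, _, _ = stats.chi2_contingency(tab, correction=False)
        chi2[i] = c
        pval[i] = p
    fdr = np.full(n, np.nan)
    tested = ~excluded
    if tested.any():
        fdr[tested] = bh_adjust(pval[tested])
    significant = tested & (fdr < alpha) & (np.abs(delta) >= delta_threshold)
    return pd.DataFrame(
        {
            "delta_log2_te": delta,
            "chi2": chi2,
            "pvalue": pval,
            "fdr": fdr,
            "significant": significant,
            "excluded": excluded,
        },
        index=rna_a.index,
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrich(
    selection: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a gene selection.

    ``term_map`` maps gene -> terms (any user-supplied annotation). Only
    background genes participate. Returns one row per term with overlap k,
    term size m, selection size n, background size N, p and BH q.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    sel = set(selection)
    if not sel <= bg:
        raise ValueError("selection must be a subset of the background")
    by_term: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene in bg:
            for t in terms:
                by_term.setdefault(t, set()).add(gene)
    rows = []
    N, n = len(bg), len(sel)
    if n:
        for term in sorted(by_term):
            genes = by_term[term]
            m = len(genes)
            k = len(genes & sel)
            p = float(stats.hypergeom.sf(k - 1, N, m, n))
            rows.append({"term_id": term, "k": k, "m": m, "n": n, "N": N, "pvalue": p})
    df = pd.DataFrame(rows, columns=["term_id", "k", "m", "n", "N", "pvalue"])
    if len(df):
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["qvalue"] = pd.Series(dtype=float)
    return df
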