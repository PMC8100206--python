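"""Transcript-level differential testing and gene-level Lancaster aggregation.

Gene Differential Expression (GDE) calls are made in three steps:

1. normalise transcript counts with median-of-ratios size factors;
2. test each transcript for a group effect with ordinary least squares on
   log2(normalized count + 1) against the shared covariate design — a
   documented, pluggable stand-in for a negative-binomial Wald test;
3. combine each gene's transcript p-values with the Lancaster method,
   weighting every transcript by its base expression (mean normalized
   count), and call GDE genes at Benjamini–Hochberg FDR < alpha.

The Lancaster statistic is ``T = sum_i Ginv(1 - p_i; shape=w_i/2, scale=2)``
with combined p ``1 - G(T; shape=sum(w_i)/2, scale=2)`` where ``G`` is the
gamma CDF. With all weights equal to 2 this reduces exactly to Fisher's
method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import TranscriptCountMatrix

log = logging.getLogger(__name__)

P_FLOOR = np.finfo(float).tiny


def normalize_counts(tcm: TranscriptCountMatrix) -> Tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Median-of-ratios normalisation.

    Size factors are the per-sample median of count ratios to the geometric
    mean, over transcripts with all-positive counts. Returns
    ``(normalized, size_factors, base_expression)`` where base_expression is
    the mean normalized count per transcript (the Lancaster weight source).
    """
    counts = tcm.counts.astype(float)
    if (counts.sum(axis=0) == 0).any():
        dead = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {dead}")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no transcript with positive counts in every sample")
    logc = np.log(counts[positive])
    log_geo = logc.mean(axis=1)
    ratios = logc.sub(log_geo, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    size_factors.name = "size_factor"
    normalized = counts.div(size_factors, axis=1)
    base_expression = normalized.mean(axis=1)
    base_expression.name = "base_expression"
    return normalized, size_factors, base_expression


def test_transcripts(normalized: pd.DataFrame, design: pd.DataFrame,
                     gene_of: pd.Series,
                     effect_column: str = "group") -> pd.DataFrame:
    """Per-transcript OLS of log2(normalized + 1) on the covariate design.

    ``effect_stat`` is the t statistic of the group column and ``p_value``
    its two-sided p. Transcripts with zero base expression are dropped
    before testing. Zero-residual (perfectly separated) fits are flagged
    ``degenerate`` with the p-value floored rather than zero.
    """
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    df_resid = n - k
    if df_resid <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    cols = [str(s) for s in design.index]
    missing = [s for s in cols if s not in normalized.columns]
    if missing:
        raise ValueError(f"samples in design but not in counts: {missing}")
    sub = normalized[cols]
    base = sub.mean(axis=1)
    keep = base > 0
    sub = sub[keep.to_numpy()]

    Y = np.log2(sub.to_numpy(dtype=float) + 1.0).T        # n x m
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                              # k x m
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df_resid
    g = design.columns.get_loc(effect_column)
    var_g = XtX_inv[g, g]
    se = np.sqrt(np.maximum(sigma2 * var_g, 0.0))
    degenerate = se <= np.sqrt(var_g) * 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[g] / se
    tstat = np.where(degenerate & (np.abs(beta[g]) <= 1e-12), 0.0, tstat)
    pvals = np.where(
        degenerate,
        np.where(np.abs(beta[g]) > 1e-12, P_FLOOR, 1.0),
        2.0 * stats.t.sf(np.abs(np.where(degenerate, 0.0, tstat)), df_resid),
    )
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    tstat = np.where(np.isfinite(tstat), tstat,
                     np.sign(beta[g]) * np.inf)

    out = pd.DataFrame({
        "transcript_id": sub.index,
        "gene_id": gene_of.reindex(sub.index).to_numpy(),
        "base_expression": base[keep].to_numpy(),
        "effect_stat": tstat,
        "p_value": pvals,
        "degenerate": degenerate,
    }).set_index("transcript_id")
    return out


def lancaster_statistic(p_values: Sequence[float], weights: Sequence[float],
                        weight_floor: float = 0.0) -> Tuple[float, float]:
    """Weighted Lancaster combination; returns ``(T, combined_p)``.

    Entries with weight <= ``weight_floor`` are excluded (near-zero weights
    destabilise the gamma transform). p = 0 inputs are clamped to the
    smallest positive float with a warning. A single retained entry is
    returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if p.shape != w.shape:
        raise ValueError("p_values and weights must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    keep = w > weight_floor
    if not keep.any():
        raise ValueError("all weights at or below the floor; aggregation undefined")
    p, w = p[keep], w[keep]
    if np.any(p == 0):
        log.warning("p=0 input clamped to smallest positive float")
        p = np.maximum(p, P_FLOOR)
    # Ginv(1-p; w/2, scale 2) computed via the survival inverse for accuracy
    t = float(np.sum(stats.gamma.isf(p, a=w / 2.0, scale=2.0)))
    combined = float(np.clip(stats.gamma.sf(t, a=float(np.sum(w)) / 2.0, scale=2.0),
                             0.0, 1.0))
    return t, combined


def lancaster_aggregate(p_values: Sequence[float], weights: Sequence[float],
                        weight_floor: float = 0.0) -> float:
    """Combined Lancaster p-value (see :func:`lancaster_statistic`)."""
    return lancaster_statistic(p_values, weights, weight_floor)[1]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def aggregate_genes(transcript_results: pd.DataFrame, alpha: float = 0.05,
                    weight_floor: float = 1.0) -> pd.DataFrame:
    """Lancaster-aggregate transcript p-values to gene level and call GDEs.

    Genes whose transcripts all fall below the weight floor are dropped
    (logged); q-values are BH-adjusted across the aggregated genes and
    ``is_gde`` uses the strict inequality q < alpha.
    """
    rows = []
    skipped = 0
    for gene_id, grp in transcript_results.groupby("gene_id", sort=True):
        try:
            t, combined = lancaster_statistic(grp["p_value"].to_numpy(),
                                              grp["base_expression"].to_numpy(),
                                              weight_floor=weight_floor)
        except ValueError:
            skipped += 1
            continue
        rows.append({"gene_id": gene_id, "n_transcripts": int(len(grp)),
                     "lancaster_T": t, "p_value": combined})
    if skipped:
        log.info("dropped %d genes with all transcript weights below the floor", skipped)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["gene_id", "n_transcripts", "lancaster_T",
                                     "p_value", "q_value", "is_gde"])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["is_gde"] = out["q_value"] < alpha
    return out.set_index("gene_id")


def call_gde(gene_results: pd.DataFrame, alpha: float = 0.05) -> Set[str]:
    """GDE genes: FDR-adjusted p strictly below alpha."""
    if gene_results.empty:
        return set()
    return set(gene_results.index[gene_results["q_value"] < alpha])


def filter_allosome_genes(tcm: TranscriptCountMatrix, genes: Iterable,
                          allosomes: Sequence[str]) -> TranscriptCountMatrix:
    """Remove transcripts of genes on sex chromosomes before any testing."""
    bad = {g.gene_id for g in genes if g.chrom in set(allosomes)}
    if bad:
        log.info("removed %d allosome genes before expression testing", len(bad))
    return tcm.drop_genes(bad)
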