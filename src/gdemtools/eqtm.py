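"""Expression quantitative trait methylation (eQTM) analysis.

For every gene that is both differentially expressed and carries an
annotated DMR, the region's per-sample median percentage methylation is
correlated (Pearson) with the transcript's log2-transformed normalized
expression. Uncertainty is quantified two ways:

* a 95% percentile bootstrap confidence interval — samples are redrawn
  with replacement ``n_bootstrap`` times and the correlation recomputed;
* a permutation p-value from a consecutive-CpG window null —
  ``n_permutation`` windows of the same number of consecutive CpGs as the
  observed DMR are drawn from the genome-wide CpG table, each window's
  median methylation is correlated with the same expression vector, and
  the p-value is the proportion of window correlations at least as
  extreme as the observed one (two-sided on |r| by default).

The window null preserves local CpG spacing and coverage structure, which
an independent-shuffle null would destroy.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import EqtmConfig
from .containers import DmrRecord, MethylationMatrix

log = logging.getLogger(__name__)


def median_methylation(dmr: DmrRecord | Tuple[str, int, int],
                       meth: MethylationMatrix,
                       min_coverage: int = 1) -> Tuple[np.ndarray, int]:
    """Per-sample median % methylation over a DMR's constituent CpGs.

    Returns ``(vector, L)`` where ``L`` is the number of CpG positions in
    the region. Samples with no covered CpG in the region get NaN; the
    caller drops such pairs downstream (logged).
    """
    if isinstance(dmr, DmrRecord):
        chrom, start, end = dmr.chrom, dmr.start, dmr.end
    else:
        chrom, start, end = dmr
    mask = meth.region_mask(chrom, start, end)
    L = int(mask.sum())
    if L == 0:
        raise ValueError(f"no CpGs inside {chrom}:{start}-{end}")
    pct = meth.pct(min_coverage)[mask]
    with np.errstate(all="ignore"):
        med = np.nanmedian(pct, axis=0)
    return med, L


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on short or constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant vector: Pearson r undefined")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of X (m x n, may contain NaN) against y.

    ``y`` is either a shared vector (n,) or per-row vectors (m x n). NaN
    entries are excluded pairwise per row; rows with fewer than 3 valid
    pairs or zero variance yield NaN.
    """
    Y = y[None, :] if y.ndim == 1 else y
    valid = np.isfinite(X) & np.isfinite(Y)
    nx = valid.sum(axis=1).astype(float)
    Xf = np.where(valid, X, 0.0)
    Yf = np.where(valid, Y, 0.0)
    with np.errstate(all="ignore"):
        mx = Xf.sum(axis=1) / nx
        my = Yf.sum(axis=1) / nx
        dx = np.where(valid, X - mx[:, None], 0.0)
        dy = np.where(valid, Y - my[:, None], 0.0)
        sxy = np.einsum("ij,ij->i", dx, dy)
        sxx = np.einsum("ij,ij->i", dx, dx)
        syy = np.einsum("ij,ij->i", dy, dy)
        r = sxy / np.sqrt(sxx * syy)
    r[(nx < 3) | (sxx <= 0) | (syy <= 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def eqtm_pair(mvec: np.ndarray, expr: np.ndarray) -> Tuple[float, int]:
    """Point-estimate correlation for one DMR x transcript pair.

    Pairs where the methylation value is missing are dropped (count
    returned). ``expr`` is expected on the log2(normalized + pseudocount)
    scale, aligned to the same samples as ``mvec``.
    """
    mvec = np.asarray(mvec, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = np.isfinite(mvec) & np.isfinite(expr)
    dropped = int(len(mvec) - ok.sum())
    if dropped:
        log.info("eqtm_pair: dropped %d samples with missing values", dropped)
    return pearson_r(mvec[ok], expr[ok]), dropped


def bootstrap_ci(mvec: Sequence[float], expr: Sequence[float],
                 cfg: EqtmConfig,
                 rng: Optional[np.random.Generator] = None) -> Tuple[float, float]:
    """Percentile bootstrap CI for the Pearson correlation.

    Samples are redrawn with replacement ``cfg.n_bootstrap`` times;
    degenerate resamples (either vector constant) are discarded and
    redrawn. If more than half of the draws are degenerate the data are
    pathological and an error is raised.
    """
    x = np.asarray(mvec, dtype=float)
    y = np.asarray(expr, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs for the bootstrap")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    B = cfg.n_bootstrap

    def draw(k: int) -> np.ndarray:
        idx = rng.integers(0, n, size=(k, n))
        return _pearson_rows(x[idx], y[idx])

    r = draw(B)
    degenerate_first = int(np.sum(~np.isfinite(r)))
    if degenerate_first > B / 2:
        raise ValueError("more than half of bootstrap resamples degenerate")
    rounds = 0
    while np.any(~np.isfinite(r)) and rounds < 100:
        bad = ~np.isfinite(r)
        r[bad] = draw(int(bad.sum()))
        rounds += 1
    r = r[np.isfinite(r)]
    tail = 100.0 * (1.0 - cfg.ci_level) / 2.0
    lo, hi = np.percentile(r, [tail, 100.0 - tail])
    return float(lo), float(hi)


class WindowNull:
    """Permutation null over consecutive-CpG windows.

    Precomputes the %-methylation matrix once so many pairs can be tested
    against the same CpG universe cheaply. Allosome CpGs should be removed
    from ``meth`` before construction.
    """

    def __init__(self, meth: MethylationMatrix, min_coverage: int = 1):
        self.meth = meth
        self.pct = meth.pct(min_coverage)
        self.chrom = meth.chrom.astype(str)
        self.pos = meth.pos

    def valid_starts(self, L: int,
                     exclude: Optional[Tuple[str, int, int]] = None) -> np.ndarray:
        """Start indices of windows of L consecutive CpGs wholly on one
        chromosome, not overlapping the excluded interval."""
        n = len(self.pos)
        if L < 2 or L > n:
            raise ValueError(f"window length {L} out of range")
        starts = np.arange(n - L + 1)
        same_chrom = self.chrom[starts] == self.chrom[starts + L - 1]
        keep = same_chrom
        if exclude is not None:
            chrom, s, e = exclude
            w_start = self.pos[starts]
            w_end = self.pos[starts + L - 1]
            overlaps = (self.chrom[starts] == chrom) & (w_start <= e) & (w_end >= s)
            keep = keep & ~overlaps
        return starts[keep]

    def window_correlations(self, starts: np.ndarray, L: int,
                            expr: np.ndarray) -> np.ndarray:
        gather = starts[:, None] + np.arange(L)[None, :]
        block = self.pct[gather]                        # (B, L, n_samples)
        with np.errstate(all="ignore"):
            med = np.nanmedian(block, axis=1)           # (B, n_samples)
        return _pearson_rows(med, np.asarray(expr, dtype=float))

    def p_value(self, observed_r: float, L: int, expr: Sequence[float],
                cfg: EqtmConfig, rng: Optional[np.random.Generator] = None,
                exclude: Optional[Tuple[str, int, int]] = None) -> float:
        """Proportion of null windows at least as extreme as observed_r."""
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        starts = self.valid_starts(L, exclude)
        if len(starts) == 0:
            raise ValueError("no valid window positions for the permutation null")
        if len(starts) < cfg.n_permutation:
            log.warning("only %d valid windows for L=%d; sampling with replacement",
                        len(starts), L)
            chosen = rng.choice(starts, size=cfg.n_permutation, replace=True)
        else:
            chosen = rng.choice(starts, size=cfg.n_permutation, replace=False)
        r_null = self.window_correlations(chosen, L, np.asarray(expr, dtype=float))
        r_null = r_null[np.isfinite(r_null)]
        if cfg.tail == "greater":
            exceed = int(np.sum(r_null >= observed_r))
        else:
            exceed = int(np.sum(np.abs(r_null) >= abs(observed_r)))
        return exceed / cfg.n_permutation


def permutation_p(observed_r: float, dmr_L: int, meth: MethylationMatrix,
                  expr_vector: Sequence[float], cfg: EqtmConfig,
                  rng: Optional[np.random.Generator] = None,
                  exclude: Optional[Tuple[str, int, int]] = None) -> float:
    """One-shot convenience wrapper around :class:`WindowNull`."""
    null = WindowNull(meth, cfg.min_cpg_coverage)
    return null.p_value(observed_r, dmr_L, expr_vector, cfg, rng, exclude)


def eqtm_analysis(pairs: Iterable[Tuple[str, DmrRecord, str]],
                  meth: MethylationMatrix,
                  log2_expr: pd.DataFrame,
                  cfg: EqtmConfig,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Full eQTM table for (gene, DMR, transcript) triples.

    ``log2_expr`` is transcript x sample on the log2(normalized +
    pseudocount) scale with columns matching ``meth.samples``. Pairs with
    undefined correlations (constant vectors) are skipped with a log line.
    One row per triple, mirroring the published table layout: point
    estimate, 95% percentile-bootstrap CI, window-permutation p, and the
    window length L.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    null = WindowNull(meth, cfg.min_cpg_coverage)
    expr_cols = [str(c) for c in log2_expr.columns]
    if expr_cols != list(meth.samples):
        raise ValueError("expression and methylation sample order differ")
    rows = []
    for gene_id, dmr, transcript_id in pairs:
        expr = log2_expr.loc[transcript_id].to_numpy(dtype=float)
        try:
            mvec, L = median_methylation(dmr, meth, cfg.min_cpg_coverage)
            r, _ = eqtm_pair(mvec, expr)
            ci_lo, ci_hi = bootstrap_ci(mvec, expr, cfg, rng)
            pp = null.p_value(r, L, expr, cfg, rng,
                              exclude=(dmr.chrom, dmr.start, dmr.end))
        except ValueError as err:
            log.warning("eQTM skipped for %s / %s / %s: %s",
                        gene_id, dmr.interval, transcript_id, err)
            continue
        rows.append({
            "gene_id": gene_id, "dmr": dmr.interval, "transcript_id": transcript_id,
            "L": L, "r": r, "ci_low": ci_lo, "ci_high": ci_hi, "perm_p": pp,
            "perm_p_display": (f"< {1.0 / cfg.n_permutation:g}" if pp == 0.0
                               else f"{pp:g}"),
        })
    return pd.DataFrame(rows, columns=["gene_id", "dmr", "transcript_id", "L",
                                       "r", "ci_low", "ci_high", "perm_p",
                                       "perm_p_display"])
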