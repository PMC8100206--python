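"""In-memory containers for the pipeline's genomic matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class MethylationMatrix:
    """Per-CpG, per-sample methylated/total read counts.

    Rows are CpG sites with 1-based genomic positions, sorted by
    (chromosome, position); columns are samples. ``meth[i, j] <= total[i, j]``
    always holds. This is the substrate for regional median methylation and
    for the consecutive-CpG window permutation null.
    """

    chrom: np.ndarray          # (n_cpg,) str
    pos: np.ndarray            # (n_cpg,) int64, 1-based
    meth: np.ndarray           # (n_cpg, n_samples) int64
    total: np.ndarray          # (n_cpg, n_samples) int64
    samples: List[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total shapes differ")
        if self.meth.shape != (len(self.pos), len(self.samples)):
            raise ValueError("count matrix shape inconsistent with sites/samples")
        if np.any(self.meth > self.total) or np.any(self.meth < 0):
            raise ValueError("require 0 <= methylated <= total")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.meth = self.meth[order]
            self.total = self.total[order]

    @property
    def n_cpgs(self) -> int:
        return len(self.pos)

    def pct(self, min_coverage: int = 1) -> np.ndarray:
        """Percent methylation per CpG x sample; NaN where coverage is short."""
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 100.0 * self.meth / self.total
        p[self.total < max(min_coverage, 1)] = np.nan
        return p

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of CpGs inside a 1-based inclusive interval."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)

    def subset_samples(self, keep: Sequence[str]) -> "MethylationMatrix":
        idx = [self.samples.index(s) for s in keep]
        return MethylationMatrix(self.chrom.copy(), self.pos.copy(),
                                 self.meth[:, idx], self.total[:, idx],
                                 list(keep))

    def drop_chroms(self, names: Iterable[str]) -> "MethylationMatrix":
        drop = set(names)
        keep = ~np.isin(self.chrom.astype(str), list(drop))
        return MethylationMatrix(self.chrom[keep], self.pos[keep],
                                 self.meth[keep], self.total[keep],
                                 list(self.samples))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationMatrix):
            return NotImplemented
        return (self.samples == other.samples
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.meth, other.meth)
                and np.array_equal(self.total, other.total))


@dataclass
class TranscriptCountMatrix:
    """Transcript x sample non-negative integer counts with a gene map."""

    counts: pd.DataFrame       # index transcript_id, columns sample ids
    gene_of: pd.Series         # index transcript_id -> gene_id

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_of.index):
            self.gene_of = self.gene_of.reindex(self.counts.index)
        if self.gene_of.isna().any():
            raise ValueError("every transcript needs a gene_id")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def subset_samples(self, keep: Sequence[str]) -> "TranscriptCountMatrix":
        return TranscriptCountMatrix(self.counts[list(keep)].copy(), self.gene_of.copy())

    def drop_genes(self, gene_ids: Iterable[str]) -> "TranscriptCountMatrix":
        bad = set(gene_ids)
        keep = ~self.gene_of.isin(bad)
        return TranscriptCountMatrix(self.counts[keep.to_numpy()].copy(),
                                     self.gene_of[keep].copy())


@dataclass(frozen=True)
class GeneModel:
    """One gene with its transcripts, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    strand: str                # "+" or "-"
    start: int
    end: int
    transcripts: Tuple[Tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError("gene start > end")
        for _, ts, te in self.transcripts:
            if ts < self.start or te > self.end:
                raise ValueError("transcript outside gene bounds")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class DmrRecord:
    """A called differentially methylated region, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str
    stat: float                # signed region statistic (z-like)
    p_value: float
    direction: str             # "hyper" | "hypo"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("DMR start > end")
        expected = "hyper" if self.stat >= 0 else "hypo"
        if self.direction != expected:
            raise ValueError("direction inconsistent with sign of stat")

    @property
    def interval(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2
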