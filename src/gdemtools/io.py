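"""Readers and writers for the pipeline's on-disk formats.

Dialects:

* Bismark-style coverage files ``<sample>.cov``: tab-separated
  chrom, position, position, %methylation, count_methylated,
  count_unmethylated — positions 1-based.
* GENCODE-dialect GTF for gene models (``gene_id``/``transcript_id``
  attributes; 1-based inclusive).
* BED6+2 DMR calls: chrom, start (0-based half-open), end, name, stat,
  strand ".", p_value, direction. Converted to 1-based inclusive exactly
  once on read.
* counts.tsv: transcript_id, gene_id, then one column per sample.

Coordinate conversions happen only here, at the boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .containers import DmrRecord, GeneModel, MethylationMatrix, TranscriptCountMatrix

log = logging.getLogger(__name__)


def _fail(path, lineno: int, msg: str) -> None:
    raise ValueError(f"{path}:{lineno}: {msg}")


# -- Bismark coverage -------------------------------------------------------

def read_bismark_cov(path) -> pd.DataFrame:
    """One sample's coverage file -> DataFrame(chrom, pos, meth, unmeth)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                _fail(path, lineno, f"expected 6 columns, got {len(parts)}")
            chrom, start, end, _pct, n_meth, n_unmeth = parts
            try:
                start_i, end_i = int(start), int(end)
                m, u = int(n_meth), int(n_unmeth)
            except ValueError:
                _fail(path, lineno, "non-integer coordinate or count")
            if start_i != end_i:
                _fail(path, lineno, "coverage records are single positions")
            rows.append((chrom, start_i, m, u))
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])


def read_coverage_dir(directory, samples: Sequence[str]) -> MethylationMatrix:
    """Assemble a MethylationMatrix from per-sample ``<sample>.cov`` files.

    The CpG universe is the union of positions across samples; a position
    absent from a sample's file gets zero coverage there.
    """
    directory = Path(directory)
    frames: Dict[str, pd.DataFrame] = {}
    for s in samples:
        p = directory / f"{s}.cov"
        if not p.exists():
            raise FileNotFoundError(f"coverage file missing: {p}")
        frames[s] = read_bismark_cov(p).set_index(["chrom", "pos"])
    universe = sorted(set().union(*(set(f.index) for f in frames.values())))
    idx = pd.MultiIndex.from_tuples(universe, names=["chrom", "pos"])
    n = len(idx)
    meth = np.zeros((n, len(samples)), dtype=np.int64)
    total = np.zeros((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        f = frames[s].reindex(idx)
        m = f["meth"].fillna(0).to_numpy(dtype=np.int64)
        u = f["unmeth"].fillna(0).to_numpy(dtype=np.int64)
        meth[:, j] = m
        total[:, j] = m + u
    chrom = np.array([c for c, _ in universe], dtype=object)
    pos = np.array([p for _, p in universe], dtype=np.int64)
    return MethylationMatrix(chrom, pos, meth, total, list(samples))


def write_coverage_dir(meth: MethylationMatrix, directory) -> List[Path]:
    """Write one Bismark-style coverage file per sample.

    Zero-coverage positions are omitted from a sample's file, matching
    how aligners report coverage.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, s in enumerate(meth.samples):
        p = directory / f"{s}.cov"
        with open(p, "w") as fh:
            for i in range(meth.n_cpgs):
                t = meth.total[i, j]
                if t == 0:
                    continue
                m = meth.meth[i, j]
                pct = 100.0 * m / t
                fh.write(f"{meth.chrom[i]}\t{meth.pos[i]}\t{meth.pos[i]}\t"
                         f"{pct:.6g}\t{m}\t{t - m}\n")
        paths.append(p)
    return paths


# -- GTF --------------------------------------------------------------------

def _parse_attributes(field: str) -> Dict[str, str]:
    attrs = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> List[GeneModel]:
    """Parse a GENCODE-dialect GTF into gene models."""
    genes: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                _fail(path, lineno, f"expected 9 GTF columns, got {len(parts)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            attrs = _parse_attributes(attr)
            if "gene_id" not in attrs:
                _fail(path, lineno, "missing gene_id attribute")
            gid = attrs["gene_id"]
            if feature == "gene":
                genes[gid] = {"chrom": chrom, "strand": strand,
                              "start": start_i, "end": end_i,
                              "transcripts": genes.get(gid, {}).get("transcripts", [])}
            elif feature == "transcript":
                if "transcript_id" not in attrs:
                    _fail(path, lineno, "transcript without transcript_id")
                genes.setdefault(gid, {"chrom": chrom, "strand": strand,
                                       "start": start_i, "end": end_i,
                                       "transcripts": []})
                genes[gid]["transcripts"].append(
                    (attrs["transcript_id"], start_i, end_i))
    return [GeneModel(gid, g["chrom"], g["strand"], g["start"], g["end"],
                      tuple(sorted(g["transcripts"])))
            for gid, g in sorted(genes.items())]


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\tgdemtools\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n")
            for tid, ts, te in g.transcripts:
                fh.write(f"{g.chrom}\tgdemtools\ttranscript\t{ts}\t{te}\t.\t"
                         f"{g.strand}\t.\tgene_id \"{g.gene_id}\"; "
                         f"transcript_id \"{tid}\";\n")


# -- DMR BED ----------------------------------------------------------------

def read_bed_dmrs(path) -> List[DmrRecord]:
    """BED6+2 DMR calls; 0-based half-open converted to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                _fail(path, lineno, f"expected >= 8 columns, got {len(parts)}")
            chrom, start0, end, name, stat, _strand, p_value, direction = parts[:8]
            try:
                rec = DmrRecord(chrom, int(start0) + 1, int(end), name,
                                float(stat), float(p_value), direction)
            except ValueError as err:
                _fail(path, lineno, str(err))
            out.append(rec)
    return out


def write_bed_dmrs(dmrs: Sequence[DmrRecord], path) -> None:
    with open(path, "w") as fh:
        for d in dmrs:
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.name}\t"
                     f"{d.stat:.6g}\t.\t{d.p_value:.6g}\t{d.direction}\n")


# -- counts -----------------------------------------------------------------

def read_counts_tsv(path) -> TranscriptCountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("transcript_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: counts table missing {col} column")
    df = df.set_index("transcript_id")
    gene_of = df.pop("gene_id")
    counts = df.astype(np.int64)
    return TranscriptCountMatrix(counts, gene_of)


def write_counts_tsv(tcm: TranscriptCountMatrix, path) -> None:
    out = tcm.counts.copy()
    out.insert(0, "gene_id", tcm.gene_of)
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


# -- result tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path, seed: Optional[int] = None,
                config_hash: Optional[str] = None,
                index: bool = False) -> None:
    """Write a result table with a provenance comment line."""
    prov = f"# gdemtools v{__version__}"
    if seed is not None:
        prov += f" seed={seed}"
    if config_hash is not None:
        prov += f" config={config_hash}"
    with open(path, "w") as fh:
        fh.write(prov + "\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
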