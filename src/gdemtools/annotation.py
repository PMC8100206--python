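"""Assign DMRs to genes with the strand-aware promoter-window rule.

A DMR is linked to a gene when it overlaps, by at least one base, the
window extending 5,000 bp upstream and 1,000 bp downstream of the gene —
where "upstream" is leftward for + genes and rightward for - genes. All
qualifying genes are reported (no nearest-gene collapsing), so a DMR may
link to several genes and a gene to several DMRs.

``annotate_dmrs`` uses an interval tree; ``brute_force_annotate`` is the
O(n*m) pairwise oracle with identical semantics, kept for testing.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

from intervaltree import IntervalTree

from .config import AnnotationConfig
from .containers import DmrRecord, GeneModel

log = logging.getLogger(__name__)

Link = Tuple[DmrRecord, GeneModel]


def gene_window(gene: GeneModel, cfg: AnnotationConfig) -> Tuple[int, int]:
    """Strand-aware eligible window, 1-based inclusive.

    With the default body anchor, a + strand gene [s, e] yields
    [s - upstream, e + downstream]; a - strand gene yields
    [s - downstream, e + upstream]. With ``anchor="tss"`` the window is
    taken around the transcription start site alone.
    """
    if cfg.anchor == "tss":
        lo = hi = gene.tss
    else:
        lo, hi = gene.start, gene.end
    if gene.strand == "+":
        return lo - cfg.upstream_bp, hi + cfg.downstream_bp
    return lo - cfg.downstream_bp, hi + cfg.upstream_bp


def _qualifies(dmr: DmrRecord, window: Tuple[int, int],
               cfg: AnnotationConfig) -> bool:
    lo, hi = window
    if cfg.require_midpoint:
        return lo <= dmr.midpoint <= hi
    return dmr.start <= hi and dmr.end >= lo


def annotate_dmrs(dmrs: Sequence[DmrRecord], genes: Sequence[GeneModel],
                  cfg: AnnotationConfig | None = None) -> List[Link]:
    """Link DMRs to genes whose promoter window they overlap.

    Returns (dmr, gene) pairs in input DMR order (duplicate DMR records
    yield duplicate links). DMRs on chromosomes absent from the gene set
    are left unannotated with a warning.
    """
    cfg = cfg or AnnotationConfig()
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        lo, hi = gene_window(gene, cfg)
        # intervaltree is half-open; +1 makes [lo, hi] inclusive
        trees.setdefault(gene.chrom, IntervalTree()).addi(lo, hi + 1, gene)

    links: List[Link] = []
    orphan_chroms = set()
    for dmr in dmrs:
        tree = trees.get(dmr.chrom)
        if tree is None:
            orphan_chroms.add(dmr.chrom)
            continue
        if cfg.require_midpoint:
            hits = tree.at(dmr.midpoint)
        else:
            hits = tree.overlap(dmr.start, dmr.end + 1)
        for iv in sorted(hits, key=lambda iv: iv.data.gene_id):
            links.append((dmr, iv.data))
    if orphan_chroms:
        log.warning("DMR chromosomes absent from gene models: %s",
                    sorted(orphan_chroms))
    return links


def brute_force_annotate(dmrs: Sequence[DmrRecord], genes: Sequence[GeneModel],
                         cfg: AnnotationConfig | None = None) -> List[Link]:
    """O(n*m) pairwise oracle with semantics identical to annotate_dmrs."""
    cfg = cfg or AnnotationConfig()
    links: List[Link] = []
    for dmr in dmrs:
        for gene in sorted(genes, key=lambda g: g.gene_id):
            if gene.chrom != dmr.chrom:
                continue
            if _qualifies(dmr, gene_window(gene, cfg), cfg):
                links.append((dmr, gene))
    return links


def drop_allosome_dmrs(dmrs: Sequence[DmrRecord],
                       allosomes: Sequence[str]) -> List[DmrRecord]:
    """Remove DMRs on sex chromosomes before annotation."""
    bad = set(allosomes)
    kept = [d for d in dmrs if d.chrom not in bad]
    if len(kept) < len(dmrs):
        log.info("removed %d allosome DMRs", len(dmrs) - len(kept))
    return kept
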