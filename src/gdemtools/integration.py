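"""Intersect GDE genes with DMR-linked genes into GDEMs and classify
transcript-direction concordance.

A GDEM (gene displaying both differential expression and methylation) is
a gene that passes the gene-level expression FDR call AND has at least one
DMR linked to it by the promoter-window rule. For each GDEM the signs of
its individually significant transcripts decide concordance: if both
positive and negative effect statistics appear among significant
transcripts, the gene's transcripts run in opposite directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .containers import DmrRecord

log = logging.getLogger(__name__)

CONCORDANT = "concordant"
OPPOSITE = "opposite"


@dataclass
class GdemRecord:
    gene_id: str
    linked_dmrs: List[DmrRecord]
    # (transcript_id, effect_stat, p_value, is_significant)
    transcript_stats: List[Tuple[str, float, float, bool]]
    concordance: str = CONCORDANT
    no_significant_transcript: bool = False


def intersect_gdem(gde_genes: Set[str],
                   dmr_gene_links: Sequence[Tuple[DmrRecord, object]]) -> Dict[str, List[DmrRecord]]:
    """Genes in both the GDE set and the DMR-linked set, with their DMRs.

    Duplicate (DMR, gene) links are de-duplicated by DMR interval per gene
    (repeated reporting rows collapse to one), with a log line. The run
    log reports the unique-DMR and unique-gene counts of the intersection.
    """
    by_gene: Dict[str, List[DmrRecord]] = {}
    seen = set()
    dupes = 0
    for dmr, gene in dmr_gene_links:
        gid = getattr(gene, "gene_id", gene)
        if gid not in gde_genes:
            continue
        key = (gid, dmr.chrom, dmr.start, dmr.end)
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        by_gene.setdefault(gid, []).append(dmr)
    if dupes:
        log.info("collapsed %d duplicate DMR-gene links", dupes)
    uniq_dmrs = {(d.chrom, d.start, d.end) for ds in by_gene.values() for d in ds}
    log.info("GDEM intersection: %d unique DMRs across %d unique genes",
             len(uniq_dmrs), len(by_gene))
    return by_gene


def classify_concordance(transcript_stats: Sequence[Tuple[str, float, float, bool]]
                         ) -> Tuple[str, bool]:
    """Concordance verdict from the significant transcripts' signs.

    Only transcripts flagged significant vote. Returns (verdict, flag)
    where flag marks genes with no significant transcript (classified
    concordant by convention, flagged for the caller).
    """
    signs = {1 if stat > 0 else -1
             for _, stat, _, sig in transcript_stats if sig and stat != 0}
    if not signs:
        return CONCORDANT, True
    return (OPPOSITE if len(signs) == 2 else CONCORDANT), False


def build_gdem_records(gde_genes: Set[str],
                       dmr_gene_links: Sequence[Tuple[DmrRecord, object]],
                       transcript_results: pd.DataFrame,
                       alpha: float = 0.05) -> List[GdemRecord]:
    """Assemble one GDEM record per intersected gene.

    Per-transcript significance is BH-adjusted across all tested
    transcripts (q < alpha, strict).
    """
    from .gde import bh_adjust

    tr = transcript_results.copy()
    tr["q_value"] = bh_adjust(tr["p_value"].to_numpy())
    tr["is_significant"] = tr["q_value"] < alpha

    by_gene = intersect_gdem(gde_genes, dmr_gene_links)
    records: List[GdemRecord] = []
    for gene_id in sorted(by_gene):
        sub = tr[tr["gene_id"] == gene_id]
        stats = [(tid, float(row["effect_stat"]), float(row["p_value"]),
                  bool(row["is_significant"]))
                 for tid, row in sub.iterrows()]
        verdict, flagged = classify_concordance(stats)
        records.append(GdemRecord(gene_id, by_gene[gene_id], stats, verdict,
                                  flagged))
    return records


def gdem_table(records: Iterable[GdemRecord],
               gene_results: pd.DataFrame) -> pd.DataFrame:
    """Long-form GDEM table: one row per gene x DMR x transcript."""
    rows = []
    for rec in records:
        gde_p = (float(gene_results.loc[rec.gene_id, "p_value"])
                 if rec.gene_id in gene_results.index else float("nan"))
        for dmr in rec.linked_dmrs:
            for tid, stat, p, sig in rec.transcript_stats:
                rows.append({
                    "gene_id": rec.gene_id, "gde_p_value": gde_p,
                    "dmr": dmr.interval, "dmr_stat": dmr.stat,
                    "dmr_p_value": dmr.p_value, "transcript_id": tid,
                    "dte_stat": stat, "dte_p_value": p,
                    "dte_significant": sig, "concordance": rec.concordance,
                })
    return pd.DataFrame(rows, columns=["gene_id", "gde_p_value", "dmr",
                                       "dmr_stat", "dmr_p_value",
                                       "transcript_id", "dte_stat",
                                       "dte_p_value", "dte_significant",
                                       "concordance"])
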