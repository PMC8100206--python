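"""End-to-end runner: stratify -> GDE -> annotate -> intersect -> eQTM.

All thresholds come from :class:`~gdemtools.config.PipelineConfig`. Every
result table carries a provenance comment line (tool version, seed,
config hash); identical config + seed gives byte-identical outputs.
Tables are only written once every stage has succeeded, so a failing
stage leaves no partial outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import annotation, cohort, eqtm, gde, integration
from . import io as gio
from .config import PipelineConfig, stage_seed
from .containers import MethylationMatrix, TranscriptCountMatrix
from .simulate import SimulatedStudy

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    samples: pd.DataFrame
    design: pd.DataFrame
    transcript_results: pd.DataFrame
    gene_results: pd.DataFrame
    gde_genes: set
    links: list
    gdem_records: list
    gdem_table: pd.DataFrame
    eqtm_table: pd.DataFrame
    log_lines: List[str] = field(default_factory=list)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(name, str(err)) from err


def run_pipeline_objects(samples: pd.DataFrame, counts: TranscriptCountMatrix,
                         genes: list, dmrs: list, meth: MethylationMatrix,
                         cfg: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run every stage on in-memory inputs."""
    cfg = cfg or PipelineConfig()
    lines: List[str] = []

    def note(stage: str, msg: str) -> None:
        line = f"{stage}: {msg}"
        lines.append(line)
        log.info(line)

    t0 = time.perf_counter()

    # stratify
    labeled = _stage("stratify", cohort.dichotomize_sjc66, samples,
                     cfg.sjc66_high_min, cfg.sjc66_low_max)
    kept = cohort.retained(labeled)
    note("stratify", f"{len(labeled)} samples; "
         f"high={int((kept['group'] == 'high').sum())}, "
         f"low={int((kept['group'] == 'low').sum())}, "
         f"excluded={len(labeled) - len(kept)}")
    design = _stage("stratify", cohort.build_design, labeled)
    kept_ids = [str(s) for s in design.index]

    # allosome removal, then expression testing
    n_before = len(counts.counts)
    counts_f = _stage("gde", gde.filter_allosome_genes, counts, genes,
                      cfg.allosomes)
    note("gde", f"allosome filter removed {n_before - len(counts_f.counts)} transcripts")
    counts_r = counts_f.subset_samples(kept_ids)
    normalized, size_factors, base_expr = _stage("gde", gde.normalize_counts,
                                                 counts_r)
    tr = _stage("gde", gde.test_transcripts, normalized, design,
                counts_r.gene_of)
    gene_results = _stage("gde", gde.aggregate_genes, tr, cfg.alpha,
                          cfg.weight_floor)
    gde_genes = gde.call_gde(gene_results, cfg.alpha)
    note("gde", f"tested {len(tr)} transcripts in {len(gene_results)} genes; "
         f"{len(gde_genes)} GDE at FDR<{cfg.alpha}; "
         f"{n_before - len(tr)} transcripts dropped (allosome or zero expression)")

    # annotation
    autosomal_genes = [g for g in genes if g.chrom not in set(cfg.allosomes)]
    dmrs_f = _stage("annotate", annotation.drop_allosome_dmrs, dmrs,
                    cfg.allosomes)
    links = _stage("annotate", annotation.annotate_dmrs, dmrs_f,
                   autosomal_genes, cfg.annotation)
    note("annotate", f"{len(links)} DMR-gene links from {len(dmrs_f)} DMRs")

    # intersection + concordance
    records = _stage("integrate", integration.build_gdem_records, gde_genes,
                     links, tr, cfg.alpha)
    table = integration.gdem_table(records, gene_results)
    uniq_dmrs = {d.interval for r in records for d in r.linked_dmrs}
    note("integrate", f"{len(uniq_dmrs)} unique DMRs across "
         f"{len(records)} unique GDEM genes")

    # eQTM on significant transcripts of each GDEM x its linked DMRs
    meth_r = meth.subset_samples(kept_ids).drop_chroms(cfg.allosomes)
    log2_expr = np.log2(normalized + cfg.eqtm.log2_pseudocount)
    pairs = []
    for rec in records:
        sig = [tid for tid, _, _, s in rec.transcript_stats if s]
        for dmr in rec.linked_dmrs:
            for tid in sig:
                pairs.append((rec.gene_id, dmr, tid))
    rng = np.random.default_rng(stage_seed(cfg.seed, "eqtm"))
    eq = _stage("eqtm", eqtm.eqtm_analysis, pairs, meth_r, log2_expr,
                cfg.eqtm, rng)
    note("eqtm", f"{len(eq)} DMR x transcript pairs analysed "
         f"({len(pairs) - len(eq)} skipped)")
    note("pipeline", f"completed in {time.perf_counter() - t0:.1f} s")

    return PipelineResult(labeled, design, tr.reset_index(),
                          gene_results.reset_index(), gde_genes, links,
                          records, table, eq, lines)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Read the five inputs from disk, run all stages, write result tables."""
    for name in ("samples_tsv", "counts_tsv", "genes_gtf", "dmrs_bed",
                 "coverage_dir"):
        p = Path(getattr(cfg, name))
        if not p.exists():
            raise PipelineError("config", f"input path missing: {name}={p}")

    samples = _stage("read", cohort.read_samples_tsv, cfg.samples_tsv)
    counts = _stage("read", gio.read_counts_tsv, cfg.counts_tsv)
    genes = _stage("read", gio.read_gtf, cfg.genes_gtf)
    dmrs = _stage("read", gio.read_bed_dmrs, cfg.dmrs_bed)
    meth = _stage("read", gio.read_coverage_dir, cfg.coverage_dir,
                  [str(s) for s in samples["sample_id"]])

    result = run_pipeline_objects(samples, counts, genes, dmrs, meth, cfg)
    write_results(result, cfg)
    return result


def write_results(result: PipelineResult, cfg: PipelineConfig) -> Dict[str, Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    written: Dict[str, Path] = {}
    try:
        for name, df, index in [
            ("transcript_results", result.transcript_results, False),
            ("gde_results", result.gene_results, False),
            ("gdem_table", result.gdem_table, False),
            ("eqtm_results", result.eqtm_table, False),
        ]:
            p = out / f"{name}.tsv"
            gio.write_table(df, p, seed=cfg.seed, config_hash=h, index=index)
            written[name] = p
        links_df = pd.DataFrame(
            [{"dmr": d.interval, "dmr_stat": d.stat, "dmr_p_value": d.p_value,
              "gene_id": g.gene_id} for d, g in result.links])
        p = out / "dmr_gene_links.tsv"
        gio.write_table(links_df, p, seed=cfg.seed, config_hash=h)
        written["dmr_gene_links"] = p
        logp = out / "run_log.txt"
        logp.write_text("\n".join(result.log_lines) + "\n")
        written["run_log"] = logp
    except Exception:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise
    return written


def run_on_study(study: SimulatedStudy,
                 cfg: Optional[PipelineConfig] = None) -> PipelineResult:
    """Convenience: run all stages directly on a simulated study."""
    return run_pipeline_objects(study.samples, study.counts, study.genes,
                                study.dmrs, study.methylome, cfg)
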