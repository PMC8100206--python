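"""Synthetic miniature study with planted, recorded truth.

Generates a complete input set for the pipeline — sample metadata, gene
models, a methylome as per-CpG read counts, transcript counts, and DMR
calls — so every downstream stage is testable without external data.

What is planted, and how:

* **Cohort** — two swollen-joint-count groups (high: SJC66 >= 9, low:
  1-8, optional zero group) with a deliberate sex confound (by default
  75% of the high group is one sex), age uniform in [25, 70] years and
  Bernoulli(0.5) DMARD use, mirroring the 17-sample study design.
* **Methylome** — baseline per-CpG methylation from a bimodal beta
  mixture; for each planted DMR a run of L consecutive CpGs injected
  near the target gene's promoter is shifted by +/- ``dmr_effect``
  percentage points in the high group, with a small per-sample random
  effect so regional methylation varies continuously. Read counts are
  Binomial(total, p) with total ~ Poisson(coverage_mean): WGBS counts
  are binomial given depth.
* **Transcripts** — negative-binomial counts around gene baselines.
  Expression-effect genes get +/- ``expr_lfc`` log2 fold change on
  designated transcripts; discordant genes get one transcript up and one
  down. For eQTM-linked pairs the latent log2 mean is coupled to the
  sample's realized median planted-DMR methylation through a Gaussian
  copula, so the target correlation magnitude ``eqtm_rho`` is
  interpretable (sign negative by default: promoter methylation up,
  expression down).

Chromosomes are named chrS1, chrS2, ... (plus the synthetic allosome
chrSX) to avoid collision with real genomes. A fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import brute_force_annotate
from .cohort import dichotomize_sjc66
from .config import AnnotationConfig, SimConfig, stage_seed
from .containers import (DmrRecord, GeneModel, MethylationMatrix,
                         TranscriptCountMatrix)
from . import io as gio

log = logging.getLogger(__name__)

ALLOSOME = "chrSX"

ROLE_GDEM = "gdem"
ROLE_GDEM_DISCORDANT = "gdem_discordant"
ROLE_GDE_ONLY = "gde_only"
ROLE_DMR_ONLY = "dmr_only"
ROLE_NULL = "null"
ROLE_ALLOSOME = "allosome"


@dataclass
class PlantedTruth:
    """Recorded ground truth of the synthetic study.

    ``genes``: per-gene role and flags (is_gde, has_dmr, is_gdem,
    concordance). ``dmrs``: planted regions with their effect sign.
    ``pairs``: planted eQTM links with signed target correlation.
    """

    genes: pd.DataFrame
    dmrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        g = self.genes
        bad = g[g["is_gdem"] & ~(g["is_gde"] & g["has_dmr"])]
        if not bad.empty:
            raise AssertionError(f"is_gdem without is_gde & has_dmr: {list(bad.index)}")
        if not self.pairs.empty:
            with_dmr = set(self.dmrs["gene_id"])
            orphan = set(self.pairs["gene_id"]) - with_dmr
            if orphan:
                raise ValueError(f"eQTM link to gene without planted DMR: {sorted(orphan)}")


@dataclass
class SimulatedStudy:
    config: SimConfig
    samples: pd.DataFrame
    genes: List[GeneModel]
    methylome: MethylationMatrix
    dmrs: List[DmrRecord]
    counts: TranscriptCountMatrix
    truth: PlantedTruth


# -- cohort -----------------------------------------------------------------

def generate_cohort(cfg: SimConfig) -> pd.DataFrame:
    """Sample metadata table with the planted sex confound."""
    if cfg.n_high <= 0 or cfg.n_low <= 0:
        raise ValueError("both comparison groups need at least one sample")
    if cfg.n_high + cfg.n_low < 4:
        raise ValueError("need at least 4 samples across the comparison groups")
    rng = np.random.default_rng(stage_seed(cfg.seed, "cohort"))
    n = cfg.n_high + cfg.n_low + cfg.n_zero
    rows = []
    for i in range(n):
        if i < cfg.n_high:
            sjc = int(rng.integers(9, 25))
            sex = "male" if rng.random() < cfg.sex_confound_rate else "female"
        elif i < cfg.n_high + cfg.n_low:
            sjc = int(rng.integers(1, 9))
            sex = "female" if rng.random() < cfg.sex_confound_rate else "male"
        else:
            sjc = 0
            sex = "male" if rng.random() < 0.5 else "female"
        rows.append({
            "sample_id": f"S{i + 1:02d}",
            "sjc66": sjc,
            "sex": sex,
            "age": float(np.round(rng.uniform(25, 70), 1)),
            "dmard_use": bool(rng.random() < 0.5),
            "joint_source": "knee" if rng.random() < 0.85 else "ankle",
        })
    return pd.DataFrame(rows)


# -- gene models ------------------------------------------------------------

def generate_gene_models(cfg: SimConfig) -> List[GeneModel]:
    """Gene models on synthetic chromosomes, ~100 genes per chromosome.

    Genes are 1-50 kb, both strands, each with 1-5 transcripts sharing
    the gene's TSS region. ``cfg.n_allosome_genes`` extra genes go on the
    synthetic allosome chrSX to exercise the allosome filter.
    """
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(stage_seed(cfg.seed, "genes"))
    genes: List[GeneModel] = []

    def make_gene(gid: str, chrom: str, cursor: int) -> Tuple[GeneModel, int]:
        start = cursor + int(rng.integers(20_000, 60_000))
        length = int(rng.integers(1_000, 50_001))
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = cfg.transcripts_per_gene
        k = int(rng.integers(lo, hi + 1))
        transcripts = []
        for t in range(k):
            # transcripts share the TSS region of the gene
            off = int(rng.integers(0, min(200, length)))
            tlen = int(rng.integers(max(length // 4, 1), length + 1))
            if strand == "+":
                ts = start + off
                te = min(ts + tlen - 1, end)
            else:
                te = end - off
                ts = max(te - tlen + 1, start)
            transcripts.append((f"{gid}.T{t + 1}", ts, te))
        return GeneModel(gid, chrom, strand, start, end, tuple(transcripts)), end

    per_chrom = 100
    cursors: Dict[str, int] = {}
    for i in range(cfg.n_genes):
        chrom = f"chrS{i // per_chrom + 1}"
        cursor = cursors.get(chrom, 0)
        gene, cursor = make_gene(f"G{i + 1:04d}", chrom, cursor)
        cursors[chrom] = cursor
        genes.append(gene)
    for i in range(cfg.n_allosome_genes):
        cursor = cursors.get(ALLOSOME, 0)
        gene, cursor = make_gene(f"GX{i + 1:02d}", ALLOSOME, cursor)
        cursors[ALLOSOME] = cursor
        genes.append(gene)
    return genes


# -- role assignment --------------------------------------------------------

def assign_roles(cfg: SimConfig, genes: List[GeneModel]) -> pd.DataFrame:
    """Deterministically assign planted roles to autosomal genes.

    Discordant genes need >= 2 transcripts, so multi-transcript genes are
    preferred for those slots. Derived from the global seed only.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "roles"))
    autosomal = [g for g in genes if g.chrom != ALLOSOME]
    order = list(rng.permutation(len(autosomal)))
    multi = [i for i in order if len(autosomal[i].transcripts) >= 2]
    if len(multi) < cfg.n_discordant:
        raise ValueError("not enough multi-transcript genes for discordant roles")

    roles: Dict[str, str] = {g.gene_id: ROLE_NULL for g in autosomal}
    discordant = multi[:cfg.n_discordant]
    taken = set(discordant)
    for i in discordant:
        roles[autosomal[i].gene_id] = ROLE_GDEM_DISCORDANT
    remaining = [i for i in order if i not in taken]
    n_conc = cfg.n_gdem - cfg.n_discordant
    for i in remaining[:n_conc]:
        roles[autosomal[i].gene_id] = ROLE_GDEM
    rest = remaining[n_conc:]
    for i in rest[:cfg.n_gde_only]:
        roles[autosomal[i].gene_id] = ROLE_GDE_ONLY
    for i in rest[cfg.n_gde_only:cfg.n_gde_only + cfg.n_dmr_only]:
        roles[autosomal[i].gene_id] = ROLE_DMR_ONLY

    rows = []
    for g in genes:
        role = ROLE_ALLOSOME if g.chrom == ALLOSOME else roles[g.gene_id]
        has_dmr = role in (ROLE_GDEM, ROLE_GDEM_DISCORDANT, ROLE_DMR_ONLY)
        is_gde = role in (ROLE_GDEM, ROLE_GDEM_DISCORDANT, ROLE_GDE_ONLY)
        rows.append({
            "gene_id": g.gene_id, "role": role,
            "is_gde": is_gde, "has_dmr": has_dmr,
            "is_gdem": has_dmr and is_gde,
            "concordance": ("opposite" if role == ROLE_GDEM_DISCORDANT
                            else ("concordant" if is_gde else "")),
        })
    return pd.DataFrame(rows).set_index("gene_id")


# -- methylome --------------------------------------------------------------

def generate_methylome(cohort: pd.DataFrame, genes: List[GeneModel],
                       cfg: SimConfig
                       ) -> Tuple[MethylationMatrix, List[DmrRecord], PlantedTruth]:
    """Methylation counts with planted DMRs near target-gene promoters.

    Background CpGs are scattered over each chromosome; every DMR gene
    additionally gets an injected cluster of L consecutive, closely
    spaced CpGs in its promoter. The high group's success probability in
    the cluster is shifted by +/- ``dmr_effect`` percentage points.
    Raises if a planted region falls outside its gene's annotation
    window (truth must be recoverable).
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "methylome"))
    truth_genes = assign_roles(cfg, genes)
    labeled = dichotomize_sjc66(cohort)
    high_mask = (labeled["group"] == "high").to_numpy()
    samples = list(labeled["sample_id"])
    n_samp = len(samples)

    chrom_len: Dict[str, int] = {}
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0), g.end + 30_000)

    # background CpG scatter, allocated proportionally to chromosome length
    total_len = sum(chrom_len.values())
    n_cpgs = (cfg.n_cpgs if cfg.n_cpgs is not None
              else total_len // cfg.cpg_spacing_bp)
    site_chrom: List[str] = []
    site_pos: List[int] = []
    for chrom in sorted(chrom_len):
        n_c = max(int(round(n_cpgs * chrom_len[chrom] / total_len)), 10)
        pos = np.unique(rng.integers(1, chrom_len[chrom], size=n_c))
        site_chrom.extend([chrom] * len(pos))
        site_pos.extend(pos.tolist())

    # planted clusters near promoters of DMR genes
    dmr_genes = truth_genes.index[truth_genes["has_dmr"]]
    gene_by_id = {g.gene_id: g for g in genes}
    cluster_sites: Dict[str, Tuple[str, np.ndarray]] = {}
    dmr_rows = []
    records: List[DmrRecord] = []
    for k, gid in enumerate(sorted(dmr_genes)):
        g = gene_by_id[gid]
        L = int(rng.integers(cfg.dmr_len[0], cfg.dmr_len[1] + 1))
        gaps = rng.integers(10, 40, size=L - 1)
        span = int(gaps.sum())
        if g.strand == "+":
            first = g.start - 2_000 + int(rng.integers(0, 500))
        else:
            first = g.end + 2_000 - span - int(rng.integers(0, 500))
        positions = first + np.concatenate(([0], np.cumsum(gaps)))
        win_lo, win_hi = ((g.start - 5_000, g.end + 1_000) if g.strand == "+"
                          else (g.start - 1_000, g.end + 5_000))
        if positions[0] < win_lo or positions[-1] > win_hi:
            raise ValueError(
                f"planted DMR for {gid} escapes its annotation window")
        sign = 1 if rng.random() < 0.4 else -1     # both directions planted
        name = f"DMR_{k + 1:04d}"
        cluster_sites[name] = (g.chrom, positions)
        stat = sign * float(np.round(rng.uniform(8, 16), 2))
        p_val = float(10 ** rng.uniform(-5, -3))
        records.append(DmrRecord(g.chrom, int(positions[0]), int(positions[-1]),
                                 name, stat, p_val,
                                 "hyper" if sign > 0 else "hypo"))
        dmr_rows.append({"name": name, "gene_id": gid, "chrom": g.chrom,
                         "start": int(positions[0]), "end": int(positions[-1]),
                         "sign": sign, "n_cpgs": L})
        site_chrom.extend([g.chrom] * L)
        site_pos.extend(positions.tolist())

    sites = pd.DataFrame({"chrom": site_chrom, "pos": site_pos})
    sites = (sites.drop_duplicates(["chrom", "pos"])
             .sort_values(["chrom", "pos"]).reset_index(drop=True))
    n_cpg = len(sites)

    # bimodal beta-mixture baseline
    lowmode = rng.random(n_cpg) < 0.55
    base = np.where(lowmode, rng.beta(0.8, 6.0, n_cpg), rng.beta(6.0, 0.8, n_cpg))
    p = np.clip(np.repeat(base[:, None], n_samp, axis=1), 0.02, 0.98)

    # overwrite planted regions: room for the shift plus per-sample wobble;
    # every CpG inside the interval shifts, including background CpGs that
    # happen to fall within it (a DMR's constituent CpGs move together)
    effect = cfg.dmr_effect / 100.0
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for row in dmr_rows:
        idx = np.flatnonzero((chrom_arr == row["chrom"])
                             & (pos_arr >= row["start"])
                             & (pos_arr <= row["end"]))
        row["n_cpgs"] = len(idx)
        sign = row["sign"]
        if sign > 0:
            region_base = rng.uniform(0.08, 0.90 - effect)
        else:
            region_base = rng.uniform(0.08 + effect, 0.90)
        cpg_base = np.clip(region_base + rng.normal(0, 0.03, len(idx)), 0.02, 0.98)
        sample_effect = rng.normal(0, 0.04, n_samp)
        region_p = cpg_base[:, None] + sample_effect[None, :]
        region_p[:, high_mask] += sign * effect
        p[idx] = np.clip(region_p, 0.01, 0.99)

    total = rng.poisson(cfg.coverage_mean, size=(n_cpg, n_samp))
    meth_counts = rng.binomial(total, p)
    meth = MethylationMatrix(sites["chrom"].to_numpy(dtype=object),
                             sites["pos"].to_numpy(dtype=np.int64),
                             meth_counts, total, samples)

    truth = PlantedTruth(genes=truth_genes, dmrs=pd.DataFrame(dmr_rows))
    # every planted DMR must map to >= 1 gene under the annotation rule
    links = brute_force_annotate(records, genes, AnnotationConfig())
    linked = {d.name for d, _ in links}
    missing = [r.name for r in records if r.name not in linked]
    if missing:
        raise ValueError(f"planted DMRs not recoverable by annotation: {missing}")
    return meth, records, truth


# -- transcript counts ------------------------------------------------------

def generate_transcript_counts(cohort: pd.DataFrame, genes: List[GeneModel],
                               methylome: MethylationMatrix, cfg: SimConfig,
                               truth: PlantedTruth
                               ) -> Tuple[TranscriptCountMatrix, PlantedTruth]:
    """NB transcript counts with planted effects and eQTM coupling.

    Effect layout per role: gde_only genes get ``+/- expr_lfc`` directly
    on designated transcripts; discordant GDEM genes get one transcript
    up and one down; concordant GDEM genes are driven through the copula
    link to their planted region's realized median methylation (negative
    sign by default), which induces both the group expression difference
    and the target correlation. Allosome genes get a sex effect so the
    allosome filter has something real to remove.
    """
    truth.validate()
    rng = np.random.default_rng(stage_seed(cfg.seed, "counts"))
    labeled = dichotomize_sjc66(cohort)
    samples = list(labeled["sample_id"])
    if samples != list(methylome.samples):
        raise ValueError("cohort and methylome sample order differ")
    n_samp = len(samples)
    high = (labeled["group"] == "high").to_numpy(dtype=float)
    male = (labeled["sex"] == "male").to_numpy(dtype=float)

    dmr_of_gene = ({row["gene_id"]: row for _, row in truth.dmrs.iterrows()}
                   if not truth.dmrs.empty else {})

    def region_median(row) -> np.ndarray:
        mask = methylome.region_mask(row["chrom"], row["start"], row["end"])
        pct = methylome.pct(1)[mask]
        with np.errstate(all="ignore"):
            med = np.nanmedian(pct, axis=0)
        return np.where(np.isfinite(med), med, np.nanmean(med))

    depth = rng.uniform(0.7, 1.4, n_samp)      # library-size variation
    amp = cfg.expr_lfc / 2.0                   # copula amplitude (log2 units)
    rho = cfg.eqtm_rho

    tids, gids, mus = [], [], []
    pair_rows = []
    for g in genes:
        role = truth.genes.loc[g.gene_id, "role"]
        n_t = len(g.transcripts)
        for t_idx, (tid, _, _) in enumerate(g.transcripts):
            log2_mu0 = rng.uniform(4.0, 9.0)
            log2_mu = np.full(n_samp, log2_mu0)
            if role == ROLE_GDE_ONLY and t_idx == 0:
                sign = 1 if rng.random() < 0.5 else -1
                log2_mu = log2_mu + sign * cfg.expr_lfc * high
            elif role == ROLE_GDEM_DISCORDANT and t_idx < 2:
                sign = 1 if t_idx == 0 else -1
                log2_mu = log2_mu + sign * cfg.expr_lfc * high
            elif role == ROLE_GDEM and t_idx < 2:
                row = dmr_of_gene[g.gene_id]
                m = region_median(row)
                sd = m.std()
                zm = (m - m.mean()) / sd if sd > 0 else np.zeros(n_samp)
                eps = rng.normal(0, 1, n_samp)
                latent = rho * zm + np.sqrt(max(1 - rho**2, 0.0)) * eps
                log2_mu = log2_mu - amp * latent   # promoter methylation represses
                if t_idx == 0:
                    pair_rows.append({"gene_id": g.gene_id,
                                      "dmr_name": row["name"],
                                      "transcript_id": tid,
                                      "rho": -rho})
            elif role == ROLE_ALLOSOME:
                log2_mu = log2_mu + 1.5 * male
            mu = depth * 2.0 ** log2_mu
            tids.append(tid)
            gids.append(g.gene_id)
            mus.append(mu)

    mu_mat = np.vstack(mus)
    if cfg.dispersion > 0:
        size = 1.0 / cfg.dispersion
        prob = size / (size + mu_mat)
        counts = rng.negative_binomial(size, prob)
    else:
        counts = rng.poisson(mu_mat)
    tcm = TranscriptCountMatrix(
        pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                     columns=samples),
        pd.Series(gids, index=pd.Index(tids, name="transcript_id"), name="gene_id"))
    truth.pairs = pd.DataFrame(pair_rows,
                               columns=["gene_id", "dmr_name", "transcript_id", "rho"])
    truth.validate()
    return tcm, truth


# -- orchestration ----------------------------------------------------------

def simulate_study(cfg: Optional[SimConfig] = None) -> SimulatedStudy:
    """Generate the full miniature study in memory."""
    cfg = cfg or SimConfig()
    cohort = generate_cohort(cfg)
    genes = generate_gene_models(cfg)
    meth, dmrs, truth = generate_methylome(cohort, genes, cfg)
    tcm, truth = generate_transcript_counts(cohort, genes, meth, cfg, truth)
    return SimulatedStudy(cfg, cohort, genes, meth, dmrs, tcm, truth)


def write_study(study: SimulatedStudy, out_dir) -> Dict[str, Path]:
    """Write every study file; byte-identical for a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out / "samples.tsv",
        "gtf": out / "genes.gtf",
        "counts": out / "counts.tsv",
        "dmrs": out / "dmrs.bed",
        "truth_genes": out / "truth_genes.tsv",
        "truth_dmrs": out / "truth_dmrs.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
    }
    study.samples.to_csv(paths["samples"], sep="\t", index=False)
    gio.write_gtf(study.genes, paths["gtf"])
    gio.write_counts_tsv(study.counts, paths["counts"])
    gio.write_bed_dmrs(study.dmrs, paths["dmrs"])
    gio.write_coverage_dir(study.methylome, out)
    study.truth.genes.to_csv(paths["truth_genes"], sep="\t")
    study.truth.dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)
    study.truth.pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths
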