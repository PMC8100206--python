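"""Self-contained validation measurements for the pipeline.

Each function recomputes one property of the method from scratch —
oracle equivalences for the aggregation, FDR and annotation primitives,
calibration of the permutation null, bootstrap coverage, and
planted-truth recovery on the default synthetic study. They back both
the test suite and the reproduction script.
"""

from __future__ import annotations

import hashlib
import tempfile
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import annotation, eqtm, gde
from .cohort import dichotomize_sjc66, retained
from .config import (AnnotationConfig, EqtmConfig, PipelineConfig, SimConfig,
                     stage_seed)
from .pipeline import run_on_study, run_pipeline
from .simulate import simulate_study, write_study


def lancaster_fisher_max_diff(n_vectors: int = 1000, seed: int = 0) -> float:
    """Max |combined p - chi-square oracle| with all weights = 2."""
    rng = np.random.default_rng(stage_seed(seed, "fisher"))
    worst = 0.0
    for _ in range(n_vectors):
        k = int(rng.integers(1, 11))
        p = rng.uniform(1e-12, 1.0, size=k)
        ours = gde.lancaster_aggregate(p, np.full(k, 2.0))
        oracle = stats.chi2.sf(-2.0 * np.sum(np.log(p)), df=2 * k)
        worst = max(worst, abs(ours - oracle))
    return worst


def single_transcript_identity_max_diff(n_cases: int = 100,
                                        seed: int = 0) -> float:
    """A one-transcript gene's combined p must equal the transcript p."""
    rng = np.random.default_rng(stage_seed(seed, "identity"))
    worst = 0.0
    for _ in range(n_cases):
        p = float(rng.uniform(1e-10, 1.0))
        w = float(rng.uniform(1.1, 100.0))
        worst = max(worst, abs(gde.lancaster_aggregate([p], [w]) - p))
    return worst


def _stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Plain Benjamini–Hochberg step-up, written independently."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def bh_oracle_max_diff(n_vectors: int = 100, seed: int = 0) -> float:
    rng = np.random.default_rng(stage_seed(seed, "bh"))
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(0.0, 1.0, size=int(rng.integers(1, 60)))
        worst = max(worst, float(np.max(np.abs(gde.bh_adjust(p) -
                                               _stepup_oracle(p)))))
    return worst


def annotation_oracle_agreement(n_instances: int = 100, seed: int = 0) -> float:
    """Fraction of random instances where the interval-tree annotation and
    the brute-force pairwise oracle return identical link multisets."""
    from .containers import DmrRecord, GeneModel

    rng = np.random.default_rng(stage_seed(seed, "annot"))
    cfg = AnnotationConfig()
    agree = 0
    for _ in range(n_instances):
        chroms = ["chr1", "chr2", "chr3"]
        genes = []
        for i in range(int(rng.integers(1, 201))):
            s = int(rng.integers(1, 2_000_000))
            genes.append(GeneModel(f"G{i}", str(rng.choice(chroms)),
                                   str(rng.choice(["+", "-"])), s,
                                   s + int(rng.integers(1, 50_000))))
        dmrs = []
        for i in range(int(rng.integers(1, 201))):
            anchor = genes[int(rng.integers(0, len(genes)))]
            # offsets concentrated near window edges so boundaries are hit
            s = max(1, anchor.start - cfg.upstream_bp
                    + int(rng.integers(-3, 4)) * int(rng.integers(1, 2000)))
            stat = float(rng.normal())
            dmrs.append(DmrRecord(str(rng.choice(chroms)), s,
                                  s + int(rng.integers(1, 20_000)), f"d{i}",
                                  stat, 1e-3, "hyper" if stat >= 0 else "hypo"))
        fast = annotation.annotate_dmrs(dmrs, genes, cfg)
        slow = annotation.brute_force_annotate(dmrs, genes, cfg)
        key = lambda links: sorted((d.name, d.start, g.gene_id) for d, g in links)
        agree += key(fast) == key(slow)
    return agree / n_instances


def permutation_null_ks(n_genes: int = 200, seed: int = 0) -> float:
    """KS-test p-value for uniformity of eQTM permutation p-values on a
    synthetic null study (no planted effects, 17 samples, 1000 windows)."""
    cfg = SimConfig(n_genes=n_genes, n_gdem=0, n_discordant=0, n_gde_only=0,
                    n_dmr_only=0, n_allosome_genes=0, expr_lfc=0.0,
                    eqtm_rho=0.0, dmr_effect=0.0, n_cpgs=20_000,
                    seed=stage_seed(seed, "nullstudy"))
    study = simulate_study(cfg)
    kept = [str(s) for s in
            retained(dichotomize_sjc66(study.samples))["sample_id"]]
    meth = study.methylome.subset_samples(kept)
    norm, _, _ = gde.normalize_counts(study.counts.subset_samples(kept))
    log2e = np.log2(norm + 1.0)

    ecfg = EqtmConfig(n_permutation=1000, seed=seed)
    null = eqtm.WindowNull(meth, ecfg.min_cpg_coverage)
    rng = np.random.default_rng(stage_seed(seed, "nullperm"))
    gene_ids = sorted(set(study.counts.gene_of))[:n_genes]
    first_tid = {g: t for t, g in
                 reversed(list(study.counts.gene_of.items()))}
    pvals = []
    for gid in gene_ids:
        expr = log2e.loc[first_tid[gid]].to_numpy()
        L = int(rng.integers(10, 51))
        starts = null.valid_starts(L)
        for _ in range(10):  # redraw if the observed window is degenerate
            obs = int(rng.choice(starts))
            r_obs = float(null.window_correlations(np.array([obs]), L, expr)[0])
            if np.isfinite(r_obs):
                break
        exclude = (str(meth.chrom[obs]), int(meth.pos[obs]),
                   int(meth.pos[obs + L - 1]))
        pvals.append(null.p_value(r_obs, L, expr, ecfg, rng, exclude))
    return float(stats.kstest(pvals, "uniform").pvalue)


def bootstrap_coverage(rho: float = 0.8, n: int = 17, n_reps: int = 500,
                       seed: int = 0) -> float:
    """Fraction of bivariate-normal replicates whose 95% percentile
    bootstrap CI contains the true correlation."""
    rng = np.random.default_rng(stage_seed(seed, "coverage"))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    cfg = EqtmConfig(n_bootstrap=1000, seed=seed)
    hits = 0
    for _ in range(n_reps):
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        lo, hi = eqtm.bootstrap_ci(xy[:, 0], xy[:, 1], cfg, rng)
        hits += lo <= rho <= hi
    return hits / n_reps


def planted_recovery(seed: int = 1) -> Dict[str, float]:
    """Run the full pipeline on the default study and score it against
    the planted truth."""
    study = simulate_study(SimConfig(seed=seed))
    result = run_on_study(study, PipelineConfig(seed=seed))
    truth = study.truth
    planted = set(truth.genes.index[truth.genes["is_gdem"]])
    found = {r.gene_id for r in result.gdem_records}
    discordant = set(truth.genes.index[truth.genes["concordance"] == "opposite"])
    # a discordant gene is scorable only when both of its planted
    # opposite-sign transcripts were themselves recovered as significant
    correct = scored = 0
    for rec in result.gdem_records:
        if rec.gene_id not in discordant:
            continue
        sig = {tid for tid, _, _, s in rec.transcript_stats if s}
        if {f"{rec.gene_id}.T1", f"{rec.gene_id}.T2"} <= sig:
            scored += 1
            correct += rec.concordance == "opposite"
    return {
        "n_planted": len(planted),
        "n_recovered": len(planted & found),
        "recovery_rate": len(planted & found) / len(planted),
        "n_false_gdem": len(found - planted),
        "concordance_accuracy": correct / scored if scored else float("nan"),
        "n_concordance_scored": scored,
    }


def planted_eqtm_power(n_seeds: int = 20, seed: int = 0,
                       threshold: float = 0.05) -> Dict[str, float]:
    """Fraction of planted eQTM pairs attaining perm_p <= threshold,
    across independent default-configuration studies."""
    total = 0
    hits = 0
    for i in range(n_seeds):
        study = simulate_study(SimConfig(seed=stage_seed(seed, f"power{i}")))
        kept = [str(s) for s in
                retained(dichotomize_sjc66(study.samples))["sample_id"]]
        meth = study.methylome.subset_samples(kept).drop_chroms(["chrSX"])
        norm, _, _ = gde.normalize_counts(study.counts.subset_samples(kept))
        log2e = np.log2(norm + 1.0)
        dmr_by_name = {d.name: d for d in study.dmrs}
        pairs = [(row.gene_id, dmr_by_name[row.dmr_name], row.transcript_id)
                 for row in study.truth.pairs.itertuples()]
        cfg = EqtmConfig(seed=stage_seed(seed, f"power-eqtm{i}"))
        table = eqtm.eqtm_analysis(pairs, meth, log2e, cfg)
        total += len(pairs)
        hits += int((table["perm_p"] <= threshold).sum())
    return {"n_pairs": total, "power": hits / total if total else float("nan")}


def stratification_exact(seed: int = 0) -> bool:
    """Boundary semantics of the SJC66 stratifier on hand values and on
    every simulated cohort."""
    toy = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "sjc66": [9, 8, 0, 66],
        "sex": ["male"] * 4, "age": [50.0] * 4,
        "dmard_use": [False] * 4, "joint_source": ["knee"] * 4,
    })
    out = dichotomize_sjc66(toy).set_index("sample_id")["group"]
    if not (out["a"] == "high" and out["b"] == "low"
            and out["c"] == "excluded" and out["d"] == "high"):
        return False
    from .simulate import generate_cohort
    for s in range(3):
        cohort = generate_cohort(SimConfig(n_zero=2, seed=stage_seed(seed, f"s{s}")))
        lab = dichotomize_sjc66(cohort)
        ok = (((lab["sjc66"] >= 9) == (lab["group"] == "high")).all()
              and (((lab["sjc66"] >= 1) & (lab["sjc66"] <= 8))
                   == (lab["group"] == "low")).all()
              and ((lab["sjc66"] == 0) == (lab["group"] == "excluded")).all())
        if not ok:
            return False
    return True


def _hash_tables(d: Path) -> str:
    # result tables only: the run log records wall times by design
    h = hashlib.sha256()
    for p in sorted(Path(d).glob("*.tsv")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def determinism_check(seed: int = 42,
                      workdir: Optional[Path] = None) -> bool:
    """Two full runs with one config+seed give byte-identical tables."""
    sim_cfg = SimConfig(n_genes=12, n_gdem=4, n_discordant=1, n_gde_only=2,
                        n_dmr_only=2, n_cpgs=800, seed=seed)
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        td = Path(td)
        study_dir = td / "study"
        write_study(simulate_study(sim_cfg), study_dir)
        hashes = []
        for run in ("one", "two"):
            cfg = PipelineConfig(samples_tsv=str(study_dir / "samples.tsv"),
                                 counts_tsv=str(study_dir / "counts.tsv"),
                                 genes_gtf=str(study_dir / "genes.gtf"),
                                 dmrs_bed=str(study_dir / "dmrs.bed"),
                                 coverage_dir=str(study_dir),
                                 out_dir=str(td / run), seed=seed)
            run_pipeline(cfg)
            hashes.append(_hash_tables(td / run))
    return hashes[0] == hashes[1]
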