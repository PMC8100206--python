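import numpy as np
import pandas as pd
import pytest

from gdemtools import annotation
from gdemtools.config import AnnotationConfig, SimConfig
from gdemtools.cohort import dichotomize_sjc66
from gdemtools import simulate as sim


class TestCohortGeneration:
    def test_group_sizes_and_ranges(self):
        cfg = SimConfig(n_high=5, n_low=5, n_zero=2, seed=1)
        cohort = sim.generate_cohort(cfg)
        assert len(cohort) == 12
        assert (cohort["sjc66"] >= 9).sum() == 5
        assert ((cohort["sjc66"] >= 1) & (cohort["sjc66"] <= 8)).sum() == 5
        assert (cohort["sjc66"] == 0).sum() == 2

    def test_seventeen_sample_default_layout(self):
        cohort = sim.generate_cohort(SimConfig(n_high=9, n_low=8, n_zero=0, seed=7))
        assert len(cohort) == 17
        assert cohort["sample_id"].is_unique

    def test_determinism(self):
        cfg = SimConfig(seed=3)
        pd.testing.assert_frame_equal(sim.generate_cohort(cfg),
                                      sim.generate_cohort(cfg))

    def test_sex_confound_planted(self):
        cohort = dichotomize_sjc66(sim.generate_cohort(SimConfig(seed=1)))
        high_male = (cohort.loc[cohort["group"] == "high", "sex"] == "male").mean()
        low_male = (cohort.loc[cohort["group"] == "low", "sex"] == "male").mean()
        assert high_male > low_male     # the deliberate confound

    def test_invalid_group_sizes_error(self):
        with pytest.raises(ValueError):
            sim.generate_cohort(SimConfig(n_high=0, n_low=8))
        with pytest.raises(ValueError):
            sim.generate_cohort(SimConfig(n_high=2, n_low=1))


class TestGeneModels:
    def test_counts_and_transcript_bounds(self):
        genes = sim.generate_gene_models(SimConfig(n_genes=10, n_gdem=3, n_discordant=1, n_gde_only=2, n_dmr_only=2, seed=3))
        autosomal = [g for g in genes if g.chrom != sim.ALLOSOME]
        assert len(autosomal) == 10
        for g in genes:
            assert len(g.transcripts) >= 1
            for _, ts, te in g.transcripts:
                assert g.start <= ts <= te <= g.end

    def test_gtf_round_trip(self, tmp_path):
        from gdemtools import io as gio
        genes = sim.generate_gene_models(SimConfig(n_genes=10, n_gdem=3, n_discordant=1, n_gde_only=2, n_dmr_only=2, seed=3))
        p = tmp_path / "genes.gtf"
        gio.write_gtf(genes, p)
        assert gio.read_gtf(p) == sorted(genes, key=lambda g: g.gene_id)


class TestMethylome:
    def test_counts_valid_and_planted_shift_recovered(self):
        # 30-point shift, depth 30, fixed run length 20: the realized group
        # difference over each planted region stays within +/-5 points
        cfg = SimConfig(dmr_effect=30.0, coverage_mean=30.0, dmr_len=(20, 20),
                        n_cpgs=3000, seed=5)
        cohort = sim.generate_cohort(cfg)
        genes = sim.generate_gene_models(cfg)
        meth, dmrs, truth = sim.generate_methylome(cohort, genes, cfg)
        assert np.all(meth.meth <= meth.total) and np.all(meth.meth >= 0)

        labeled = dichotomize_sjc66(cohort)
        high = (labeled["group"] == "high").to_numpy()
        pct = meth.pct(1)
        diffs = []
        for d in dmrs:
            mask = meth.region_mask(d.chrom, d.start, d.end)
            assert mask.sum() >= 20   # planted run plus any background CpGs inside
            diff = np.nanmean(pct[mask][:, high]) - np.nanmean(pct[mask][:, ~high])
            sign = 1 if d.direction == "hyper" else -1
            diffs.append(diff * sign)
        # per-region group means carry ~2-point sampling noise at n=9+8
        assert np.mean(diffs) == pytest.approx(30.0, abs=5.0)
        assert np.all(np.abs(np.array(diffs) - 30.0) < 10.0)

    def test_null_effect_gives_no_shift(self):
        cfg = SimConfig(dmr_effect=0.0, n_cpgs=2000, seed=6)
        cohort = sim.generate_cohort(cfg)
        genes = sim.generate_gene_models(cfg)
        meth, dmrs, _ = sim.generate_methylome(cohort, genes, cfg)
        labeled = dichotomize_sjc66(cohort)
        high = (labeled["group"] == "high").to_numpy()
        pct = meth.pct(1)
        diffs = []
        for d in dmrs:
            mask = meth.region_mask(d.chrom, d.start, d.end)
            diffs.append(np.nanmean(pct[mask][:, high]) -
                         np.nanmean(pct[mask][:, ~high]))
        assert abs(np.mean(diffs)) < 3.0

    def test_planted_dmrs_recoverable_by_annotation(self, study):
        links = annotation.brute_force_annotate(study.dmrs, study.genes,
                                                AnnotationConfig())
        linked_names = {d.name for d, _ in links}
        assert linked_names >= set(study.truth.dmrs["name"])


class TestTranscriptCounts:
    def test_counts_are_nonnegative_integers(self, study):
        vals = study.counts.counts.to_numpy()
        assert np.issubdtype(vals.dtype, np.integer) and np.all(vals >= 0)

    def test_truth_flags_consistent(self, study):
        g = study.truth.genes
        assert (g["is_gdem"] == (g["is_gde"] & g["has_dmr"])).all()
        assert set(study.truth.pairs["gene_id"]) <= set(study.truth.dmrs["gene_id"])
        study.truth.validate()

    def test_eqtm_link_without_dmr_rejected(self, study):
        broken = sim.PlantedTruth(
            genes=study.truth.genes,
            dmrs=study.truth.dmrs[study.truth.dmrs["gene_id"] == "nope"],
            pairs=study.truth.pairs)
        with pytest.raises(ValueError, match="without planted DMR"):
            broken.validate()


def test_written_study_is_byte_identical_across_runs(tmp_path):
    import hashlib

    def hash_dir(d):
        h = hashlib.sha256()
        for p in sorted(d.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    cfg = SimConfig(n_genes=12, n_gdem=3, n_discordant=1, n_gde_only=2,
                    n_dmr_only=2, n_cpgs=600, seed=42)
    a, b = tmp_path / "a", tmp_path / "b"
    sim.write_study(sim.simulate_study(cfg), a)
    sim.write_study(sim.simulate_study(cfg), b)
    assert hash_dir(a) == hash_dir(b)
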