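import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gdemtools import cohort, gde
from gdemtools.containers import TranscriptCountMatrix


def _tcm(counts, samples=None, genes=None):
    counts = np.asarray(counts)
    samples = samples or [f"S{i}" for i in range(counts.shape[1])]
    tids = [f"T{i}" for i in range(counts.shape[0])]
    genes = genes or ["G0"] * counts.shape[0]
    return TranscriptCountMatrix(
        pd.DataFrame(counts, index=pd.Index(tids, name="transcript_id"),
                     columns=samples),
        pd.Series(genes, index=tids, name="gene_id"))


class TestNormalization:
    def test_identical_columns_have_unit_size_factors(self):
        tcm = _tcm([[10, 10], [40, 40], [100, 100]])
        _, sf, _ = gde.normalize_counts(tcm)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_gets_double_size_factor(self):
        # hand computation: ratios to the geometric mean give sqrt(2) and
        # 2/sqrt(2), so the second factor is exactly twice the first
        tcm = _tcm([[10, 20], [40, 80], [100, 200]])
        norm, sf, _ = gde.normalize_counts(tcm)
        assert sf["S1"] == pytest.approx(2.0 * sf["S0"])
        assert np.allclose(norm["S0"], norm["S1"])

    def test_all_zero_transcript_has_zero_base_expression(self):
        tcm = _tcm([[10, 20], [0, 0], [100, 200]])
        _, _, base = gde.normalize_counts(tcm)
        assert base["T1"] == 0.0

    def test_all_zero_sample_rejected(self):
        tcm = _tcm([[10, 0], [40, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            gde.normalize_counts(tcm)


class TestTranscriptTest:
    @pytest.fixture()
    def design(self, toy_samples):
        return cohort.build_design(toy_samples)

    def test_zero_effect_in_noiseless_data(self, design):
        norm = pd.DataFrame(np.full((2, 9), 7.0), index=["T0", "T1"],
                            columns=design.index)
        res = gde.test_transcripts(norm, design, pd.Series(["G0", "G0"],
                                                           index=["T0", "T1"]))
        assert np.allclose(res["effect_stat"], 0.0)
        assert np.allclose(res["p_value"], 1.0)

    def test_perfect_separation_floored_and_flagged(self, design):
        vals = np.where(design["group"].to_numpy() == 1.0, 255.0, 7.0)
        norm = pd.DataFrame([vals], index=["T0"], columns=design.index)
        res = gde.test_transcripts(norm, design, pd.Series(["G0"], index=["T0"]))
        assert bool(res.loc["T0", "degenerate"])
        assert 0 < res.loc["T0", "p_value"] <= np.finfo(float).tiny

    def test_matches_statsmodels_ols(self, design):
        # the vectorised fit must agree with an independent OLS implementation
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        norm = pd.DataFrame(rng.gamma(2.0, 50.0, size=(6, 9)),
                            index=[f"T{i}" for i in range(6)],
                            columns=design.index)
        res = gde.test_transcripts(norm, design,
                                   pd.Series(["G0"] * 6, index=norm.index))
        for tid in norm.index:
            fit = sm.OLS(np.log2(norm.loc[tid] + 1.0), design).fit()
            assert res.loc[tid, "effect_stat"] == pytest.approx(fit.tvalues["group"])
            assert res.loc[tid, "p_value"] == pytest.approx(fit.pvalues["group"])

    def test_no_residual_dof_errors(self, design):
        small = design.iloc[:5]
        norm = pd.DataFrame([[1.0] * 5], index=["T0"], columns=small.index)
        with pytest.raises(ValueError, match="degrees of freedom"):
            gde.test_transcripts(norm, small, pd.Series(["G0"], index=["T0"]))


class TestLancaster:
    def test_single_element_is_identity(self):
        assert gde.lancaster_aggregate([0.03], [5.0]) == pytest.approx(0.03, abs=1e-12)

    def test_reduces_to_fisher_at_weight_two(self):
        # Fisher: -2*sum(log p) ~ chi2(2k); independent oracle
        p = np.array([0.05, 0.05])
        fisher_stat = -2.0 * np.sum(np.log(p))
        assert fisher_stat == pytest.approx(11.9829, abs=1e-4)
        expected = stats.chi2.sf(fisher_stat, df=4)
        assert gde.lancaster_aggregate(p, [2.0, 2.0]) == pytest.approx(expected,
                                                                       abs=1e-12)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_weight_two_fisher_equivalence_property(self, pvals):
        p = np.array(pvals)
        ours = gde.lancaster_aggregate(p, np.full(len(p), 2.0))
        oracle = stats.chi2.sf(-2.0 * np.sum(np.log(p)), df=2 * len(p))
        assert abs(ours - oracle) < 1e-10

    @given(st.lists(st.tuples(st.floats(1e-6, 1.0), st.floats(0.5, 50.0)),
                    min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_p_and_permutation_invariant(self, pairs):
        p = np.array([a for a, _ in pairs])
        w = np.array([b for _, b in pairs])
        base = gde.lancaster_aggregate(p, w)
        perm = np.random.default_rng(0).permutation(len(p))
        assert gde.lancaster_aggregate(p[perm], w[perm]) == pytest.approx(base,
                                                                          abs=1e-12)
        bumped = np.minimum(p * 1.5, 1.0)
        assert gde.lancaster_aggregate(bumped, w) >= base - 1e-12

    def test_all_weights_below_floor_errors(self):
        with pytest.raises(ValueError, match="floor"):
            gde.lancaster_aggregate([0.5, 0.5], [0.2, 0.9], weight_floor=1.0)

    def test_zero_p_clamped_not_crashing(self):
        out = gde.lancaster_aggregate([0.0, 0.5], [3.0, 3.0])
        assert 0.0 <= out < 0.5


class TestBH:
    def test_hand_verified_step_up(self):
        # step-up by hand: q_i = min over j>=i of p_j * n / j
        assert np.allclose(gde.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert gde.bh_adjust([0.2])[0] == pytest.approx(0.2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_q_monotone_in_p_ranking(self, pvals):
        p = np.array(pvals)
        q = gde.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0 + 1e-12))


class TestGdeCall:
    def test_strict_threshold(self):
        df = pd.DataFrame({"q_value": [0.049, 0.05, 0.2]},
                          index=["A", "B", "C"])
        assert gde.call_gde(df) == {"A"}

    def test_empty_input(self):
        assert gde.call_gde(pd.DataFrame(columns=["q_value"])) == set()


def test_allosome_genes_never_reach_testing(study, result):
    allosome_genes = {g.gene_id for g in study.genes if g.chrom == "chrSX"}
    assert allosome_genes
    tested = set(result.transcript_results["gene_id"])
    assert not (allosome_genes & tested)
    assert not (allosome_genes & set(result.gene_results["gene_id"]))


def test_null_study_gene_pvalues_calibrated():
    """With nothing planted, the aggregated-p discovery rate at 5% stays
    inside the binomial 99% band around 5%."""
    from gdemtools.config import PipelineConfig, SimConfig
    from gdemtools.pipeline import run_on_study
    from gdemtools.simulate import simulate_study

    cfg = SimConfig(n_genes=200, n_gdem=0, n_discordant=0, n_gde_only=0,
                    n_dmr_only=0, n_allosome_genes=0, expr_lfc=0.0,
                    eqtm_rho=0.0, dmr_effect=0.0, n_cpgs=2000, seed=11)
    res = run_on_study(simulate_study(cfg), PipelineConfig(seed=11))
    p = res.gene_results["p_value"].to_numpy()
    rate = (p < 0.05).mean()
    half_band = 2.576 * np.sqrt(0.05 * 0.95 / len(p))
    assert abs(rate - 0.05) <= half_band
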