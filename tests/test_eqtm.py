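import numpy as np
import pytest

from gdemtools import eqtm
from gdemtools.config import EqtmConfig
from gdemtools.containers import DmrRecord, MethylationMatrix


def meth_from_pct(chrom, pos, pct_matrix, depth=10):
    """Exact-percentage methylome helper (total = depth everywhere)."""
    pct = np.asarray(pct_matrix, dtype=float)
    total = np.full(pct.shape, depth, dtype=np.int64)
    m = np.round(pct / 100.0 * depth).astype(np.int64)
    samples = [f"S{i}" for i in range(pct.shape[1])]
    return MethylationMatrix(np.array([chrom] * len(pos), dtype=object),
                             np.array(pos), m, total, samples)


class TestMedianMethylation:
    def test_odd_and_even_medians(self):
        meth = meth_from_pct("c", [10, 20, 30], [[10], [20], [90]])
        vec, L = eqtm.median_methylation(("c", 10, 30), meth)
        assert L == 3 and vec[0] == pytest.approx(20.0)
        meth2 = meth_from_pct("c", [10, 20], [[10], [90]])
        vec2, L2 = eqtm.median_methylation(("c", 10, 20), meth2)
        assert L2 == 2 and vec2[0] == pytest.approx(50.0)

    def test_uncovered_sample_is_missing(self):
        meth = meth_from_pct("c", [10, 20], [[10, 40], [30, 60]])
        meth.total[:, 1] = 0
        meth.meth[:, 1] = 0
        vec, _ = eqtm.median_methylation(("c", 10, 20), meth)
        assert vec[0] == pytest.approx(20.0) and np.isnan(vec[1])

    def test_empty_region_errors(self):
        meth = meth_from_pct("c", [10], [[50]])
        with pytest.raises(ValueError, match="no CpGs"):
            eqtm.median_methylation(("c", 100, 200), meth)


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (6, 4, 2), -1.0),
        ((1, 2, 3), (1, 3, 2), 0.5),   # direct formula by hand
    ])
    def test_known_values(self, x, y, expected):
        assert eqtm.pearson_r(x, y) == pytest.approx(expected)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            eqtm.pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="3 paired"):
            eqtm.pearson_r([1, 2], [3, 4])


class TestBootstrap:
    def test_exactly_linear_data_gives_degenerate_ci(self):
        x = np.arange(10.0)
        cfg = EqtmConfig(n_bootstrap=200, seed=3)
        lo, hi = eqtm.bootstrap_ci(x, 2 * x + 1, cfg)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_fixed_seed_reproducible_and_bounded(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=17)
        y = 0.8 * x + rng.normal(scale=0.6, size=17)
        cfg = EqtmConfig(n_bootstrap=500, seed=21)
        a = eqtm.bootstrap_ci(x, y, cfg)
        b = eqtm.bootstrap_ci(x, y, cfg)
        assert a == b
        assert -1.0 <= a[0] <= a[1] <= 1.0

    def test_pathological_data_errors(self):
        # x almost always constant in a resample of n=3 from 2 distinct values
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0])[:3]
        with pytest.raises(ValueError):
            eqtm.bootstrap_ci(x, [1.0, 2.0, 3.0], EqtmConfig(n_bootstrap=100, seed=0))


class TestWindowNull:
    @pytest.fixture()
    def null_meth(self):
        rng = np.random.default_rng(4)
        n, s = 400, 12
        pos = np.sort(rng.choice(np.arange(1, 50_000), size=n, replace=False))
        total = rng.poisson(25, size=(n, s)) + 1
        m = rng.binomial(total, np.clip(rng.beta(2, 2, size=n), 0.05, 0.95)[:, None])
        return MethylationMatrix(np.array(["c"] * n, dtype=object), pos,
                                 m, total, [f"S{i}" for i in range(s)])

    def test_perm_p_granularity(self, null_meth):
        cfg = EqtmConfig(n_permutation=250, seed=5)
        rng = np.random.default_rng(5)
        expr = rng.normal(size=12)
        p = eqtm.permutation_p(0.4, 8, null_meth, expr, cfg, rng)
        assert (p * cfg.n_permutation) == pytest.approx(round(p * cfg.n_permutation))
        assert 0.0 <= p <= 1.0

    def test_perfect_correlation_unbeatable(self, null_meth):
        cfg = EqtmConfig(n_permutation=200, seed=6)
        expr = np.random.default_rng(6).normal(size=12)
        assert eqtm.permutation_p(1.0, 8, null_meth, expr, cfg) == 0.0

    def test_single_permutation_is_binary(self, null_meth):
        cfg = EqtmConfig(n_permutation=1, seed=7)
        expr = np.random.default_rng(7).normal(size=12)
        assert eqtm.permutation_p(0.2, 8, null_meth, expr, cfg) in (0.0, 1.0)

    def test_observed_window_excluded_from_null(self, null_meth):
        null = eqtm.WindowNull(null_meth)
        L = 10
        starts_all = null.valid_starts(L)
        ex = ("c", int(null_meth.pos[50]), int(null_meth.pos[50 + L - 1]))
        starts_ex = null.valid_starts(L, exclude=ex)
        assert len(starts_ex) < len(starts_all)
        w_start = null_meth.pos[starts_ex]
        w_end = null_meth.pos[starts_ex + L - 1]
        assert not np.any((w_start <= ex[2]) & (w_end >= ex[1]))

    def test_too_few_windows_warns_and_resamples(self, null_meth, caplog):
        import logging
        cfg = EqtmConfig(n_permutation=1000, seed=8)
        expr = np.random.default_rng(8).normal(size=12)
        with caplog.at_level(logging.WARNING):
            p = eqtm.permutation_p(0.3, 399, null_meth, expr, cfg)
        assert any("replacement" in r.message for r in caplog.records)
        assert 0.0 <= p <= 1.0

    def test_literal_one_sided_rule(self, null_meth):
        # the literal "higher than observed" rule: a strong negative r is
        # beaten by almost every null window
        cfg = EqtmConfig(n_permutation=200, seed=9, tail="greater")
        expr = np.random.default_rng(9).normal(size=12)
        p = eqtm.permutation_p(-0.95, 8, null_meth, expr, cfg)
        assert p > 0.9


def test_planted_pairs_recover_strong_negative_r(study, result):
    """Planted coupling (|rho| = 0.9) should come back as a strong negative
    correlation with a tight CI on the default study."""
    truth = study.truth
    eq = result.eqtm_table.merge(truth.pairs, on=["gene_id", "transcript_id"])
    assert len(eq) >= 5
    assert (eq["r"] < -0.6).mean() >= 0.8
    assert np.all(eq["ci_low"] <= eq["r"]) and np.all(eq["r"] <= eq["ci_high"])
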