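"""Differential expression: CPM, dispersion estimation, NB exact test,
moderated t, BH-FDR and gating."""

import dataclasses
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncopanel.expression import (
    DEMode,
    DEThresholds,
    bh_fdr,
    call_de,
    cpm,
    equalize_library_sizes,
    estimate_common_dispersion,
    log_cpm,
    moderated_t,
    nb_de_table,
    nb_exact_test,
)
from oncopanel.panel_io import CountMatrix
from oncopanel.simulate import DeSim, SimConfig, simulate_counts


def _counts(values, samples=None):
    values = np.asarray(values)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=samples)


class TestCpm:
    def test_single_sample_arithmetic(self):
        df = _counts([[1], [1], [2]])
        assert list(cpm(df).iloc[:, 0]) == [250000, 250000, 500000]

    def test_scale_invariance(self):
        df = _counts([[3, 1], [5, 7], [2, 2]])
        doubled = df.copy()
        doubled["s0"] *= 2
        pd.testing.assert_series_equal(cpm(df)["s0"], cpm(doubled)["s0"])

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            cpm(_counts([[0], [0]]))

    def test_log_cpm_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        df = _counts(rng.integers(0, 500, size=(50, 4)))
        prior = 0.5
        expected = np.log2((df + prior) / (df.sum(axis=0) + 2 * prior) * 1e6)
        np.testing.assert_allclose(log_cpm(df, prior), expected, atol=1e-12)


class TestDispersion:
    def test_poisson_data_recovers_zero(self):
        rng = np.random.default_rng(7)
        mu = rng.lognormal(np.log(100), 0.5, size=500)
        df = _counts(rng.poisson(mu[:, None], size=(500, 6)))
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=df.columns)
        assert estimate_common_dispersion(df, groups) <= 0.01

    def test_nb_dispersion_recovered_across_seeds(self):
        phi = 0.2
        hats = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(np.log(150), 0.6, size=500)
            r = 1 / phi
            df = _counts(rng.negative_binomial(r, r / (r + mu[:, None]), size=(500, 8)))
            groups = pd.Series(["a"] * 4 + ["b"] * 4, index=df.columns)
            hats.append(estimate_common_dispersion(df, groups))
        assert all(0.15 <= h <= 0.25 for h in hats)

    def test_duplicated_samples_hit_grid_minimum(self):
        col = np.arange(1, 41)
        df = _counts(np.stack([col, col, col, col], axis=1))
        groups = pd.Series(["a", "a", "b", "b"], index=df.columns)
        assert estimate_common_dispersion(df, groups) <= 1.1e-6

    def test_all_zero_matrix_rejected(self):
        df = _counts(np.zeros((5, 4), dtype=int))
        groups = pd.Series(["a", "a", "b", "b"], index=df.columns)
        with pytest.raises(ValueError):
            estimate_common_dispersion(df, groups)


def poisson_split_p(counts, groups):
    """Exact-fraction enumeration of the binomial split test (phi = 0)."""
    y = np.asarray(counts)
    g = np.asarray(groups)
    labels = sorted(set(g))
    n1 = int((g == labels[0]).sum())
    n2 = int((g == labels[1]).sum())
    s1 = int(y[g == labels[0]].sum())
    z = int(y.sum())
    q = Fraction(n1, n1 + n2)
    pmf = [comb(z, s) * q**s * (1 - q) ** (z - s) for s in range(z + 1)]
    return float(sum(p for p in pmf if p <= pmf[s1]))


class TestNbExactTest:
    def test_equal_split_gives_p_one(self):
        y = np.array([10, 10, 10, 10])
        g = np.array(["a", "a", "b", "b"])
        assert nb_exact_test(y, g, 0.1) == 1.0

    def test_all_zero_gene_gives_p_one(self):
        assert nb_exact_test(np.zeros(4, dtype=int), np.array(["a", "a", "b", "b"]), 0.1) == 1.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.array([1, 2]), np.array(["a", "b"]), -0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_phi_zero_matches_exact_binomial_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 15, size=6)
        g = np.array(["a"] * 2 + ["b"] * 4)
        ours = nb_exact_test(y, g, 0.0)
        assert ours == pytest.approx(poisson_split_p(y, g), abs=1e-10)

    def test_symmetric_under_group_relabeling(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 200, size=8)
        g = np.array(["a"] * 4 + ["b"] * 4)
        swapped = np.where(g == "a", "b", "a")
        assert nb_exact_test(y, g, 0.15) == pytest.approx(
            nb_exact_test(y, swapped, 0.15), rel=1e-12
        )

    def test_null_type_one_error_in_band(self):
        config = SimConfig(seed=11, de=DeSim(n_up=0, n_down=0, n_group2=4, phi=0.1))
        cm, _ = simulate_counts(config)
        phi = estimate_common_dispersion(cm.counts, cm.groups)
        eq, _ = equalize_library_sizes(cm.counts)
        g = cm.groups.to_numpy()
        p = np.array([nb_exact_test(row, g, phi) for row in eq.to_numpy()])
        assert 0.035 <= (p < 0.05).mean() <= 0.065


class TestModeratedT:
    @staticmethod
    def _null_data(seed=5, n_genes=500, het=False):
        rng = np.random.default_rng(seed)
        sd = rng.choice([0.5, 1.0, 2.0], size=n_genes)[:, None] if het else 1.0
        x = pd.DataFrame(
            rng.normal(size=(n_genes, 8)) * sd,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=x.columns)
        return x, groups

    def test_d0_zero_equals_ordinary_t(self):
        x, groups = self._null_data(het=True)
        ours = moderated_t(x, groups, d0_override=0.0)
        ref = stats.ttest_ind(
            x.iloc[:, 4:], x.iloc[:, :4], axis=1, equal_var=True
        )
        np.testing.assert_allclose(ours["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(ours["p"], ref.pvalue, atol=1e-10)

    def test_d0_infinite_pools_variances(self):
        x, groups = self._null_data(het=True)
        ours = moderated_t(x, groups, d0_override=np.inf)
        assert ours["s2_posterior"].nunique() == 1

    def test_shrunk_variance_between_gene_and_prior(self):
        x, groups = self._null_data(het=True)
        fit = moderated_t(x, groups)
        d0, s0 = fit.attrs["d0"], fit.attrs["s0_sq"]
        assert 0 < d0 < np.inf
        raw = moderated_t(x, groups, d0_override=0.0)["s2_posterior"]
        lo = np.minimum(raw, s0)
        hi = np.maximum(raw, s0)
        assert ((fit["s2_posterior"] >= lo - 1e-12) & (fit["s2_posterior"] <= hi + 1e-12)).all()

    def test_null_type_one_and_ks(self):
        x, groups = self._null_data(seed=5, n_genes=2000)
        fit = moderated_t(x, groups)
        assert 0.035 <= (fit["p"] < 0.05).mean() <= 0.065
        assert stats.kstest(fit["p"], "uniform").statistic <= 0.03

    def test_unreplicated_design_rejected(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(10, 2)), columns=["s0", "s1"])
        groups = pd.Series(["a", "b"], index=x.columns)
        with pytest.raises(ValueError, match="NB"):
            moderated_t(x, groups)


def bh_bruteforce(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        j = np.arange(rank_idx, m)
        q[i] = min(np.minimum(p[order[j]] * m / (j + 1), 1.0))
    return q


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal(self):
        q = bh_fdr(np.full(10, 0.2))
        np.testing.assert_allclose(q, 0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, np.nan]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(bh_fdr(p), bh_bruteforce(p), atol=1e-12)

    def test_monotone_in_sorted_p_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallDe:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])

    def test_fc_and_q_gates(self):
        df = self._frame(
            [
                {"log2_fold_change": 1.5, "p": 1e-4, "q": 0.001},
                {"log2_fold_change": 0.9, "p": 1e-4, "q": 0.001},
                {"log2_fold_change": -2.0, "p": 1e-4, "q": 0.001},
                {"log2_fold_change": 3.0, "p": 0.5, "q": 0.6},
            ]
        )
        up, down, n = call_de(df, DEThresholds(), DEMode.NB_FDR)
        assert up == ["g0"] and down == ["g2"]
        assert n == {"total": 2, "up": 1, "down": 1}
        assert list(df["direction"]) == ["up", "ns", "down", "ns"]

    def test_modt_mode_uses_raw_p(self):
        df = self._frame([{"log2_fold_change": 1.5, "p": 0.03, "q": 0.4}])
        up, _, _ = call_de(df, DEThresholds(), DEMode.MODT_P)
        assert up == ["g0"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            call_de(self._frame([{"log2_fold_change": 0, "p": 1, "q": 1}]), DEThresholds(), "bogus")

    def test_planted_up_down_recovered_within_ten_percent(self):
        config = SimConfig(seed=21, de=DeSim(n_group2=4))
        cm, truth = simulate_counts(config)
        table = nb_de_table(cm, ("normal", "cancer"))
        up, down, n = call_de(table, DEThresholds(), DEMode.NB_FDR)
        assert n["total"] == n["up"] + n["down"]
        assert abs(n["up"] - 30) <= 3
        assert abs(n["down"] - 50) <= 5

    def test_relabeling_negates_fold_change(self):
        config = SimConfig(seed=22, de=DeSim(n_genes=200, n_group2=4, n_up=5, n_down=5))
        cm, _ = simulate_counts(config)
        fwd = nb_de_table(cm, ("normal", "cancer"))
        rev = nb_de_table(cm, ("cancer", "normal"))
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-9)
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-9
        )
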