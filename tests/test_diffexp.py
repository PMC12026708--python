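"""NB Wald test: dispersion estimation, calibration, DEG calling, BH."""

import numpy as np
import pandas as pd
import pytest

import tempodeg as td
from tempodeg.diffexp import ALPHA_MIN

from conftest import make_de_table


def bh_brute_force(p):
    """Independent step-up BH: adj_i = min_{j >= i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestDispersion:
    def test_poisson_gene_floors_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100, size=1000)
        labels = np.repeat(["a", "b"], 500)
        alpha = td.estimate_dispersion(y, np.ones(1000), labels)
        assert alpha < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        alpha_true, mu = 0.5, 200.0
        size = 1.0 / alpha_true
        y = rng.negative_binomial(size, size / (size + mu), size=1000)
        labels = np.repeat(["a", "b"], 500)
        alpha = td.estimate_dispersion(y, np.ones(1000), labels)
        assert 0.4 <= alpha <= 0.6

    def test_constant_counts_floor(self):
        alpha = td.estimate_dispersion(np.full(10, 7), np.ones(10), np.repeat(["a", "b"], 5))
        assert alpha == ALPHA_MIN


class TestWaldTest:
    @staticmethod
    def _two_group_exp(counts_a, counts_b):
        from tempodeg.io import CountExperiment

        counts = np.concatenate([counts_a, counts_b], axis=1)
        cdf = pd.DataFrame(
            counts,
            index=[f"g{i}" for i in range(counts.shape[0])],
            columns=[f"s{j}" for j in range(counts.shape[1])],
        )
        table = pd.DataFrame(
            {
                "group": ["sham"] * counts_a.shape[1] + ["injured_1d"] * counts_b.shape[1],
                "region": "FC",
                "subject": [f"p{j}" for j in range(counts.shape[1])],
            },
            index=cdf.columns,
        )
        return CountExperiment(counts=cdf, sample_table=table)

    def test_identical_groups_null_identity(self):
        block = np.array([[10, 20, 30], [5, 5, 5]])
        exp = self._two_group_exp(block, block)
        s = pd.Series(1.0, index=exp.sample_ids)
        res = td.wald_test(exp, s, ("sham", "injured_1d"))
        assert res.table["log2FC"].to_numpy() == pytest.approx(0.0)
        assert res.table["pvalue"].to_numpy() == pytest.approx(1.0)

    def test_group_swap_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(100, size=(20, 6))
        b = rng.poisson(150, size=(20, 6))
        exp = self._two_group_exp(a, b)
        s = pd.Series(1.0, index=exp.sample_ids)
        fwd = td.wald_test(exp, s, ("sham", "injured_1d"))
        rev = td.wald_test(exp, s, ("injured_1d", "sham"))
        assert fwd.table["log2FC"].to_numpy() == pytest.approx(-rev.table["log2FC"].to_numpy())
        assert fwd.table["pvalue"].to_numpy() == pytest.approx(rev.table["pvalue"].to_numpy())

    def test_wald_stat_is_lfc_over_se(self, default_de):
        _, _, _, _, de = default_de
        t = de["A"].table
        nonzero = t[t["se"] > 0]
        assert np.abs(nonzero["stat"] - nonzero["log2FC"] / nonzero["se"]).max() < 1e-10

    def test_planted_effect_recovered_across_replicates(self):
        """log2FC estimate lands in [1.5, 2.5] in >= 95% of replicates for a
        planted 2-fold-squared effect at n = 8 per group."""
        rng = np.random.default_rng(3)
        mu, alpha, n = 150.0, 0.05, 8
        size = 1.0 / alpha
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.negative_binomial(size, size / (size + mu), size=(1, n))
            b = rng.negative_binomial(size, size / (size + 4 * mu), size=(1, n))
            exp = self._two_group_exp(a, b)
            s = pd.Series(1.0, index=exp.sample_ids)
            res = td.wald_test(exp, s, ("sham", "injured_1d"))
            if 1.5 <= res.table["log2FC"].iloc[0] <= 2.5:
                hits += 1
        assert hits / reps >= 0.95

    def test_null_type_one_error_calibrated(self):
        spec = td.SimulationSpec(
            n_genes=2000,
            samples_per_group={"sham": 50, "injured_1d": 50},
            planted_temporal=[],
            planted_treatment=[],
            planted_modules=[],
            dispersion=0.1,
            seed=11,
        )
        exp, _ = td.simulate_counts(spec)
        s = td.size_factors(exp)
        res = td.wald_test(exp, s, ("sham", "injured_1d"))
        frac = (res.table["pvalue"] <= 0.05).mean()
        assert 0.04 <= frac <= 0.065

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(4)
        mu, alpha, n = 150.0, 0.1, 8
        size = 1.0 / alpha
        rates = []
        for lfc in (0.5, 1.0, 2.0):
            hits = 0
            for _ in range(60):
                a = rng.negative_binomial(size, size / (size + mu), size=(1, n))
                b = rng.negative_binomial(size, size / (size + mu * 2**lfc), size=(1, n))
                exp = self._two_group_exp(a, b)
                s = pd.Series(1.0, index=exp.sample_ids)
                res = td.wald_test(exp, s, ("sham", "injured_1d"))
                hits += len(td.call_degs(res))
            rates.append(hits / 60)
        assert rates[0] <= rates[1] <= rates[2]


class TestDEGCalls:
    def test_inclusive_thresholds(self):
        t = make_de_table(["a", "b", "c"], [1.0, 0.9, -1.2], [0.05, 0.01, 0.2])
        calls = td.call_degs(t)
        assert list(calls.index) == ["a"]
        assert calls.loc["a", "direction"] == "up"

    def test_toy_table_matches_brute_force_filter(self):
        rng = np.random.default_rng(5)
        lfc = rng.normal(0, 1.5, 6)
        p = rng.uniform(0, 0.2, 6)
        t = make_de_table([f"g{i}" for i in range(6)], lfc, p)
        calls = td.call_degs(t, p_max=0.05, lfc_min=1.0)
        expected = {f"g{i}" for i in range(6) if p[i] <= 0.05 and abs(lfc[i]) >= 1.0}
        assert set(calls.index) == expected

    def test_fdr_mode_uses_adjusted_p(self):
        t = make_de_table(["a", "b"], [2.0, 2.0], [0.01, 0.01], fdr=[0.04, 0.2])
        assert set(td.call_degs(t, fdr_mode=True).index) == {"a"}


class TestTopDEGs:
    def test_short_stratum_returns_fewer(self):
        t = make_de_table(
            ["a", "b", "c", "d"], [2.0, 1.5, -2.0, 1.0], [0.01] * 4, fdr=[0.01, 0.01, 0.01, 0.5]
        )
        up, down = td.top_degs(t, k=5)
        assert list(up.index) == ["a", "b"] and list(down.index) == ["c"]

    def test_lfc_tie_broken_by_smaller_fdr(self):
        t = make_de_table(["a", "b"], [2.0, 2.0], [0.01, 0.01], fdr=[0.03, 0.01])
        up, _ = td.top_degs(t, k=1)
        assert list(up.index) == ["b"]

    def test_ten_gene_table_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(10)]
        lfc = rng.normal(0, 2, 10)
        fdr = rng.uniform(0, 0.1, 10)
        t = make_de_table(genes, lfc, fdr, fdr=fdr)
        up, down = td.top_degs(t, k=5)
        stratum = [(g, l, f) for g, l, f in zip(genes, lfc, fdr) if f <= 0.05]
        oracle_up = [g for g, l, f in sorted(stratum, key=lambda x: (-x[1], x[2], x[0]))[:5] if l > 0]
        oracle_down = [g for g, l, f in sorted(stratum, key=lambda x: (x[1], x[2], x[0]))[:5] if l < 0]
        assert list(up.index) == oracle_up
        assert list(down.index) == oracle_down


def test_bh_matches_brute_force_step_up():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    for _ in range(200):
        p = rng.uniform(0, 1, rng.integers(1, 40))
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.abs(ours - bh_brute_force(p)).max() <= 1e-12
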