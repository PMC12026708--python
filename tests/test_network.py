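"""Co-expression network: bicor, adjacency, TOM, modules, eigengene tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import tempodeg as td
from tempodeg.network import _eigengene, _merge_modules


def bicor_pair_oracle(x, y):
    """Independent single-pair biweight midcorrelation (9-MAD tuning)."""

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def tom_brute_force(A):
    """Triple-loop mean-denominator TOM."""
    n = A.shape[0]
    tom = np.eye(n)
    k = np.array([A[i].sum() - A[i, i] for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + A[i, j]) / ((k[i] + k[j]) / 2 - A[i, j] + 1)
    return tom


def random_adjacency(rng, n):
    C = rng.uniform(-1, 1, size=(n, n))
    C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    return td.signed_adjacency(C, 6)


class TestBicor:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 20))
        cor = td.bicor_matrix(X)
        assert np.diag(cor) == pytest.approx(1.0)

    def test_antithetic_vectors(self):
        x = np.arange(10.0)
        X = np.vstack([x, -x])
        cor = td.bicor_matrix(X)
        assert cor[0, 1] == pytest.approx(-1.0)

    def test_matches_pairwise_formula_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 30))
        cor = td.bicor_matrix(X)
        for i in range(8):
            for j in range(i + 1, 8):
                assert cor[i, j] == pytest.approx(bicor_pair_oracle(X[i], X[j]), abs=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            td.bicor_matrix(np.ones((3, 3)))


class TestSignedAdjacency:
    def test_closed_forms(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert td.signed_adjacency(C, 12)[0, 1] == 1.0
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert td.signed_adjacency(C, 12)[0, 1] == 0.0
        C = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert td.signed_adjacency(C, 12)[0, 1] == pytest.approx(2.0**-12)


class TestTOM:
    def test_two_gene_network_equals_adjacency(self):
        a12 = 0.37
        A = np.array([[1.0, a12], [a12, 1.0]])
        tom = td.tom_similarity(A)
        assert tom[0, 1] == pytest.approx(a12)

    def test_perfect_overlap_reaches_one(self):
        # two genes adjacent at 1 whose shared neighbors saturate the
        # overlap: l = k_min - a, so TOM hits its upper bound of 1
        A = np.ones((4, 4))
        tom = td.tom_similarity(A)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            A = random_adjacency(rng, 20)
            assert np.abs(np.asarray(td.tom_similarity(A)) - tom_brute_force(A)).max() <= 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(3, 15))
    def test_bounds_symmetry_unit_diagonal(self, seed, n):
        A = random_adjacency(np.random.default_rng(seed), n)
        tom = np.asarray(td.tom_similarity(A))
        assert np.all(tom >= -1e-12) and np.all(tom <= 1 + 1e-12)
        assert np.allclose(tom, tom.T)
        assert np.diag(tom) == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        A = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            td.tom_similarity(A)


@pytest.fixture(scope="module")
def planted_blocks():
    spec = td.SimulationSpec(
        n_genes=150,
        planted_temporal=[],
        planted_treatment=[],
        planted_modules=[(30, 0.9, {}), (30, 0.9, {}), (30, 0.9, {})],
        seed=7,
    )
    exp, gt = td.simulate_counts(spec)
    norm = td.normalize_transform(exp, td.size_factors(exp))
    return norm.normexpr, gt.genes["module"].to_numpy()


class TestDetectModules:
    def test_planted_blocks_recovered(self, planted_blocks):
        normexpr, truth = planted_blocks
        ms = td.detect_modules(normexpr)
        assert adjusted_rand_score(truth, ms.assignments.to_numpy()) >= 0.8

    def test_pure_noise_mostly_unassigned(self):
        spec = td.SimulationSpec(
            n_genes=150, planted_temporal=[], planted_treatment=[], planted_modules=[], seed=7
        )
        exp, _ = td.simulate_counts(spec)
        norm = td.normalize_transform(exp, td.size_factors(exp))
        ms = td.detect_modules(norm.normexpr)
        assert (ms.assignments == 0).mean() >= 0.9

    def test_duplicated_block_halves_merge(self):
        # one latent factor driving two 20-gene halves -> eigengene cor ~ 1,
        # any split must merge at cut height 0.15
        rng = np.random.default_rng(3)
        z = rng.normal(size=30)
        X = 0.9 * np.tile(z, (40, 1)) + 0.3 * rng.normal(size=(40, 30))
        noise = rng.normal(size=(40, 30))
        ms = td.detect_modules(np.vstack([X, noise]))
        block_labels = set(ms.assignments.iloc[:40])
        assert len(block_labels - {0}) == 1

    def test_gene_order_permutation_invariance(self, planted_blocks):
        normexpr, _ = planted_blocks
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(normexpr))
        ms1 = td.detect_modules(normexpr)
        ms2 = td.detect_modules(normexpr.iloc[perm])
        a = ms1.assignments.to_numpy()[perm]
        b = ms2.assignments.to_numpy()
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_eigengene_sign_and_unit_variance(self, planted_blocks):
        normexpr, _ = planted_blocks
        ms = td.detect_modules(normexpr)
        X = normexpr.to_numpy()
        for m in ms.module_ids:
            score = ms.eigengenes[f"ME{m}"].to_numpy()
            assert score.std() == pytest.approx(1.0)
            members = ms.assignments.to_numpy() == m
            Z = X[members] - X[members].mean(axis=1, keepdims=True)
            Z /= np.where(Z.std(axis=1, keepdims=True) == 0, 1, Z.std(axis=1, keepdims=True))
            assert np.corrcoef(score, Z.mean(axis=0))[0, 1] >= 0

    def test_merge_is_idempotent(self, planted_blocks):
        normexpr, _ = planted_blocks
        ms = td.detect_modules(normexpr)
        labels = ms.assignments.to_numpy().copy()
        again = _merge_modules(normexpr.to_numpy(), labels, 0.15)
        assert np.array_equal(labels, again)


class TestModuleGroupTests:
    @staticmethod
    def _moduleset_with_scores(scores, groups):
        samples = [f"s{j}" for j in range(len(scores))]
        ms = td.ModuleSet(
            assignments=pd.Series([1] * 12, index=[f"g{i}" for i in range(12)]),
            eigengenes=pd.DataFrame({"ME1": scores}, index=samples),
            kme=pd.DataFrame({"ME1": np.ones(12)}, index=[f"g{i}" for i in range(12)]),
        )
        table = pd.DataFrame(
            {"group": groups, "region": "FC", "subject": samples}, index=samples
        )
        return ms, table

    def test_identical_distributions_not_significant(self):
        ms, table = self._moduleset_with_scores(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["sham"] * 3 + ["injured_1d"] * 3
        )
        out = td.module_group_test(ms, table)
        assert out["p_adj"].iloc[0] == 1.0

    def test_separated_groups_exact_p(self):
        ms, table = self._moduleset_with_scores(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], ["sham"] * 3 + ["injured_1d"] * 3
        )
        out = td.module_group_test(ms, table)
        assert out["pvalue"].iloc[0] == pytest.approx(0.1)
        assert out["exact"].iloc[0]

    def test_bonferroni_multiplier_is_number_of_pairs(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=16)
        groups = ["sham"] * 4 + ["injured_1d"] * 4 + ["injured_1wk"] * 4 + ["treated_1d"] * 4
        ms, table = self._moduleset_with_scores(scores, groups)
        out = td.module_group_test(ms, table)
        assert len(out) == 6
        assert np.allclose(
            out["p_adj"], np.minimum(1.0, out["pvalue"] * 6)
        )


class TestModuleTreatmentLabels:
    def test_planted_accelerated_and_dampened_modules(self, default_de):
        exp, truth, s, norm, _ = default_de
        ms = td.detect_modules(norm.normexpr)
        tests = td.module_group_test(ms, exp.sample_table)
        labels = td.classify_module_treatment(tests)
        t = truth.genes.loc[norm.normexpr.index]
        # planted module 2 shifts at 1wk + treated (accelerated); module 3
        # shifts at 1d only (dampened)
        for planted, expected in ((2, "accelerated"), (3, "dampened")):
            members = t.index[t["module"] == planted]
            detected = ms.assignments.loc[members].mode().iat[0]
            assert labels.loc[detected] == expected

    def test_no_group_differences_is_other(self):
        rng = np.random.default_rng(6)
        samples = [f"s{j}" for j in range(32)]
        groups = ["sham", "injured_1d", "injured_1wk", "treated_1d"] * 8
        ms = td.ModuleSet(
            assignments=pd.Series([1] * 12, index=[f"g{i}" for i in range(12)]),
            eigengenes=pd.DataFrame({"ME1": rng.normal(size=32)}, index=samples),
            kme=pd.DataFrame({"ME1": np.ones(12)}, index=[f"g{i}" for i in range(12)]),
        )
        table = pd.DataFrame({"group": groups, "region": "FC", "subject": samples}, index=samples)
        labels = td.classify_module_treatment(td.module_group_test(ms, table))
        assert labels.loc[1] == "other"

    def test_missing_group_is_error(self):
        ms, table = TestModuleGroupTests._moduleset_with_scores(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], ["sham"] * 3 + ["injured_1d"] * 3
        )
        tests = td.module_group_test(ms, table)
        with pytest.raises(ValueError, match="missing groups"):
            td.classify_module_treatment(tests)


def test_hub_genes_are_top_kme_members(planted_blocks):
    normexpr, _ = planted_blocks
    ms = td.detect_modules(normexpr)
    hubs = td.hub_genes(ms, k=5)
    for m in ms.module_ids:
        sub = hubs[hubs["module"] == m]
        assert len(sub) == 5
        members = ms.assignments.index[ms.assignments == m]
        top = ms.kme.loc[members, f"ME{m}"].nlargest(5)
        assert set(sub["gene"]) == set(top.index)
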