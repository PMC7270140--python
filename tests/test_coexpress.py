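"""Co-expression network: adjacency, TOM, module detection, meta-genes,
location tests and the panel classifier."""

import numpy as np
import pandas as pd
import pytest

from menimm.coexpress import (NetworkConfig, detect_modules, label_cytokines,
                              location_classifier, module_eigengene,
                              pick_soft_threshold, roc_auc, soft_adjacency,
                              top_module_genes, topological_overlap)
from menimm.coexpress import test_module_location as module_location_tests
from menimm.errors import DegenerateInputError, ValidationError
from menimm.types import ExpressionMatrix


def em(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, scale="log2", standardized=True)


def planted_blocks(rng, sizes=(50, 50), n_bg=0, n_samples=40, within=0.9):
    """Genes driven by per-block latent factors (within-block cor ~ `within`)."""
    blocks = []
    labels = []
    for b, size in enumerate(sizes, start=1):
        f = rng.normal(size=n_samples)
        lam = np.sqrt(within)
        noise = rng.normal(size=(size, n_samples))
        blocks.append(lam * f[None, :] + np.sqrt(1 - lam ** 2) * noise)
        labels += [b] * size
    if n_bg:
        blocks.append(rng.normal(size=(n_bg, n_samples)))
        labels += [0] * n_bg
    return em(np.vstack(blocks)), np.array(labels)


def tom_bruteforce(A):
    n = A.shape[0]
    k = A.sum(axis=0)
    T = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                T[i, j] = 1.0
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestSoftAdjacency:
    def test_powers_of_known_correlations(self):
        # two genes exactly correlated, one at cor 0.9 via construction
        t = np.linspace(-1, 1, 200)
        g3 = 0.9 * t + np.sqrt(1 - 0.81) * np.sin(37 * t)  # approx decorrelated part
        m = em(np.vstack([t, t, -t]))
        A = soft_adjacency(m, NetworkConfig(power=20))
        assert A[0, 1] == pytest.approx(1.0)
        assert A[0, 2] == pytest.approx(1.0)      # unsigned: |cor| = 1
        assert np.all(np.diag(A) == 0)

    def test_unsigned_value_at_09(self, rng):
        f = rng.normal(size=2000)
        x = f
        y = 0.9 * f + np.sqrt(1 - 0.81) * rng.normal(size=2000)
        m = em(np.vstack([x, y]))
        A = soft_adjacency(m, NetworkConfig(power=20))
        r = np.corrcoef(x, y)[0, 1]
        assert A[0, 1] == pytest.approx(abs(r) ** 20, rel=1e-10)

    def test_signed_mode(self, rng):
        x = rng.normal(size=100)
        m = em(np.vstack([x, -x]))
        A = soft_adjacency(m, NetworkConfig(power=2.0, network_type="signed"))
        assert A[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_named(self):
        m = em(np.vstack([np.ones(10), np.arange(10.0)]), genes=["flat", "ok"])
        with pytest.raises(DegenerateInputError, match="flat"):
            soft_adjacency(m, NetworkConfig())


class TestTOM:
    def test_hand_computed_three_node_cases(self):
        A = np.array([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]])
        T = topological_overlap(A)
        assert T[0, 1] == pytest.approx(0.5 / (0.5 + 1 - 0.5))
        K3 = np.ones((3, 3)) - np.eye(3)
        T3 = topological_overlap(K3)
        assert T3[0, 1] == pytest.approx((1 + 1) / (2 + 1 - 1))

    def test_zero_adjacency(self):
        T = topological_overlap(np.zeros((4, 4)))
        assert np.all(T[~np.eye(4, dtype=bool)] == 0)
        assert np.all(np.diag(T) == 1)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(3):
            A = rng.uniform(0, 1, (50, 50))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            assert np.abs(topological_overlap(A) - tom_bruteforce(A)).max() < 1e-12

    def test_asymmetric_rejected(self):
        A = np.array([[0, 0.2], [0.3, 0]])
        with pytest.raises(ValidationError):
            topological_overlap(A)


class TestDetectModules:
    def test_recovers_two_planted_blocks(self, rng):
        m, truth = planted_blocks(rng, sizes=(50, 50))
        cfg = NetworkConfig(power=6, min_module_size=30)
        labels = detect_modules(topological_overlap(soft_adjacency(m, cfg)), cfg)
        assert labels.max() == 2
        # block purity: each planted block maps to exactly one label
        for b in (1, 2):
            assert len(set(labels[truth == b])) == 1
        assert len(set(labels[truth == 1]) | set(labels[truth == 2])) == 2

    def test_small_cluster_goes_grey(self, rng):
        m, truth = planted_blocks(rng, sizes=(50, 10), n_bg=60)
        cfg = NetworkConfig(power=6, min_module_size=30)
        labels = detect_modules(topological_overlap(soft_adjacency(m, cfg)), cfg)
        assert np.all(labels[truth == 2] == 0)
        assert np.all(labels[truth == 1] == labels[truth == 1][0])
        assert labels[truth == 1][0] != 0

    def test_gene_order_equivariance(self, rng):
        m, _ = planted_blocks(rng, sizes=(40, 40), n_bg=20)
        cfg = NetworkConfig(power=6, min_module_size=30)
        tom = topological_overlap(soft_adjacency(m, cfg))
        labels = detect_modules(tom, cfg)
        perm = rng.permutation(m.n_genes)
        labels_perm = detect_modules(tom[np.ix_(perm, perm)], cfg)
        assert np.array_equal(labels_perm, labels[perm])

    def test_min_size_constraint_always_holds(self, rng):
        m, _ = planted_blocks(rng, sizes=(35, 45), n_bg=40)
        cfg = NetworkConfig(power=6, min_module_size=30)
        labels = detect_modules(topological_overlap(soft_adjacency(m, cfg)), cfg)
        for lab in set(labels) - {0}:
            assert (labels == lab).sum() >= 30


class TestEigengene:
    def test_identical_profiles_fully_explained(self, rng):
        profile = rng.normal(size=20)
        m = em(np.tile(profile, (5, 1)) * rng.uniform(1, 3, size=(5, 1)))
        mg, ve = module_eigengene(m, np.ones(5, dtype=int))
        assert ve[1] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(mg["ME1"], z)[0, 1]) == pytest.approx(1.0)

    def test_sign_aligned_with_mean_profile(self, rng):
        m, _ = planted_blocks(rng, sizes=(30,))
        labels = np.ones(30, dtype=int)
        mg, _ = module_eigengene(m, labels)
        Z = (m.values - m.values.mean(1, keepdims=True)) / m.values.std(1, keepdims=True)
        assert float(mg["ME1"].to_numpy() @ Z.mean(0)) >= 0

    def test_flipping_all_genes_leaves_metagene_invariant_up_to_alignment(self, rng):
        m, _ = planted_blocks(rng, sizes=(30,))
        labels = np.ones(30, dtype=int)
        mg1, _ = module_eigengene(m, labels)
        flipped = em(-m.values)
        mg2, _ = module_eigengene(flipped, labels)
        # same subspace; sign fixed by each matrix's own mean profile
        assert abs(np.corrcoef(mg1["ME1"], mg2["ME1"])[0, 1]) == pytest.approx(1.0)

    def test_two_orthogonal_half_modules(self, rng):
        a = np.sin(np.linspace(0, 8 * np.pi, 64))
        b = np.cos(np.linspace(0, 8 * np.pi, 64))
        rows = [a] * 10 + [b] * 10
        m = em(np.array(rows) + rng.normal(0, 1e-6, (20, 64)))
        _, ve = module_eigengene(m, np.ones(20, dtype=int))
        assert ve[1] == pytest.approx(0.5, abs=0.01)

    def test_unit_norm(self, rng):
        m, _ = planted_blocks(rng, sizes=(40, 40))
        mg, _ = module_eigengene(m, np.array([1] * 40 + [2] * 40))
        for col in mg.columns:
            assert np.linalg.norm(mg[col]) == pytest.approx(1.0)


def _meta(n_sb, n_conv, grades=None, seed=0):
    rng = np.random.default_rng(seed)
    n = n_sb + n_conv
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "study": ["A"] * n,
        "location": ["skull_base"] * n_sb + ["convexity"] * n_conv,
        "grade": grades if grades is not None else rng.choice([1, 2], n).tolist(),
        "age": rng.normal(56, 12, n).round(1),
        "sex": rng.choice(["M", "F"], n).tolist(),
    })


class TestModuleLocationTests:
    def test_extreme_separation(self):
        meta = _meta(20, 20)
        mg = pd.DataFrame({"ME1": [1.0 + 0.01 * i for i in range(20)]
                           + [-1.0 - 0.01 * i for i in range(20)]},
                          index=[f"s{i}" for i in range(40)])
        res = module_location_tests(mg, meta)
        assert res.loc["ME1", "mann_whitney_p"] < 1e-6

    def test_null_metagenes_have_uniform_p(self, rng):
        meta = _meta(30, 30, seed=1)
        mg = pd.DataFrame(rng.normal(size=(60, 1000)),
                          index=[f"s{i}" for i in range(60)],
                          columns=[f"ME{k}" for k in range(1000)])
        res = module_location_tests(mg, meta)
        frac = (res["mann_whitney_p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_grade_confounding_absorbed_by_adjustment(self, rng):
        # grade tracks location; metagene IS grade -> adjusted test must not
        # credit the metagene with the location signal
        n = 60
        grades = [2] * 25 + [1] * 5 + [1] * 25 + [2] * 5
        meta = _meta(30, 30, grades=grades, seed=2)
        mg = pd.DataFrame(
            {"ME1": np.array(grades, float) + rng.normal(0, 0.1, n)},
            index=[f"s{i}" for i in range(n)])
        res = module_location_tests(mg, meta)
        assert res.loc["ME1", "adjusted_p"] > 10 * res.loc["ME1", "mann_whitney_p"]


class TestCytokineLabels:
    def test_label_rules(self, rng):
        n = 50
        mgvec = rng.normal(size=n)
        exact = mgvec.copy()
        negative = -0.9 * mgvec + 0.1 * rng.normal(size=n)
        weak = 0.55 * (mgvec - mgvec.mean()) / mgvec.std() + \
            np.sqrt(1 - 0.55 ** 2) * rng.normal(size=n)
        m = ExpressionMatrix(["EXACT", "NEG", "WEAK"], [f"s{i}" for i in range(n)],
                             np.vstack([exact, negative, weak]), scale="log2",
                             standardized=True)
        mg = pd.DataFrame({"ME1": mgvec}, index=m.sample_ids)
        labels, missing = label_cytokines(mg, m, ["EXACT", "NEG", "WEAK", "ABSENT"])
        assert labels["ME1"] == ["EXACT"]
        assert missing == ["ABSENT"]


class TestTopGenes:
    def test_ranking_matches_bruteforce(self, rng):
        m, _ = planted_blocks(rng, sizes=(30,))
        mgvec = m.values.mean(axis=0)
        got = top_module_genes(m, mgvec, m.gene_ids, n=10)
        cors = {g: np.corrcoef(m.values[i], mgvec)[0, 1]
                for i, g in enumerate(m.gene_ids)}
        want = sorted(m.gene_ids, key=lambda g: (-cors[g], g))[:10]
        assert got == want

    def test_full_module_returned_sorted(self, rng):
        m, _ = planted_blocks(rng, sizes=(30,))
        mgvec = m.values[0]
        got = top_module_genes(m, mgvec, m.gene_ids, n=30)
        assert len(got) == 30 and got[0] == "g0"


class TestClassifier:
    def test_auc_rank_formula_equals_trapezoid(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            if y.min() == y.max():
                continue
            s = rng.normal(size=50)
            assert roc_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_three_point_hand_example(self):
        assert roc_auc(np.array([1, 0, 1]), np.array([0.8, 0.6, 0.4])) == 0.5

    def test_perfectly_ordered_scores(self, rng):
        m, truth = planted_blocks(rng, sizes=(10,), n_samples=40)
        meta = _meta(20, 20)
        # shift the module genes by location to force separation
        shift = np.array([8.0] * 20 + [0.0] * 20)
        m = em(m.values + shift[None, :])
        auc, roc = location_classifier(m, m.gene_ids[:5], meta)
        assert auc == 1.0
        assert {"fpr", "tpr"} <= set(roc.columns)

    def test_permuted_labels_give_chance_auc_out_of_fold(self, rng):
        """Under label permutation the out-of-fold AUC is centred on 0.5."""
        n = 100
        X = rng.normal(size=(10, n))
        m = em(X, samples=[f"s{i}" for i in range(n)])
        aucs = []
        for rep in range(25):
            perm = rng.permutation(n)
            meta = _meta(50, 50, seed=rep)
            meta["sample_id"] = [f"s{i}" for i in perm]
            auc, _ = location_classifier(m, m.gene_ids, meta, scheme="kfold",
                                         seed=rep)
            aucs.append(auc)
        assert 0.45 <= float(np.mean(aucs)) <= 0.55


class TestPickSoftThreshold:
    def test_row_per_candidate_power(self, rng):
        m, _ = planted_blocks(rng, sizes=(40, 40), n_bg=40)
        table = pick_soft_threshold(m, [1, 4, 8])
        assert list(table["power"]) == [1, 4, 8]

    def test_random_data_poor_fit_at_power_one(self, rng):
        m = em(rng.normal(size=(120, 30)))
        table = pick_soft_threshold(m, [1])
        assert table["sft_r2"].iloc[0] < 0.7
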