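import math

import numpy as np
import pandas as pd
import pytest

from dielomics import (
    adjacency_from_correlation,
    build_modules,
    detect_modules,
    mcc_scores,
    module_eigengene,
    module_timepoint_assign,
    pearson_matrix,
    pick_soft_threshold,
    tom_from_adjacency,
    zscore_by_gene,
)
from dielomics.errors import InputError, SelectionError

from conftest import make_matrix


def _zmat(vals, tps=None):
    vals = np.asarray(vals, dtype=float)
    tps = tps or ["MidDark1"] * vals.shape[1]
    return zscore_by_gene(make_matrix(vals + 1000.0, tps))


class TestPearson:
    def test_self_negation_and_hand_value(self):
        Z = _zmat([[1, 2, 3], [3, 2, 1], [1, 3, 2]])
        C = pearson_matrix(Z)
        assert C.iloc[0, 0] == pytest.approx(1.0)
        assert C.iloc[0, 1] == pytest.approx(-1.0)
        # x=[1,2,3], y=[1,3,2]: cov=0.5, sds=1 -> r=0.5
        assert C.iloc[0, 2] == pytest.approx(0.5)

    def test_constant_gene_zeroed_with_warning(self):
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        tps = ["MidDark1"] * 3
        Z = zscore_by_gene(make_matrix(vals, tps))
        with pytest.warns(UserWarning, match="constant"):
            C = pearson_matrix(Z)
        assert C.iloc[0, 1] == 0.0


def tom_bruteforce(a):
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTom:
    def test_zero_adjacency(self):
        A = pd.DataFrame(np.zeros((4, 4)))
        tom = tom_from_adjacency(A).to_numpy()
        assert np.allclose(tom, np.eye(4))

    def test_complete_unit_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = tom_from_adjacency(pd.DataFrame(a)).to_numpy()
        # (l + a) / (min k + 1 - a) = (1 + 1) / (2 + 1 - 1) = 1
        assert np.allclose(tom, 1.0)

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = tom_from_adjacency(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom_bruteforce(a), atol=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.random((30, 30))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = tom_from_adjacency(pd.DataFrame(a)).to_numpy()
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            tom_from_adjacency(pd.DataFrame([[0.0, 1.5], [1.5, 0.0]]))


class TestSoftThreshold:
    def _corr_from_hub_network(self, seed=0, n=60, m=20):
        """Expression driven by a few latent hubs -> heavy-tailed connectivity."""
        rng = np.random.default_rng(seed)
        latents = rng.normal(size=(3, m))
        load = rng.choice([0, 0, 0, 1], size=(n, 3)) * rng.normal(1, 0.2, (n, 3))
        vals = load @ latents + rng.normal(0, 0.7, size=(n, m))
        return pd.DataFrame(np.corrcoef(vals))

    def test_choice_matches_independent_fit_table(self):
        C = self._corr_from_hub_network()
        candidates = list(range(1, 9))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pick_soft_threshold(C, candidates, r2_target=0.8)
        # independent regression per power, same 10-bin convention
        qualifying = []
        for beta in candidates:
            a = np.abs(C.to_numpy()) ** beta
            np.fill_diagonal(a, 0)
            k = a.sum(axis=1)
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max() + 1e-12, 11)
            idx = np.digitize(k, edges) - 1
            xs, ys = [], []
            for b in range(10):
                sel = idx == b
                if sel.sum():
                    xs.append(np.log10(k[sel].mean()))
                    ys.append(np.log10(sel.sum() / k.size))
            slope, intercept = np.polyfit(xs, ys, 1)
            pred = slope * np.array(xs) + intercept
            ss_res = ((np.array(ys) - pred) ** 2).sum()
            ss_tot = ((np.array(ys) - np.mean(ys)) ** 2).sum()
            r2 = 1 - ss_res / ss_tot
            row = res.fit_table[res.fit_table["power"] == beta].iloc[0]
            assert row["r2"] == pytest.approx(r2, abs=1e-9)
            if r2 >= 0.8 and slope < 0:
                qualifying.append(beta)
        expected = min(qualifying) if qualifying else 6
        assert res.beta == expected
        assert res.fallback == (not qualifying)

    def test_fallback_warns_and_returns_six(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 8))
        C = pd.DataFrame(np.corrcoef(vals))
        with pytest.warns(UserWarning, match="beta = 6"):
            res = pick_soft_threshold(C, [1, 2], r2_target=0.999)
        assert res.beta == 6 and res.fallback

    def test_bad_candidates_rejected(self):
        with pytest.raises(InputError):
            pick_soft_threshold(pd.DataFrame(np.eye(3)), [])


class TestModules:
    def test_block_diagonal_two_modules(self):
        n = 10
        C = np.eye(2 * n)
        C[:n, :n] = 1.0
        C[n:, n:] = 1.0
        A = adjacency_from_correlation(pd.DataFrame(C), beta=6)
        tom = tom_from_adjacency(A)
        ms = detect_modules(tom, min_size=5)
        genes = list(tom.index)
        first = set(ms.assignment[genes[:n]])
        second = set(ms.assignment[genes[n:]])
        assert len(first) == 1 and len(second) == 1 and first != second
        assert "unassigned" not in first | second

    def test_min_size_unassigns_everything(self):
        C = pd.DataFrame(np.eye(6))
        tom = tom_from_adjacency(adjacency_from_correlation(C, 6))
        ms = detect_modules(tom, min_size=50)
        assert set(ms.assignment) == {"unassigned"}

    def test_gene_permutation_preserves_partition(self):
        rng = np.random.default_rng(7)
        import dielomics as d
        cfg = d.SimExprConfig(n_genes=150, frac_light_pref=0, frac_dark_pref=0,
                              module_specs=d.default_module_specs()[:2], seed=7)
        X, _ = d.simulate_diel_counts(cfg)
        Z = zscore_by_gene(X)
        C = pearson_matrix(Z)
        A = adjacency_from_correlation(C, 6)
        tom = tom_from_adjacency(A)
        ms1 = detect_modules(tom)
        perm = rng.permutation(len(tom))
        tom_p = tom.iloc[perm, perm]
        ms2 = detect_modules(tom_p)

        def parts(assign):
            out = {}
            for g, m in assign.items():
                if m != "unassigned":
                    out.setdefault(m, set()).add(g)
            return {frozenset(v) for v in out.values()}

        assert parts(ms1.assignment) == parts(ms2.assignment)


class TestEigengene:
    def test_identical_genes_rank_one(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        Z = _zmat(np.vstack([profile] * 4))
        eig, ve = module_eigengene(Z, Z.gene_ids)
        assert ve == pytest.approx(1.0)
        centered = profile - profile.mean()
        expected = centered / np.linalg.norm(centered)
        assert np.allclose(np.abs(eig), np.abs(expected))
        assert np.dot(eig, centered) > 0

    def test_two_gene_closed_form(self):
        Z = _zmat(np.array([[1.0, 2.0, 4.0, 3.0], [2.0, 1.0, 5.0, 4.0]]))
        eig, ve = module_eigengene(Z, Z.gene_ids)
        X = Z.values.to_numpy()
        X = X - X.mean(axis=1, keepdims=True)
        G = X @ X.T  # 2x2 Gram; analytic top eigenpair
        tr, det = G.trace(), np.linalg.det(G)
        lam = tr / 2 + math.sqrt(tr ** 2 / 4 - det)
        lam2 = tr / 2 - math.sqrt(tr ** 2 / 4 - det)
        v = np.array([G[0, 1], lam - G[0, 0]])
        v = v / np.linalg.norm(v)
        e = v @ X
        e = e / np.linalg.norm(e)
        if np.dot(e, X.mean(axis=0)) < 0:
            e = -e
        assert np.allclose(eig.to_numpy(), e, atol=1e-9)
        assert ve == pytest.approx(lam / (lam + lam2))

    def test_sign_convention_under_flips(self):
        rng = np.random.default_rng(8)
        vals = np.vstack([rng.normal(size=5)] * 3) + rng.normal(0, 0.1, (3, 5))
        Z = _zmat(vals)
        eig, _ = module_eigengene(Z, Z.gene_ids)
        mean_profile = Z.values.to_numpy().mean(axis=0)
        assert np.corrcoef(eig, mean_profile)[0, 1] >= 0

    def test_constant_module_rejected(self):
        Z = _zmat(np.zeros((3, 4)))
        with pytest.raises(SelectionError):
            module_eigengene(Z, Z.gene_ids)


class TestTimepointAssign:
    def _design(self):
        tps = [tp for tp in ["MidDark1", "Pre-Dawn1", "MidLight1"] for _ in range(4)]
        return pd.Series(tps, index=[f"s{i}" for i in range(12)])

    def test_indicator_eigengene_perfect_match(self):
        tps = self._design()
        ind = (tps == "Pre-Dawn1").astype(float)
        eig = pd.DataFrame([ind.to_numpy()], index=["M1"], columns=tps.index)
        table, assign = module_timepoint_assign(eig, tps)
        row = table[(table.module == "M1") & (table.timepoint == "Pre-Dawn1")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert assign["M1"] == "Pre-Dawn1"

    def test_shifted_indicator_matches_hand_pearson(self):
        tps = self._design()
        e = np.roll((tps == "Pre-Dawn1").astype(float).to_numpy(), 1)
        eig = pd.DataFrame([e], index=["M1"], columns=tps.index)
        table, _ = module_timepoint_assign(eig, tps)
        ind = (tps == "Pre-Dawn1").astype(float).to_numpy()
        ec, ic = e - e.mean(), ind - ind.mean()
        hand_r = (ec * ic).sum() / math.sqrt((ec ** 2).sum() * (ic ** 2).sum())
        row = table[(table.module == "M1") & (table.timepoint == "Pre-Dawn1")].iloc[0]
        assert row["r"] == pytest.approx(hand_r, abs=1e-12)

    def test_thin_timepoint_rejected(self):
        tps = pd.Series(["MidDark1", "MidDark1", "Pre-Dawn1"],
                        index=["s0", "s1", "s2"])
        eig = pd.DataFrame([[1.0, 0.0, 0.0]], index=["M1"], columns=tps.index)
        with pytest.raises(InputError):
            module_timepoint_assign(eig, tps)


def brute_force_mcc(adj):
    """All maximal cliques by exhaustive ordered growth + maximality check."""
    nodes = sorted(adj)
    cliques = []

    def grow(cur, cand):
        if cur and all(
                any(w not in adj[u] for w in cur)
                for u in nodes if u not in cur):
            if len(cur) >= 2:
                cliques.append(list(cur))
        for i, v in enumerate(cand):
            grow(cur + [v], [u for u in cand[i + 1:] if u in adj[v]])

    grow([], nodes)
    scores = {v: 0 for v in nodes}
    for c in cliques:
        for v in c:
            scores[v] += math.factorial(len(c) - 1)
    return scores


class TestMcc:
    def _frame(self, edges, nodes):
        m = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for a, b in edges:
            m.loc[a, b] = m.loc[b, a] = 1.0
        return m

    def test_triangle(self):
        m = self._frame([("a", "b"), ("b", "c"), ("a", "c")], list("abc"))
        out = mcc_scores(m, edge_threshold=0.5)
        assert out.scores.to_dict() == {"a": 2, "b": 2, "c": 2}

    def test_path(self):
        m = self._frame([("a", "b"), ("b", "c")], list("abc"))
        out = mcc_scores(m, edge_threshold=0.5)
        assert out.scores.to_dict() == {"a": 1, "b": 2, "c": 1}

    def test_isolated_vertex_zero(self):
        m = self._frame([("a", "b")], list("abc"))
        out = mcc_scores(m, edge_threshold=0.5)
        assert out.scores["c"] == 0

    def test_triangle_free_equals_degree(self):
        import networkx as nx
        G = nx.cycle_graph(7)  # C7 is triangle-free
        m = pd.DataFrame(nx.to_numpy_array(G))
        out = mcc_scores(m, edge_threshold=0.5)
        for v in G.nodes:
            assert out.scores[v] == G.degree[v]

    def test_node_guard(self):
        m = pd.DataFrame(np.zeros((11, 11)))
        with pytest.raises(InputError, match="guard"):
            mcc_scores(m, edge_threshold=0.5, max_nodes=10)

    def test_matches_bruteforce_random_graph(self):
        import networkx as nx
        for seed in range(5):
            G = nx.gnp_random_graph(15, 0.3, seed=seed)
            m = pd.DataFrame(nx.to_numpy_array(G))
            out = mcc_scores(m, edge_threshold=0.5)
            adj = {v: set(G.neighbors(v)) for v in G.nodes}
            assert out.scores.to_dict() == brute_force_mcc(adj)


def test_spike_module_assignment_property():
    """A planted one-time-point spike module lands on its true time point."""
    import dielomics as d
    hits = 0
    for seed in range(10):
        cfg = d.SimExprConfig(
            n_genes=120, frac_light_pref=0, frac_dark_pref=0,
            module_specs=[d.default_module_specs()[3]], seed=seed)
        X, truth = d.simulate_diel_counts(cfg)
        Z = zscore_by_gene(X)
        C = pearson_matrix(Z)
        tom = tom_from_adjacency(adjacency_from_correlation(C, 6))
        ms = build_modules(Z, tom)
        spike_genes = truth.module_assignment.dropna().index
        mods = ms.assignment[spike_genes].mode()
        if len(mods) and ms.tp_assignment is not None:
            if ms.tp_assignment.get(mods[0]) == "MidDark2":
                hits += 1
    assert hits >= 9
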