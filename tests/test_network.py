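import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rosalnc.io_formats import ValidationError
from rosalnc.network import (
    GREY,
    ModuleAssignment,
    NetworkParams,
    adjacency,
    compute_eigengenes,
    detect_modules,
    merge_modules,
    module_eigengene,
    module_trait,
    run_network,
    tom,
    tom_dissimilarity,
)
from rosalnc.synthetic import simulate_module_expression, simulate_trait_vectors


def tom_oracle(A: np.ndarray) -> np.ndarray:
    """Literal double-loop evaluation of the topological overlap formula."""
    n = A.shape[0]
    T = np.eye(n)
    k = A.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def random_adjacency(rng, n=8):
    M = rng.uniform(0, 1, size=(n, n))
    A = (M + M.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


class TestAdjacency:
    def test_powers_of_correlation(self):
        x = np.arange(10.0)
        expr = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        A = adjacency(expr, power=6)
        assert A[0, 1] == pytest.approx(1.0)
        assert A[0, 0] == 0.0

    def test_hand_power_example(self):
        # cor = -0.8 at beta 6 -> 0.8^6 = 0.262144
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        e = rng.normal(size=2000)
        # construct y with exact sample correlation -0.8 via orthogonalization
        xc = (x - x.mean()) / x.std()
        ec = e - e.mean()
        ec -= (ec @ xc) / (xc @ xc) * xc
        ec /= ec.std()
        y = -0.8 * xc + np.sqrt(1 - 0.64) * ec
        A = adjacency(pd.DataFrame([xc, y]), power=6)
        assert A[0, 1] == pytest.approx(0.262144, abs=1e-9)

    def test_constant_row_gets_zero(self):
        expr = pd.DataFrame([[1.0] * 8, list(range(8))], index=["const", "x"])
        A = adjacency(expr)
        assert A[0, 1] == 0.0


class TestTom:
    def test_two_node_tom_equals_adjacency(self):
        for a in (0.0, 0.3, 0.99):
            A = np.array([[0.0, a], [a, 0.0]])
            T = tom(A)
            assert T[0, 1] == pytest.approx(a, abs=1e-15)
            assert T[0, 0] == 1.0

    def test_three_node_hand_value(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 0.0)
        T = tom(A)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert np.allclose(T[~np.eye(3, dtype=bool)], 0.5)

    def test_zero_adjacency_zero_overlap(self):
        T = tom(np.zeros((4, 4)))
        assert np.allclose(T, np.eye(4))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            A = random_adjacency(rng)
            assert np.allclose(tom(A), tom_oracle(A), atol=1e-12)

    def test_symmetry_range_and_diagonal(self):
        rng = np.random.default_rng(9)
        A = random_adjacency(rng, n=12)
        T = tom(A)
        assert np.allclose(T, T.T)
        assert T.min() >= 0 and T.max() <= 1 + 1e-12
        assert np.allclose(np.diag(T), 1.0)

    def test_asymmetric_input_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 0.5
        with pytest.raises(ValidationError):
            tom(A)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        expr, labels, _traj = simulate_module_expression(
            n_modules=2, module_size_range=(10, 10), n_samples=24, noise_sd=0.1, seed=4
        )
        diss = tom_dissimilarity(expr)
        assignment = detect_modules(diss, ids=list(expr.index))
        detected = [assignment.labels[i] for i in expr.index]
        planted = [labels[i] for i in expr.index]
        assert len(assignment.modules) == 2
        assert adjusted_rand_score(planted, detected) == 1.0

    def test_identical_rows_single_module(self):
        expr = pd.DataFrame(
            np.tile(np.arange(20.0), (8, 1)) + np.random.default_rng(0).normal(0, 1e-6, (8, 20)),
            index=[f"t{i}" for i in range(8)],
        )
        diss = tom_dissimilarity(expr)
        assignment = detect_modules(diss, ids=list(expr.index))
        assert len(assignment.modules) == 1
        assert GREY not in assignment.labels.values()

    def test_fewer_than_min_module_size_all_grey(self):
        diss = np.zeros((5, 5))
        assignment = detect_modules(diss, NetworkParams(min_module_size=6))
        assert set(assignment.labels.values()) == {GREY}

    def test_colors_ordered_by_decreasing_size(self):
        expr, _labels, _ = simulate_module_expression(
            n_modules=3, module_size_range=(6, 12), n_samples=24, noise_sd=0.1, seed=2
        )
        diss = tom_dissimilarity(expr)
        assignment = detect_modules(diss, ids=list(expr.index))
        sizes = assignment.sizes.drop(GREY, errors="ignore")
        ordered = sorted(
            (m for m in sizes.index), key=lambda m: -sizes[m]
        )
        from rosalnc.network import MODULE_COLORS

        assert list(sizes.loc[MODULE_COLORS[: len(sizes)]].values) == [
            sizes[m] for m in ordered
        ]


class TestEigengene:
    def test_identical_members_give_standardized_common_vector(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        expr = pd.DataFrame([v, v, v], index=list("abc"))
        me = module_eigengene(expr).to_numpy()
        z = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(me, z, atol=1e-9)

    def test_sign_oriented_toward_first_member_on_tie(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 0.0])
        expr = pd.DataFrame([v, -v], index=["x", "negx"])
        me = module_eigengene(expr).to_numpy()
        cor = np.corrcoef(me, v)[0, 1]
        assert cor > 0  # tie broken toward the first member

    def test_recovers_planted_trajectory(self):
        expr, labels, traj = simulate_module_expression(
            n_modules=1, module_size_range=(12, 12), n_samples=30, noise_sd=0.2, seed=6
        )
        me = module_eigengene(expr).to_numpy()
        r = np.corrcoef(me, traj[0])[0, 1]
        assert abs(r) >= 0.95

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            module_eigengene(pd.DataFrame([[1.0, 2.0, 3.0]]))


class TestMerge:
    def _assignment_with_shared_trajectory(self):
        rng = np.random.default_rng(12)
        traj = rng.normal(size=24)
        rows, ids = [], []
        for m in range(2):
            for k in range(8):
                rows.append(traj * rng.uniform(0.9, 1.1) + rng.normal(0, 0.1, 24))
                ids.append(f"m{m}_{k}")
        expr = pd.DataFrame(rows, index=ids)
        labels = {i: ("turquoise" if i.startswith("m0") else "blue") for i in ids}
        return ModuleAssignment(labels), expr

    def test_shared_trajectory_modules_merge(self):
        assignment, expr = self._assignment_with_shared_trajectory()
        merged = merge_modules(assignment, expr)
        assert len(merged.modules) == 1

    def test_orthogonal_modules_stay_separate(self):
        expr, labels, _ = simulate_module_expression(
            n_modules=2, module_size_range=(8, 8), n_samples=24, noise_sd=0.1, seed=3
        )
        assignment = ModuleAssignment(
            {i: ("turquoise" if m == 0 else "blue") for i, m in labels.items()}
        )
        merged = merge_modules(assignment, expr)
        assert len(merged.modules) == 2

    def test_single_module_unchanged_and_fixed_point(self):
        expr, labels, _ = simulate_module_expression(
            n_modules=1, module_size_range=(8, 8), n_samples=24, seed=5
        )
        assignment = ModuleAssignment({i: "turquoise" for i in labels})
        merged = merge_modules(assignment, expr)
        assert merged.labels == assignment.labels
        again = merge_modules(merged, expr)
        assert again.labels == merged.labels

    def test_module_count_never_increases(self):
        expr, labels, _ = simulate_module_expression(
            n_modules=4, module_size_range=(6, 8), n_samples=24, seed=9
        )
        assignment = detect_modules(
            tom_dissimilarity(expr), ids=list(expr.index)
        )
        merged = merge_modules(assignment, expr)
        assert len(merged.modules) <= len(assignment.modules)


class TestModuleTrait:
    def test_compound_equal_to_eigengene_ranks_first_with_r_one(self):
        expr, labels, traj = simulate_module_expression(
            n_modules=3, module_size_range=(8, 8), n_samples=24, seed=13
        )
        assignment = detect_modules(tom_dissimilarity(expr), ids=list(expr.index))
        mes = compute_eigengenes(expr, assignment)
        first_module = mes.columns[0]
        volatile = pd.DataFrame(
            [mes[first_module].to_numpy()], index=["geraniol"], columns=mes.index
        )
        table = module_trait(mes, volatile)
        top_module, top_r = table.top3["geraniol"][0]
        assert top_module == first_module
        assert top_r == pytest.approx(1.0)

    def test_independent_noise_still_returns_three_modules(self):
        expr, labels, _ = simulate_module_expression(
            n_modules=4, module_size_range=(6, 8), n_samples=24, seed=14
        )
        assignment = detect_modules(tom_dissimilarity(expr), ids=list(expr.index))
        mes = compute_eigengenes(expr, assignment)
        rng = np.random.default_rng(0)
        volatile = pd.DataFrame(
            [rng.normal(size=len(mes))], index=["noise"], columns=mes.index
        )
        table = module_trait(mes, volatile)
        assert len(table.top3["noise"]) == 3
        assert max(abs(r) for _m, r in table.top3["noise"]) < 0.9

    def test_constant_compound_skipped(self):
        expr, labels, _ = simulate_module_expression(
            n_modules=2, module_size_range=(6, 6), n_samples=20, seed=15
        )
        assignment = detect_modules(tom_dissimilarity(expr), ids=list(expr.index))
        mes = compute_eigengenes(expr, assignment)
        volatile = pd.DataFrame(
            [[1.0] * len(mes)], index=["flat"], columns=mes.index
        )
        table = module_trait(mes, volatile)
        assert "flat" not in table.top3


class TestEndToEnd:
    def test_planted_modules_and_links_recovered(self):
        expr, labels, traj = simulate_module_expression(seed=21)
        links = [(f"c{i}", i % traj.shape[0], 0.9) for i in range(10)]
        volatile = simulate_trait_vectors(traj, links, seed=21)
        assignment, table = run_network(expr, volatile)
        planted = [labels[i] for i in expr.index]
        detected = [assignment.labels[i] for i in expr.index]
        assert adjusted_rand_score(planted, detected) >= 0.9
        # linked module (by max member overlap) should usually rank top-3
        hits = 0
        for name, m, _r in links:
            members = {i for i, lab in labels.items() if lab == m}
            best = max(
                assignment.modules,
                key=lambda mod: len(set(assignment.members(mod)) & members),
            )
            hits += best in [mod for mod, _ in table.top3[name]]
        assert hits >= 9

    def test_too_few_samples_rejected(self):
        expr, _labels, _ = simulate_module_expression(n_samples=10, seed=1)
        with pytest.raises(ValueError, match="15"):
            tom_dissimilarity(expr)
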