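"""Iterative-PCA clustering engine: primitives and recursion behavior."""

import numpy as np
import pytest
from sklearn.base import clone

import finestrat as fs
from finestrat.cluster import effective_support, mixture_split, node_pca, rubikclust, standardize


# -- standardize ------------------------------------------------------------


def test_standardize_hand_case():
    Z, kept = standardize(np.array([[0.0], [1.0], [2.0]]))
    scale = np.sqrt(2 * 0.5 * 0.5)
    np.testing.assert_allclose(Z[:, 0], np.array([-1, 0, 1]) / scale)
    assert kept.tolist() == [0]


def test_standardize_drops_monomorphic_and_centers():
    X = np.array([[0.0, 2.0, 1.0], [0.0, 2.0, 2.0], [0.0, 2.0, 0.0]])
    Z, kept = standardize(X)
    assert kept.tolist() == [2]
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)


def test_standardize_rejects_missing():
    with pytest.raises(ValueError, match="imputed"):
        standardize(np.array([[0.0, -1.0], [1.0, 2.0]]))


# -- node_pca ---------------------------------------------------------------


def test_pca_eigenvalue_sum_conserves_variance():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 3, size=(30, 80)).astype(float)
    Z, _ = standardize(X)
    ev, _, _ = node_pca(Z)
    assert ev.sum() == pytest.approx((Z**2).sum() / (Z.shape[0] - 1))


def test_pca_agrees_with_brute_force_svd():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(20, 50))
    Z -= Z.mean(axis=0)
    ev, scores, _ = node_pca(Z, k=5)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    np.testing.assert_allclose(ev[:19], s[:19] ** 2 / 19, atol=1e-8)
    # scores reproduce the SVD up to the documented sign convention
    np.testing.assert_allclose(np.abs(scores), np.abs(U[:, :5] * s[:5]), atol=1e-8)


def test_pca_mean_shift_separates_on_pc1():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 100))
    X[:20] += 4.0
    X -= X.mean(axis=0)
    _, scores, _ = node_pca(X, k=3)
    side = scores[:, 0] > 0
    assert side[:20].all() != side[20:].any()  # PC1 splits the two blocks


def test_pca_sign_convention_largest_loading_positive():
    rng = np.random.default_rng(3)
    Z = rng.normal(size=(15, 40))
    Z -= Z.mean(axis=0)
    ev, scores, _ = node_pca(Z, k=3)
    for j in range(3):
        loading = Z.T @ scores[:, j]
        assert loading[np.argmax(np.abs(loading))] > 0


# -- eigenfit ---------------------------------------------------------------


def test_eigenfit_flat_spectrum_is_zero():
    assert fs.eigenfit(np.ones(10)) == 0.0


def test_eigenfit_single_dominant_gap():
    ev = np.array([100.0] + [1.0] * 9)
    assert fs.eigenfit(ev) == pytest.approx(2.0)


def test_eigenfit_ignores_nonpositive_and_pads():
    ev = np.array([10.0, 1.0, 0.0, -0.5])
    # only (10, 1) are positive; padding with 1.0 adds zero gaps
    assert fs.eigenfit(ev, n_eigs_fit=10) == pytest.approx(1.0)


def test_eigenfit_gap_beyond_window_invisible():
    ev = np.concatenate([np.ones(10) * 5.0, [0.005]])
    assert fs.eigenfit(ev, n_eigs_fit=10) == 0.0
    assert fs.eigenfit(ev, n_eigs_fit=11) == pytest.approx(3.0)


def test_effective_support_counts_carrying_samples():
    u = np.zeros((100, 2))
    u[0, 0] = 1.0  # singleton component
    u[:, 1] = 1.0 / 10  # spread over all 100 samples equally
    support = effective_support(u)
    assert support[0] == pytest.approx(1.0)
    assert support[1] == pytest.approx(100.0)


# -- rubikclust -------------------------------------------------------------


def test_rubik_recovers_two_separated_clouds():
    rng = np.random.default_rng(4)
    cloud = rng.normal(scale=1.0, size=(60, 3))
    shift = np.array([10.0, 10.0, 10.0]) / np.sqrt(3)  # diagonal separation
    S = np.vstack([cloud[:30], cloud[30:] + 10 * shift])
    labels = rubikclust(S)
    assert labels is not None
    assert len(np.unique(labels)) == 2
    assert len(np.unique(labels[:30])) == 1 and len(np.unique(labels[30:])) == 1
    assert labels[0] != labels[-1]


def test_rubik_no_separation_on_single_gaussian():
    rng = np.random.default_rng(5)
    assert rubikclust(rng.normal(size=(200, 3))) is None


def test_rubik_peels_far_outlier():
    rng = np.random.default_rng(6)
    S = rng.normal(size=(80, 3))
    S[-1] = [20.0, 0.0, 0.0]
    labels = rubikclust(S)
    assert labels is not None
    counts = np.bincount(labels)
    assert sorted(counts.tolist()) == [1, 79]
    assert labels[-1] != labels[0]


def test_rubik_multiway_peels_outliers_strung_along_axis():
    rng = np.random.default_rng(7)
    S = rng.normal(size=(100, 3))
    S[-2] = [25.0, 0.0, 0.0]
    S[-1] = [50.0, 0.0, 0.0]
    labels = rubikclust(S)
    assert labels is not None
    assert len(np.unique(labels)) == 3  # cloud + two singletons


def test_rubik_tiny_input_returns_none():
    assert rubikclust(np.zeros((3, 3))) is None


# -- mixture_split ----------------------------------------------------------


def test_mixture_recovers_separated_gaussians():
    rng = np.random.default_rng(8)
    S = np.vstack([rng.normal(size=(50, 3)), rng.normal(size=(50, 3)) + 8.0])
    labels = mixture_split(S, random_state=0)
    assert labels is not None
    assert len(np.unique(labels[:50])) == 1 and len(np.unique(labels[50:])) == 1
    assert labels[0] != labels[-1]


def test_mixture_prefers_single_component_on_one_gaussian():
    none_count = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        if mixture_split(rng.normal(size=(120, 3)), random_state=seed) is None:
            none_count += 1
    assert none_count >= 18  # BIC keeps one component in >= 90% of replicates


def test_mixture_deterministic_for_fixed_seed():
    rng = np.random.default_rng(9)
    S = np.vstack([rng.normal(size=(40, 3)), rng.normal(size=(40, 3)) + 5.0])
    a = mixture_split(S, random_state=3)
    b = mixture_split(S, random_state=3)
    np.testing.assert_array_equal(a, b)


# -- engine -----------------------------------------------------------------


def test_single_population_yields_single_group(simulate_pops):
    ds = simulate_pops(1, 0.005, 100, 4000, seed=13)
    est = fs.IterativePCAClustering(random_state=0).fit(ds.dosages.astype(float))
    assert est.n_groups_ == 1
    assert len(est.tree_.outlier_groups) == 0


def test_two_diverged_populations_split(simulate_pops):
    ds = simulate_pops(2, 0.02, 60, 6000, seed=17)
    est = fs.IterativePCAClustering(random_state=0).fit(ds.dosages.astype(float))
    truth = np.array(ds.population_labels())
    assert est.n_groups_ == 2
    for g in est.tree_.groups:
        assert len(set(truth[g.members])) == 1  # pure groups


def test_min_fst_gate_rejects_panmictic_split(simulate_pops):
    # force an artificially high threshold so only the FST gate can stop a
    # mixture split of a panmictic cloud
    ds = simulate_pops(1, 0.004, 120, 3000, seed=19)
    est = fs.IterativePCAClustering(min_fst=0.5, random_state=0).fit(
        ds.dosages.astype(float)
    )
    assert est.n_groups_ == 1  # any proposed split fails the impossible gate


def test_small_distant_group_becomes_outlier_leaf(simulate_pops):
    root = fs.PopulationNode(
        name="root",
        children=[
            fs.PopulationNode(name="MAIN", F=0.005, n_samples=100),
            fs.PopulationNode(name="FAR", F=0.6, n_samples=3),
        ],
    )
    freqs = fs.simulate_tree(fs.PopulationTreeSpec(root=root, n_snps=6000, seed=23))
    ds = fs.sample_genotypes(freqs, {"MAIN": 100, "FAR": 3}, seed=24)
    tree, assignment = fs.ipcaps(ds, fs.IPCAPSParams(seed=0))
    truth = np.array(ds.population_labels())
    far = np.flatnonzero(truth == "FAR")
    flags = assignment.outlier_flags
    assert flags[far].all()  # the trio lands in outlier groups (< 5 members)
    assert not flags[truth == "MAIN"].any()


def test_leaves_partition_samples_and_groups_are_deterministic(simulate_pops):
    ds = simulate_pops(3, 0.02, 40, 4000, seed=29)
    X = ds.dosages.astype(float)
    est1 = fs.IterativePCAClustering(random_state=5).fit(X)
    est2 = fs.IterativePCAClustering(random_state=5).fit(X)
    np.testing.assert_array_equal(est1.labels_, est2.labels_)
    leaves = est1.tree_.root.leaves()
    members = np.concatenate([leaf.members for leaf in leaves])
    assert sorted(members.tolist()) == list(range(ds.n_samples))
    assert est1.labels_.min() >= 1


def test_accepted_sibling_pairs_respect_min_fst(simulate_pops):
    ds = simulate_pops(3, 0.02, 40, 4000, seed=31)
    est = fs.IterativePCAClustering(random_state=1).fit(ds.dosages.astype(float))

    def walk(node):
        if node.children:
            if node.inter_child_fst is not None:
                assert node.inter_child_fst >= est.min_fst
            for child in node.children:
                walk(child)

    walk(est.tree_.root)


def test_estimator_api_round_trips_params():
    est = fs.IterativePCAClustering(threshold=0.05, min_in_group=10, random_state=3)
    params = est.get_params()
    assert params["threshold"] == 0.05 and params["min_in_group"] == 10
    cloned = clone(est)
    assert cloned.get_params() == params
    est.set_params(threshold=0.18)
    assert est.threshold == 0.18


def test_invalid_dosages_rejected():
    with pytest.raises(ValueError, match="dosages"):
        fs.IterativePCAClustering().fit(np.array([[0.0, 3.0], [1.0, 2.0]]))


def test_out_of_range_threshold_warns():
    with pytest.warns(UserWarning, match="calibrated range"):
        fs.IPCAPSParams(threshold=0.01)


def test_tiny_root_is_single_leaf(make_dataset):
    rng = np.random.default_rng(33)
    ds = make_dataset(rng.integers(0, 3, size=(8, 50)).astype(np.int8))
    tree, assignment = fs.ipcaps(ds, fs.IPCAPSParams(seed=0))
    assert len(tree.groups) == 1
    assert tree.groups[0].size == 8


def test_ipcaps_rejects_missing_dosages(make_dataset):
    d = np.zeros((25, 10), dtype=np.int8)
    d[0, 0] = fs.MISSING
    with pytest.raises(ValueError, match="impute"):
        fs.ipcaps(make_dataset(d))
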