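"""Seven-step QC protocol: filters, exact HWE test, LD pruning, imputation."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest

import finestrat as fs
from finestrat.io import MISSING


# -- step 1-2: pedigree and chromosome filters ------------------------------


def test_founder_filter_keeps_parents_drops_offspring(make_dataset):
    ds = make_dataset(
        np.zeros((3, 2), dtype=np.int8),
        parents=[("0", "0"), ("0", "0"), ("s0", "s1")],
    )
    out, removed = fs.filter_founders(ds)
    assert [s.individual_id for s in out.samples] == ["s0", "s1"]
    assert removed == ["s2"]


def test_founder_filter_identity_on_all_founders(make_dataset):
    ds = make_dataset(np.ones((4, 2), dtype=np.int8))
    out, removed = fs.filter_founders(ds)
    assert out.equals(ds) and removed == []


def test_one_known_parent_is_not_a_founder(make_dataset):
    ds = make_dataset(np.zeros((2, 1), dtype=np.int8), parents=[("0", "0"), ("x", "0")])
    out, removed = fs.filter_founders(ds)
    assert removed == ["s1"]


def test_autosome_filter(make_dataset):
    ds = make_dataset(np.zeros((2, 4), dtype=np.int8), chromosomes=[1, 23, 26, 0])
    out, removed = fs.filter_autosomes(ds)
    assert [v.identifier for v in out.variants] == ["v0"]
    assert sorted(removed) == ["v1", "v2", "v3"]  # X, MT and unknown all go


# -- step 3: LD r^2 and pruning ---------------------------------------------


def test_r2_duplicate_and_flipped_snp_score_one():
    x = np.array([0, 1, 2, 0, 2])
    assert fs.genotype_r2(x, x) == pytest.approx(1.0)
    assert fs.genotype_r2(x, 2 - x) == pytest.approx(1.0)


def test_r2_hand_computed_value():
    x = np.array([0, 1, 2, 0, 2])
    y = np.array([0, 1, 1, 0, 2])
    # cov = 3.0, var_x = 4.0, var_y = 2.8 on centered values
    assert fs.genotype_r2(x, y) == pytest.approx(9.0 / 11.2)


def test_r2_zero_variance_scores_zero():
    assert fs.genotype_r2(np.ones(5), np.array([0, 1, 2, 0, 2])) == 0.0


def test_r2_uses_pairwise_complete_entries():
    x = np.array([0, 1, 2, MISSING, 2, 0])
    y = np.array([0, 1, 2, 2, MISSING, 0])
    # complete subset is positions 0,1,2,5 where x == y
    assert fs.genotype_r2(x, y) == pytest.approx(1.0)


def test_ld_prune_removes_one_of_identical_pair(make_dataset):
    rng = np.random.default_rng(0)
    base = rng.integers(0, 3, size=(40, 1), dtype=np.int8)
    other = rng.integers(0, 3, size=(40, 1), dtype=np.int8)
    ds = make_dataset(np.hstack([base, base, other]))
    out, removed = fs.ld_prune(ds)
    assert len(removed) == 1 and removed[0] in {"v0", "v1"}
    assert out.n_variants == 2


def test_ld_prune_noop_below_threshold(make_dataset):
    rng = np.random.default_rng(1)
    # independent permuted columns: r^2 ~ 1/n, far below 0.2
    cols = [rng.permutation([0] * 30 + [1] * 40 + [2] * 30) for _ in range(10)]
    ds = make_dataset(np.array(cols, dtype=np.int8).T)
    out, removed = fs.ld_prune(ds)
    assert removed == []


def test_ld_prune_breaks_planted_pairs_and_satisfies_contract(make_dataset):
    rng = np.random.default_rng(2)
    n = 60
    a = rng.integers(0, 3, n).astype(np.int8)
    b = a.copy()  # duplicate pair (r^2 = 1)
    c = rng.permutation([0] * 20 + [1] * 20 + [2] * 20).astype(np.int8)
    d = rng.integers(0, 3, n).astype(np.int8)
    e = d.copy()
    flip = rng.choice(n, size=18, replace=False)
    e[flip] = rng.integers(0, 3, 18)  # correlated pair, r^2 ~ 0.5
    assert 0.2 < fs.genotype_r2(d, e) < 0.95
    ds = make_dataset(np.column_stack([a, b, c, d, e]))
    out, removed = fs.ld_prune(ds)
    assert out.n_variants == 3
    # oracle: exhaustive pairwise check on the survivors
    for i in range(out.n_variants):
        for j in range(i + 1, out.n_variants):
            assert fs.genotype_r2(out.dosages[:, i], out.dosages[:, j]) <= 0.2


def test_ld_prune_requires_sorted_variants(make_dataset):
    ds = make_dataset(np.zeros((4, 2), dtype=np.int8), positions=[2000, 1000])
    with pytest.raises(ValueError, match="sorted"):
        fs.ld_prune(ds)


# -- step 4: Hardy-Weinberg exact test --------------------------------------


def hwe_brute_force(h1, het, h2):
    """Independent oracle: full enumeration with exact rationals."""
    n = h1 + het + h2
    nA, na = 2 * h1 + het, 2 * h2 + het

    def weight(h):
        a1hom, a2hom = (nA - h) // 2, (na - h) // 2
        if (nA - h) % 2 or a1hom < 0 or a2hom < 0:
            return Fraction(0)
        return Fraction(factorial(n) * 2**h, factorial(a1hom) * factorial(h) * factorial(a2hom))

    weights = {h: weight(h) for h in range(min(nA, na) + 1)}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items() if w > 0}
    p_obs = probs[het]
    return float(sum(p for p in probs.values() if p <= p_obs))


@pytest.mark.parametrize(
    "counts",
    [(3, 5, 2), (5, 1, 5), (10, 10, 10), (2, 8, 0), (1, 1, 1), (0, 4, 7), (6, 0, 6)],
)
def test_hwe_exact_matches_brute_force_enumeration(counts):
    assert fs.hwe_exact_p(*counts) == pytest.approx(hwe_brute_force(*counts), rel=1e-10)


def test_hwe_monomorphic_is_one():
    assert fs.hwe_exact_p(17, 0, 0) == 1.0


def test_hwe_total_heterozygosity_is_extreme():
    assert fs.hwe_exact_p(0, 100, 0) < 1e-20


def test_hwe_filter_removes_only_planted_violator(make_dataset):
    rng = np.random.default_rng(4)
    cols = [rng.permutation([0] * 25 + [1] * 50 + [2] * 25) for _ in range(6)]
    cols.insert(3, np.ones(100, dtype=np.int8))  # universal heterozygote
    ds = make_dataset(np.array(cols, dtype=np.int8).T)
    out, removed = fs.hwe_filter(ds, 0.001)
    assert removed == ["v3"]
    assert out.n_variants == 6


# -- steps 5-7: missingness and MAF -----------------------------------------


def test_sample_call_rate_boundary(make_dataset):
    d = np.zeros((3, 100), dtype=np.int8)
    d[0, :5] = MISSING  # exactly 5%: retained (strict >)
    d[1, :6] = MISSING  # 6%: removed
    ds = make_dataset(d)
    out, removed = fs.sample_call_rate_filter(ds, 0.05)
    assert removed == ["s1"]
    assert out.n_samples == 2


def test_snp_missingness_boundary(make_dataset):
    d = np.zeros((100, 2), dtype=np.int8)
    d[:2, 0] = MISSING  # exactly 2%: retained
    d[:3, 1] = MISSING  # 3%: removed
    out, removed = fs.snp_missingness_filter(make_dataset(d), 0.02)
    assert removed == ["v1"]


def test_maf_filter_boundaries(make_dataset):
    monomorphic = np.zeros(10, dtype=np.int8)
    at_threshold = np.array([1] * 1 + [0] * 9, dtype=np.int8)  # MAF 1/20 = 0.05: kept
    common = np.array([0, 0, 1, 2] + [0] * 6, dtype=np.int8)
    ds = make_dataset(np.column_stack([monomorphic, at_threshold, common]))
    out, removed = fs.maf_filter(ds, 0.05)
    assert removed == ["v0"]
    assert [v.identifier for v in out.variants] == ["v1", "v2"]


def test_maf_hand_computed(make_dataset):
    # dosages (0,0,1,2) over 4 samples: 3 alt alleles / 8 -> MAF 0.375
    ds = make_dataset(np.array([[0], [0], [1], [2]], dtype=np.int8))
    out, removed = fs.maf_filter(ds, 0.05)
    assert removed == []


# -- imputation -------------------------------------------------------------


def test_impute_mode_and_tie_break(make_dataset):
    d = np.array(
        [[0, 0, MISSING], [0, 1, MISSING], [1, MISSING, 0], [MISSING, 1, 1]],
        dtype=np.int8,
    )
    out = fs.impute_most_frequent(make_dataset(d))
    assert out.dosages[3, 0] == 0  # column 0 observed (0,0,1): mode 0
    assert out.dosages[2, 1] == 1  # column 1 observed (0,1,1): mode 1
    # column 2 observed (0,1): tie between modes -> smaller dosage
    assert out.dosages[0, 2] == 0 and out.dosages[1, 2] == 0
    assert not (out.dosages == MISSING).any()


def test_impute_identity_on_complete_data(make_dataset):
    ds = make_dataset(np.array([[0, 1], [2, 1]], dtype=np.int8))
    assert fs.impute_most_frequent(ds).equals(ds)


def test_impute_all_missing_snp_is_error(make_dataset):
    ds = make_dataset(np.full((3, 1), MISSING, dtype=np.int8))
    with pytest.raises(ValueError, match="impute"):
        fs.impute_most_frequent(ds)


# -- full protocol ----------------------------------------------------------


def test_run_qc_clean_dataset_removes_nothing(simulate_pops):
    # MAF-safe ancestral band keeps every SNP clear of the 0.05 cutoff
    ds = simulate_pops(1, 0.001, 80, 300, seed=7, ancestral=(0.25, 0.75))
    out, report = fs.run_qc(ds)
    frame = report.to_frame()
    assert (frame["n_removed"] == 0).all()
    assert out.n_samples == ds.n_samples and out.n_variants == ds.n_variants


@pytest.mark.parametrize("seed", [0, 11])
def test_run_qc_removes_exactly_planted_violations_in_order(seed):
    ds, planted = fs.qc_violation_fixture(seed=seed)
    out, report = fs.run_qc(ds)
    steps = {s.step: s for s in report.steps}
    for name, expected in planted.items():
        assert sorted(steps[name].removed) == sorted(expected), name
    # one removal per filtering step, nothing else
    assert [len(s.removed) for s in report.steps] == [1] * 7 + [0]


def test_run_qc_report_counts_telescope():
    ds, _ = fs.qc_violation_fixture(seed=5)
    _, report = fs.run_qc(ds)
    for prev, cur in zip(report.steps, report.steps[1:]):
        assert (cur.samples_before, cur.snps_before) == (prev.samples_after, prev.snps_after)


def test_run_qc_order_sensitivity_maf_after_sample_removal(make_dataset):
    # two samples fail call rate; with them, the last SNP's MAF is 1/24 < 0.05,
    # without them it is 1/20 = 0.05 and must be retained
    n, m = 12, 60
    rng = np.random.default_rng(9)
    d = np.array(
        [rng.permutation([0] * 4 + [1] * 4 + [2] * 4) for _ in range(m)], dtype=np.int8
    ).T
    d[0, : m // 2] = MISSING  # 50% missing -> removed by --mind
    d[1, : m // 2] = MISSING
    d[:, -1] = 0
    d[2, -1] = 1  # single alternate allele carried by a retained sample
    ds = make_dataset(d)
    out, report = fs.run_qc(ds)
    kept_ids = [v.identifier for v in out.variants]
    assert f"v{m - 1}" in kept_ids


@pytest.mark.parametrize(
    "filter_fn",
    [
        fs.filter_founders,
        fs.filter_autosomes,
        lambda ds: fs.hwe_filter(ds, 0.001),
        lambda ds: fs.sample_call_rate_filter(ds, 0.05),
        lambda ds: fs.snp_missingness_filter(ds, 0.02),
        lambda ds: fs.maf_filter(ds, 0.05),
        fs.ld_prune,
    ],
)
def test_filters_are_idempotent(filter_fn):
    ds, _ = fs.qc_violation_fixture(seed=2)
    once, removed_once = filter_fn(ds)
    twice, removed_twice = filter_fn(once)
    assert removed_twice == []
    assert twice.equals(once)
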