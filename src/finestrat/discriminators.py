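"""Discriminator SNPs between inferred groups and their uniqueness test.

For each pair of accepted (non-outlier) groups the per-SNP Hudson FST is
ranked and the SNPs in the top 0.1% (99.9th percentile, ascending
nearest-rank with ">= cutoff" selection) are the pair's discriminators.
Whether such a set could have been randomly selected is assessed by
individual resampling: in each round a without-replacement half-cohort of
every group (labels kept) yields a recomputed top set, which is compared to
the observed set with a bootstrap Jaccard/Tanimoto similarity test; the
*maximum* p-value over all rounds summarizes uniqueness.  A genuine
discriminator set reproduces itself in every cohort (max p minimal); a
noise set fails to reproduce in some round (max p large).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np

from . import popstat
from .io import ClusterAssignmentTable, GenotypeDataset

__all__ = [
    "DiscriminatorParams",
    "DiscriminatorResult",
    "nearest_rank_cutoff",
    "top_fst_snps",
    "jaccard_index",
    "jaccard_test_p",
    "permutation_uniqueness",
    "all_pairs",
]


@dataclass(frozen=True)
class DiscriminatorParams:
    """Selection percentile and resampling effort."""

    percentile: float = 0.999
    n_permutations: int = 10_000
    bootstrap_B: int = 1_000
    subsample_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must be in (0, 1)")
        if self.n_permutations < 1 or self.bootstrap_B < 1:
            raise ValueError("resampling counts must be positive")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class DiscriminatorResult:
    """Top-FST SNP set for one group pair (p-value filled in separately)."""

    pair: tuple[int, int]
    snp_ids: list[str]
    snp_indices: np.ndarray
    fst_values: np.ndarray
    cutoff: float
    max_permutation_p: float | None = None

    @property
    def set_size(self) -> int:
        return len(self.snp_ids)


def nearest_rank_cutoff(values: np.ndarray, percentile: float) -> tuple[float, np.ndarray]:
    """Ascending nearest-rank percentile cutoff and the ">= cutoff" selection.

    The cutoff is the value at rank ``ceil(percentile * m)`` (1-based) of the
    ascending sort; everything at or above it is selected.  With tie-free
    values this selects exactly ``m - ceil(percentile * m) + 1`` SNPs; ties
    spanning the cutoff can only reduce the count relative to shifting the
    cutoff below them.
    """
    v = np.asarray(values, dtype=float)
    m = v.size
    if m == 0:
        raise ValueError("no values to rank")
    rank = max(1, ceil(percentile * m))
    cutoff = float(np.sort(v)[rank - 1])
    return cutoff, np.flatnonzero(v >= cutoff)


def top_fst_snps(
    dataset: GenotypeDataset | np.ndarray,
    group_i: np.ndarray,
    group_j: np.ndarray,
    percentile: float = 0.999,
    pair: tuple[int, int] = (0, 1),
) -> DiscriminatorResult:
    """Select the top-percentile per-SNP FST set between two member lists.

    SNPs monomorphic across both groups rank below all polymorphic SNPs
    (their Hudson denominator is zero, so they carry no signal).
    """
    dosages = dataset.dosages if isinstance(dataset, GenotypeDataset) else np.asarray(dataset)
    values = popstat.per_snp_fst(dosages, group_i, group_j)
    cutoff, selected = nearest_rank_cutoff(values, percentile)
    ids = (
        [dataset.variants[j].identifier for j in selected]
        if isinstance(dataset, GenotypeDataset)
        else [f"snp{j}" for j in selected]
    )
    return DiscriminatorResult(
        pair=pair,
        snp_ids=ids,
        snp_indices=selected,
        fst_values=values[selected],
        cutoff=cutoff,
    )


def jaccard_index(set_a, set_b) -> float:
    """|A n B| / |A u B|; defined as 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def jaccard_test_p(
    set_a,
    set_b,
    universe_size: int,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap two-sided p-value for the Jaccard index of two SNP sets.

    Under independent membership with the observed marginals
    ``pi_A = |A|/m`` and ``pi_B = |B|/m``, the expected Jaccard index is
    ``pi_A pi_B / (pi_A + pi_B - pi_A pi_B)``.  The null distribution is
    formed by ``B`` resamples of independently re-drawn membership
    indicators with those marginals; the p-value is the add-one-smoothed
    fraction of null statistics at least as far from the expectation as the
    observed one.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 1.0
    m = int(universe_size)
    if m < len(union):
        raise ValueError("universe smaller than the union of the sets")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi_a = len(a) / m
    pi_b = len(b) / m
    expected = pi_a * pi_b / (pi_a + pi_b - pi_a * pi_b)
    observed = jaccard_index(a, b)
    # each of the m SNPs falls in (both, A only, B only, neither) independently
    p_both = pi_a * pi_b
    probs = [p_both, pi_a - p_both, pi_b - p_both, 1.0 - pi_a - pi_b + p_both]
    draws = rng.multinomial(m, probs, size=B).astype(float)
    union_sizes = draws[:, :3].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_j = np.where(union_sizes > 0, draws[:, 0] / union_sizes, 0.0)
    extreme = np.abs(null_j - expected) >= abs(observed - expected) - 1e-12
    return float((1 + extreme.sum()) / (B + 1))


def permutation_uniqueness(
    dataset: GenotypeDataset | np.ndarray,
    group_i: np.ndarray,
    group_j: np.ndarray,
    params: DiscriminatorParams = DiscriminatorParams(),
    observed: DiscriminatorResult | None = None,
) -> float:
    """Maximum Jaccard-test p-value over resampling rounds for one pair.

    Each round draws, without replacement, a ``subsample_fraction`` cohort
    from every group of the pair (the resampled individuals keep their
    assigned cluster labels), recomputes the top-FST set on the cohort, and
    compares it with the observed set via the bootstrap Jaccard test.  The
    maximum p over all rounds is reported: a genuine discriminator set
    reproduces itself in *every* perturbed cohort (all rounds maximally
    significant, max p near ``1/(B+1)``), whereas a noise-selected set fails
    to reproduce in at least some rounds (max p large).  Deterministic for a
    fixed seed; SNP column order does not affect the result (sets are
    compared by identity, not position).
    """
    dosages = dataset.dosages if isinstance(dataset, GenotypeDataset) else np.asarray(dataset)
    group_i = np.asarray(group_i)
    group_j = np.asarray(group_j)
    if observed is None:
        observed = top_fst_snps(dosages, group_i, group_j, params.percentile)
    obs_set = set(observed.snp_indices.tolist())
    m = dosages.shape[1]
    k_i = max(2, int(round(params.subsample_fraction * group_i.size)))
    k_j = max(2, int(round(params.subsample_fraction * group_j.size)))
    rng = np.random.default_rng(params.seed)
    max_p = 0.0
    for _ in range(params.n_permutations):
        sub_i = rng.choice(group_i, size=k_i, replace=False)
        sub_j = rng.choice(group_j, size=k_j, replace=False)
        top = top_fst_snps(dosages, sub_i, sub_j, params.percentile)
        p = jaccard_test_p(
            obs_set, set(top.snp_indices.tolist()), m, params.bootstrap_B, rng
        )
        if p > max_p:
            max_p = p
    return max_p


def all_pairs(
    dataset: GenotypeDataset,
    assignment: ClusterAssignmentTable,
    params: DiscriminatorParams = DiscriminatorParams(),
    with_permutation_p: bool = False,
) -> list[DiscriminatorResult]:
    """Top-FST SNP lists for every unordered pair of accepted groups.

    Outlier groups are excluded; ``k`` accepted groups yield
    ``k (k - 1) / 2`` results.  Permutation p-values are optional because
    they dominate runtime at the published resampling effort.
    """
    ids = assignment.accepted_group_ids()
    members = {g: assignment.members_of(g) for g in ids}
    results: list[DiscriminatorResult] = []
    for a, b in combinations(ids, 2):
        res = top_fst_snps(dataset, members[a], members[b], params.percentile, pair=(a, b))
        if with_permutation_p:
            res.max_permutation_p = permutation_uniqueness(
                dataset, members[a], members[b], params, observed=res
            )
        results.append(res)
    return results
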