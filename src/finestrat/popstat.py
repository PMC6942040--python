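"""Hudson's FST estimator: per-SNP components and ratio-of-averages aggregate.

For two groups with sample allele frequencies ``p1, p2`` estimated from
``n1, n2`` chromosomes, the per-SNP components are

    N = (p1 - p2)^2 - p1 (1 - p1) / (n1 - 1) - p2 (1 - p2) / (n2 - 1)
    D = p1 (1 - p2) + p2 (1 - p1)

and the multi-SNP estimate is the ratio of averages ``mean(N) / mean(D)``
over SNPs with ``D > 0`` (not the average of per-SNP ratios, which is biased
by low-information SNPs).  ``n1, n2`` are non-missing allele counts, i.e.
twice the non-missing genotype count per SNP per group.  Negative values are
retained: near zero divergence the estimator is unbiased around 0, and the
clustering gate simply treats them as below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset

__all__ = [
    "FstComponents",
    "hudson_components",
    "group_frequencies",
    "snp_fst_components",
    "average_fst",
    "per_snp_fst",
    "pairwise_group_fst",
]


@dataclass
class FstComponents:
    """Per-SNP Hudson numerators/denominators and their inputs."""

    numerator: np.ndarray
    denominator: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray

    def ratio_of_averages(self) -> float:
        return average_fst(self.numerator, self.denominator)

    def per_snp(self) -> np.ndarray:
        """Per-SNP N/D ratios; SNPs monomorphic across both groups get -inf."""
        out = np.full(self.numerator.shape, -np.inf)
        ok = self.denominator > 0
        out[ok] = self.numerator[ok] / self.denominator[ok]
        return out


def hudson_components(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Hudson N and D for frequencies ``p1, p2`` from ``n1, n2`` chromosomes.

    Accepts scalars or arrays; requires ``n1, n2 > 1`` (the unbiasing terms
    divide by ``n - 1``).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("allele sample sizes must exceed 1 chromosome")
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def group_frequencies(
    dosages: np.ndarray, members: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Allele-1 frequency and chromosome count per SNP for one group.

    Chromosome counts are twice the non-missing genotype counts, so
    missingness reduces the effective sample size per SNP.
    """
    sub = dosages[np.asarray(members)]
    present = sub != MISSING
    n_chrom = 2.0 * present.sum(axis=0)
    totals = np.where(present, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_chrom > 0, totals / n_chrom, np.nan)
    return freq, n_chrom


def snp_fst_components(
    dosages: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> FstComponents:
    """Per-SNP Hudson components between two index sets of samples.

    SNPs where either group has fewer than 2 observed chromosomes are marked
    monomorphic-equivalent (N = D = 0) and excluded from aggregates.
    """
    group1 = np.asarray(group1)
    group2 = np.asarray(group2)
    if group1.size < 2 or group2.size < 2:
        raise ValueError("each group needs at least 2 samples for Hudson FST")
    p1, n1 = group_frequencies(dosages, group1)
    p2, n2 = group_frequencies(dosages, group2)
    ok = (n1 > 1) & (n2 > 1)
    num = np.zeros(p1.shape)
    den = np.zeros(p1.shape)
    if ok.any():
        num[ok], den[ok] = hudson_components(p1[ok], n1[ok], p2[ok], n2[ok])
    return FstComponents(numerator=num, denominator=den, p1=p1, p2=p2, n1=n1, n2=n2)


def average_fst(numerator: np.ndarray, denominator: np.ndarray) -> float:
    """Ratio-of-averages aggregate over SNPs with ``D > 0``.

    Raises if every SNP is monomorphic across both groups (no information).
    """
    numerator = np.asarray(numerator, dtype=float)
    denominator = np.asarray(denominator, dtype=float)
    ok = denominator > 0
    if not ok.any():
        raise ValueError("all SNPs are monomorphic across both groups")
    return float(numerator[ok].mean() / denominator[ok].mean())


def per_snp_fst(
    dosages: np.ndarray, group1: np.ndarray, group2: np.ndarray
) -> np.ndarray:
    """Per-SNP Hudson ratios; monomorphic-across-both SNPs get -inf."""
    return snp_fst_components(dosages, group1, group2).per_snp()


def pairwise_group_fst(
    dataset: GenotypeDataset | np.ndarray,
    assignment,
    include_outliers: bool = False,
) -> pd.DataFrame:
    """Symmetric matrix of average Hudson FST over all group pairs.

    ``assignment`` is a :class:`~finestrat.io.ClusterAssignmentTable` (or any
    object with ``groups``/``outlier_flags`` arrays aligned with the dataset's
    sample order).  Outlier groups are excluded unless requested.  Any group
    of a single sample is an error (the ``n - 1`` correction is undefined).
    """
    dosages = dataset.dosages if isinstance(dataset, GenotypeDataset) else np.asarray(dataset)
    groups = np.asarray(assignment.groups)
    flags = np.asarray(assignment.outlier_flags, dtype=bool)
    if groups.shape[0] != dosages.shape[0]:
        raise ValueError("assignment length does not match sample count")
    ids = sorted(set(groups[~flags] if not include_outliers else groups))
    if len(ids) < 2:
        raise ValueError("need at least two non-outlier groups")
    members = {g: np.flatnonzero(groups == g) for g in ids}
    for g, idx in members.items():
        if idx.size < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for a_pos, a in enumerate(ids):
        for b in ids[a_pos + 1 :]:
            comp = snp_fst_components(dosages, members[a], members[b])
            value = comp.ratio_of_averages()
            out.loc[a, b] = value
            out.loc[b, a] = value
    return out
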