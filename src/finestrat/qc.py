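"""Seven-step genotype quality control and most-frequent imputation.

The protocol mirrors the standard PLINK workflow for structure analysis,
applied in this fixed order:

1. founders only (both parent IDs unknown),
2. autosomes only (chromosome codes 1-22),
3. LD pruning (sliding window, pairwise r-squared),
4. Hardy-Weinberg exact-test filter,
5. per-sample call-rate filter,
6. per-SNP missingness filter,
7. minor-allele-frequency filter,

with statistics recomputed after every step, and single imputation by the
per-SNP modal dosage applied last.  Boundary conventions: the missingness
filters remove strictly-greater-than fractions; the MAF and HWE filters
remove strictly-less-than values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeDataset

__all__ = [
    "QCParams",
    "QCReport",
    "filter_founders",
    "filter_autosomes",
    "genotype_r2",
    "ld_prune",
    "hwe_exact_p",
    "hwe_filter",
    "sample_call_rate_filter",
    "snp_missingness_filter",
    "maf_filter",
    "impute_most_frequent",
    "run_qc",
]


@dataclass(frozen=True)
class QCParams:
    """Thresholds for the seven QC steps (PLINK flag defaults)."""

    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2
    hwe_p_min: float = 0.001
    sample_max_missing: float = 0.05
    snp_max_missing: float = 0.02
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        for name in ("ld_r2_max", "hwe_p_min", "sample_max_missing", "snp_max_missing", "maf_min"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.ld_step > self.ld_window:
            raise ValueError("ld_step must not exceed ld_window")
        if self.ld_window < 2:
            raise ValueError("ld_window must be at least 2")


@dataclass
class QCStepRecord:
    step: str
    samples_before: int
    samples_after: int
    snps_before: int
    snps_after: int
    removed: list[str]


@dataclass
class QCReport:
    """Ordered per-step counts; counts telescope from step to step."""

    steps: list[QCStepRecord] = field(default_factory=list)

    def add(self, record: QCStepRecord) -> None:
        if self.steps:
            last = self.steps[-1]
            if (record.samples_before, record.snps_before) != (last.samples_after, last.snps_after):
                raise ValueError("QC report counts do not telescope")
        self.steps.append(record)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [s.step for s in self.steps],
                "samples_before": [s.samples_before for s in self.steps],
                "samples_after": [s.samples_after for s in self.steps],
                "snps_before": [s.snps_before for s in self.steps],
                "snps_after": [s.snps_after for s in self.steps],
                "n_removed": [len(s.removed) for s in self.steps],
            }
        )


# ---------------------------------------------------------------------------
# Step 1-2: sample pedigree and chromosome filters


def filter_founders(dataset: GenotypeDataset) -> tuple[GenotypeDataset, list[str]]:
    """Keep only founders (father and mother both "0")."""
    keep = [i for i, s in enumerate(dataset.samples) if s.is_founder]
    removed = [dataset.samples[i].individual_id for i in range(dataset.n_samples) if i not in set(keep)]
    if not keep:
        warnings.warn("no founders remain after filtering", stacklevel=2)
    return dataset.subset(sample_indices=keep), removed


def filter_autosomes(dataset: GenotypeDataset) -> tuple[GenotypeDataset, list[str]]:
    """Keep only variants on chromosomes 1-22 (drops 0/X/Y/XY/MT)."""
    keep = [j for j, v in enumerate(dataset.variants) if 1 <= v.chromosome <= 22]
    removed = [v.identifier for j, v in enumerate(dataset.variants) if not 1 <= v.chromosome <= 22]
    return dataset.subset(variant_indices=keep), removed


# ---------------------------------------------------------------------------
# Step 3: LD pruning


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on pairwise-complete (both non-missing) entries.  A pair with
    zero variance on that subset cannot evidence LD and scores 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    xd = xs - xs.mean()
    yd = ys - ys.mean()
    vx = float(xd @ xd)
    vy = float(yd @ yd)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    return float((xd @ yd) ** 2 / (vx * vy))


def _window_r2(dosages: np.ndarray) -> np.ndarray:
    """Pairwise-complete r-squared for all column pairs of one window."""
    d = dosages.astype(float)
    present = (d != MISSING).astype(float)
    d0 = np.where(d == MISSING, 0.0, d)
    n = present.T @ present
    sx = d0.T @ present
    sxy = d0.T @ d0
    sxx = (d0 * d0).T @ present
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx**2 / n
        r2 = cov**2 / (varx * varx.T)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 0.0)
    return np.clip(r2, 0.0, 1.0)


def _minor_allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    present = dosages != MISSING
    counts = 2 * present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(dosages == MISSING, 0, dosages).sum(axis=0) / counts
    freq = np.where(counts > 0, freq, np.nan)
    return np.minimum(freq, 1.0 - freq)


def ld_prune(
    dataset: GenotypeDataset, params: QCParams = QCParams()
) -> tuple[GenotypeDataset, list[str]]:
    """Greedy sliding-window LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window of ``ld_window`` SNPs per chromosome, while any
    retained pair has r-squared above ``ld_r2_max``, one SNP of the worst
    pair is removed (the one with smaller MAF; on a tie, the later in map
    order); the window then slides by ``ld_step``.  The contract is that no
    surviving pair within any window exceeds the threshold.
    """
    chroms = np.array([v.chromosome for v in dataset.variants])
    positions = np.array([v.position for v in dataset.variants])
    order_key = np.lexsort((positions, chroms))
    if not np.array_equal(order_key, np.arange(dataset.n_variants)):
        raise ValueError("variants must be sorted by (chromosome, position)")

    maf = _minor_allele_frequencies(dataset.dosages)
    alive = np.ones(dataset.n_variants, dtype=bool)
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            window = idx[start : start + params.ld_window]
            if window.size >= 2:
                r2 = _window_r2(dataset.dosages[:, window])
                local_alive = alive[window].copy()
                while True:
                    act = np.flatnonzero(local_alive)
                    if act.size < 2:
                        break
                    sub = r2[np.ix_(act, act)]
                    worst_flat = np.argmax(sub)
                    worst = sub.flat[worst_flat]
                    if worst <= params.ld_r2_max:
                        break
                    a, b = np.unravel_index(worst_flat, sub.shape)
                    ga, gb = window[act[a]], window[act[b]]
                    if maf[ga] < maf[gb]:
                        drop = act[a]
                    elif maf[gb] < maf[ga]:
                        drop = act[b]
                    else:
                        drop = act[max(a, b)]  # equal MAF: later in map order
                    local_alive[drop] = False
                alive[window] = local_alive
            if start + params.ld_window >= idx.size:
                break
            start += params.ld_step
    removed = [dataset.variants[j].identifier for j in np.flatnonzero(~alive)]
    return dataset.subset(variant_indices=np.flatnonzero(alive)), removed


# ---------------------------------------------------------------------------
# Step 4: Hardy-Weinberg exact test


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test probability.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (Wigginton-style mid-free exact test, computed by full
    enumeration in log space).
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    lg = math.lgamma
    logp = np.empty(hets.size)
    for k, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if rare_hom < 0 or common_hom < 0:
            logp[k] = -np.inf
            continue
        # P(h | allele counts) = n! / (hom1! het! hom2!) * 2^h * ... (hypergeometric form)
        logp[k] = (
            lg(n + 1)
            - lg(rare_hom + 1)
            - lg(h + 1)
            - lg(common_hom + 1)
            + h * math.log(2.0)
            + lg(n_rare + 1)
            + lg(2 * n - n_rare + 1)
            - lg(2 * n + 1)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[hets == n_het]
    if observed.size == 0:
        return 1.0
    p_obs = float(observed[0])
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP (hom-a1, het, hom-a2) counts over non-missing entries."""
    return np.stack(
        [(dosages == 2).sum(axis=0), (dosages == 1).sum(axis=0), (dosages == 0).sum(axis=0)],
        axis=1,
    )


def hwe_filter(
    dataset: GenotypeDataset, p_min: float = 0.001
) -> tuple[GenotypeDataset, list[str]]:
    """Remove variants whose exact HWE p-value is below ``p_min``."""
    counts = _genotype_counts(dataset.dosages)
    keep, removed = [], []
    for j, (h1, het, h2) in enumerate(counts):
        total = h1 + het + h2
        p = 1.0 if total == 0 else hwe_exact_p(int(h1), int(het), int(h2))
        if p < p_min:
            removed.append(dataset.variants[j].identifier)
        else:
            keep.append(j)
    return dataset.subset(variant_indices=keep), removed


# ---------------------------------------------------------------------------
# Steps 5-7: missingness and frequency filters


def sample_call_rate_filter(
    dataset: GenotypeDataset, max_missing: float = 0.05
) -> tuple[GenotypeDataset, list[str]]:
    """Remove samples with missing-genotype fraction strictly above the cap."""
    if dataset.n_variants == 0:
        return dataset, []
    frac = dataset.missing_mask().mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing)
    removed = [dataset.samples[i].individual_id for i in np.flatnonzero(frac > max_missing)]
    return dataset.subset(sample_indices=keep), removed


def snp_missingness_filter(
    dataset: GenotypeDataset, max_missing: float = 0.02
) -> tuple[GenotypeDataset, list[str]]:
    """Remove variants with missing-genotype fraction strictly above the cap."""
    if dataset.n_samples == 0:
        return dataset, []
    frac = dataset.missing_mask().mean(axis=0)
    keep = np.flatnonzero(frac <= max_missing)
    removed = [dataset.variants[j].identifier for j in np.flatnonzero(frac > max_missing)]
    return dataset.subset(variant_indices=keep), removed


def maf_filter(
    dataset: GenotypeDataset, maf_min: float = 0.05
) -> tuple[GenotypeDataset, list[str]]:
    """Remove variants with minor-allele frequency strictly below ``maf_min``."""
    maf = _minor_allele_frequencies(dataset.dosages)
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep = np.flatnonzero(maf >= maf_min)
    removed = [dataset.variants[j].identifier for j in np.flatnonzero(maf < maf_min)]
    return dataset.subset(variant_indices=keep), removed


# ---------------------------------------------------------------------------
# Imputation


def impute_most_frequent(dataset: GenotypeDataset) -> GenotypeDataset:
    """Replace every missing entry by the SNP's modal non-missing dosage.

    Ties between modes break to the smaller dosage (determinism).  A SNP with
    all entries missing is an error: it should have been removed upstream.
    """
    d = dataset.dosages.copy()
    missing = d == MISSING
    if not missing.any():
        return dataset
    counts = np.stack([(d == k).sum(axis=0) for k in (0, 1, 2)], axis=1)
    if (counts.sum(axis=1) == 0).any():
        bad = np.flatnonzero(counts.sum(axis=1) == 0)
        raise ValueError(
            f"cannot impute SNPs with no observed genotypes: "
            f"{[dataset.variants[j].identifier for j in bad[:5]]}"
        )
    modes = counts.argmax(axis=1).astype(np.int8)  # argmax takes the smallest on ties
    cols = np.nonzero(missing)
    d[cols] = modes[cols[1]]
    return GenotypeDataset(samples=dataset.samples, variants=dataset.variants, dosages=d)


# ---------------------------------------------------------------------------
# Full protocol


def run_qc(
    dataset: GenotypeDataset, params: QCParams = QCParams(), impute: bool = True
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the seven steps in protocol order, then impute.

    Statistics (missingness, MAF, HWE counts) are recomputed on the current
    dataset at each step, so removals cascade exactly as a sequential PLINK
    run would produce them.
    """
    report = QCReport()
    current = dataset

    def record(step: str, before: GenotypeDataset, after: GenotypeDataset, removed: list[str]):
        report.add(
            QCStepRecord(
                step=step,
                samples_before=before.n_samples,
                samples_after=after.n_samples,
                snps_before=before.n_variants,
                snps_after=after.n_variants,
                removed=removed,
            )
        )

    steps = [
        ("founders", lambda ds: filter_founders(ds)),
        ("autosomes", lambda ds: filter_autosomes(ds)),
        ("ld_prune", lambda ds: ld_prune(ds, params)),
        ("hwe", lambda ds: hwe_filter(ds, params.hwe_p_min)),
        ("sample_call_rate", lambda ds: sample_call_rate_filter(ds, params.sample_max_missing)),
        ("snp_missingness", lambda ds: snp_missingness_filter(ds, params.snp_max_missing)),
        ("maf", lambda ds: maf_filter(ds, params.maf_min)),
    ]
    for name, fn in steps:
        after, removed = fn(current)
        record(name, current, after, removed)
        current = after

    if impute:
        imputed = impute_most_frequent(current)
        record("impute", current, imputed, [])
        current = imputed
    return current, report
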