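"""Synthetic structured-population genotype generator.

Populations diverge from a shared ancestral allele-frequency pool under the
Balding-Nichols model: along a branch with drift parameter ``F`` the allele
frequency moves from ``p`` to a draw from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``
(mean ``p``, variance ``F p (1-p)``).  Two populations drawn independently
at drift ``F`` from the same ancestor have expected pairwise Hudson FST
equal to ``F``; for distinct branch parameters ``F_i, F_j`` the expectation
is ``(F_i + F_j) / 2``.  Genotypes are binomial(2, p) draws; admixed
individuals draw from a per-individual mixture of population frequencies.

No linkage disequilibrium is simulated (drift acts per SNP), so LD-pruning
tests rely on explicitly planted duplicated/correlated SNPs, available
through :class:`NoiseSpec` together with the other planted QC violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeDataset, SampleRecord, Variant

__all__ = [
    "PopulationNode",
    "PopulationTreeSpec",
    "AdmixtureSpec",
    "NoiseSpec",
    "balding_nichols_freq",
    "simulate_tree",
    "sample_genotypes",
    "western_africa_like",
    "qc_violation_fixture",
]


# ---------------------------------------------------------------------------
# Specs


@dataclass
class PopulationNode:
    """One node of the population tree.

    ``F`` is the Balding-Nichols drift parameter of the branch leading to
    this node (ignored for the root).  Leaves carry diploid sample sizes.
    """

    name: str
    F: float = 0.0
    n_samples: int = 0
    children: list["PopulationNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.children and self.n_samples:
            raise ValueError("internal nodes do not carry samples")
        if not self.children and not 0.0 < self.F < 1.0:
            # root-as-leaf edge case is disallowed; every leaf has a branch
            raise ValueError(f"leaf {self.name}: branch F must be in (0, 1)")

    def leaves(self) -> list["PopulationNode"]:
        if not self.children:
            return [self]
        out: list[PopulationNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PopulationTreeSpec:
    """Blueprint for a hierarchy of diverging populations."""

    root: PopulationNode
    n_snps: int
    seed: int = 0
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not 0.0 <= self.ancestral_low < self.ancestral_high <= 1.0:
            raise ValueError("ancestral frequency bounds must satisfy 0 <= low < high <= 1")


@dataclass
class AdmixtureSpec:
    """One admixed group.

    ``proportions`` maps leaf-population names to fixed mixing weights.
    If ``outgroup`` is set, each individual additionally draws an out-group
    ancestry fraction uniformly from ``outgroup_range`` and the remaining
    weight is shared among ``proportions`` (renormalized), emulating a
    diaspora group with individually varying out-group admixture.
    """

    name: str
    n_samples: int
    proportions: dict[str, float]
    outgroup: str | None = None
    outgroup_range: tuple[float, float] = (0.05, 0.15)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("admixed group needs at least one sample")
        total = sum(self.proportions.values())
        if total <= 0:
            raise ValueError("mixing proportions must sum to a positive value")
        if self.outgroup is None and abs(total - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        lo, hi = self.outgroup_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("outgroup_range must satisfy 0 <= low <= high < 1")


@dataclass
class NoiseSpec:
    """Missingness plus planted QC violations for fixture datasets."""

    missing_rate: float = 0.0
    n_hwe_violations: int = 0
    n_low_maf: int = 0
    n_duplicate_pairs: int = 0
    n_high_missing_snps: int = 0
    n_low_call_samples: int = 0
    n_nonfounder_samples: int = 0
    n_nonautosomal: int = 0
    low_call_rate: float = 0.10
    high_snp_missing_rate: float = 0.06

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Frequency evolution


def balding_nichols_freq(
    p: np.ndarray | float, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Drifted population frequencies for ancestral frequencies ``p``.

    Draws from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``: mean ``p``, variance
    ``F p (1-p)``.  ``F -> 0`` concentrates at ``p``; ``F -> 1`` pushes mass
    to fixation or loss.
    """
    p = np.asarray(p, dtype=float)
    if not 0.0 < F < 1.0:
        raise ValueError("F must be in (0, 1)")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must be in (0, 1)")
    ratio = (1.0 - F) / F
    freq = rng.beta(p * ratio, (1.0 - p) * ratio)
    # guard against numerically exact 0/1 so later branches stay valid
    return np.clip(freq, 1e-12, 1.0 - 1e-12)


def simulate_tree(spec: PopulationTreeSpec) -> dict[str, np.ndarray]:
    """Evolve frequencies root -> leaves; returns per-leaf frequency arrays."""
    rng = np.random.default_rng(spec.seed)
    ancestral = rng.uniform(spec.ancestral_low, spec.ancestral_high, spec.n_snps)
    out: dict[str, np.ndarray] = {}

    def descend(node: PopulationNode, freq: np.ndarray) -> None:
        if not node.children:
            out[node.name] = balding_nichols_freq(freq, node.F, rng)
            return
        drifted = freq if node.F == 0.0 else balding_nichols_freq(freq, node.F, rng)
        for child in node.children:
            descend(child, drifted)

    if not spec.root.children:
        raise ValueError("population tree needs at least one leaf under the root")
    for child in spec.root.children:
        descend(child, ancestral)
    names = [leaf.name for leaf in spec.root.leaves()]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")
    return out


# ---------------------------------------------------------------------------
# Genotype sampling


def _make_variants(n_snps: int, rng: np.random.Generator) -> list[Variant]:
    chroms = np.sort(rng.integers(1, 23, n_snps))
    positions = np.zeros(n_snps, dtype=int)
    for c in np.unique(chroms):
        k = int((chroms == c).sum())
        positions[chroms == c] = np.cumsum(rng.integers(500, 5000, k))
    return [
        Variant(
            chromosome=int(chroms[j]),
            position=int(positions[j]),
            identifier=f"snp{j:06d}",
            allele1="A",
            allele2="G",
        )
        for j in range(n_snps)
    ]


def sample_genotypes(
    frequencies: dict[str, np.ndarray],
    sizes: dict[str, int],
    admixture: list[AdmixtureSpec] | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> GenotypeDataset:
    """Draw diploid genotypes for unadmixed and admixed groups.

    ``frequencies`` come from :func:`simulate_tree`; ``sizes`` gives diploid
    counts for (a subset of) the leaf populations.  Admixed individuals use
    an effective frequency ``p_eff = sum_k Q_k p_k`` with per-individual
    ``Q``.  Missingness and planted QC violations (from ``noise``) are
    applied last; the generating population name is recorded in each
    sample's ``population_label`` (reporting only).
    """
    rng = np.random.default_rng(seed)
    noise = noise or NoiseSpec()
    admixture = admixture or []
    n_snps = len(next(iter(frequencies.values())))

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    for name, n in sizes.items():
        if name not in frequencies:
            raise KeyError(f"no simulated frequencies for population {name!r}")
        if n < 1:
            continue
        p = frequencies[name]
        blocks.append(rng.binomial(2, np.broadcast_to(p, (n, n_snps))).astype(np.int8))
        labels.extend([name] * n)
    for adm in admixture:
        for pop in list(adm.proportions) + ([adm.outgroup] if adm.outgroup else []):
            if pop not in frequencies:
                raise KeyError(f"no simulated frequencies for population {pop!r}")
        base = np.array([adm.proportions[k] for k in adm.proportions], dtype=float)
        base = base / base.sum()
        comp_freqs = np.stack([frequencies[k] for k in adm.proportions])
        if adm.outgroup is not None:
            lo, hi = adm.outgroup_range
            q_out = rng.uniform(lo, hi, adm.n_samples)
            p_eff = (1.0 - q_out)[:, None] * (base @ comp_freqs)[None, :] + q_out[
                :, None
            ] * frequencies[adm.outgroup][None, :]
        else:
            p_eff = np.broadcast_to(base @ comp_freqs, (adm.n_samples, n_snps))
        blocks.append(rng.binomial(2, p_eff).astype(np.int8))
        labels.extend([adm.name] * adm.n_samples)

    if not blocks:
        raise ValueError("no samples requested")
    dosages = np.vstack(blocks)
    n_total = dosages.shape[0]

    variants = _make_variants(n_snps, rng)
    samples = [
        SampleRecord(
            family_id=labels[i],
            individual_id=f"{labels[i]}_{i:04d}",
            population_label=labels[i],
        )
        for i in range(n_total)
    ]

    dosages, variants, samples = _apply_noise(dosages, variants, samples, noise, rng)
    return GenotypeDataset(samples=samples, variants=variants, dosages=dosages)


def _apply_noise(dosages, variants, samples, noise: NoiseSpec, rng):
    from dataclasses import replace

    n, m = dosages.shape
    if noise.missing_rate > 0:
        mask = rng.random(dosages.shape) < noise.missing_rate
        dosages = dosages.copy()
        dosages[mask] = MISSING

    planted_cols = iter(rng.permutation(m))

    def next_cols(k):
        return [next(planted_cols) for _ in range(k)]

    dosages = np.asarray(dosages).copy()
    variants = list(variants)
    samples = list(samples)

    for j in next_cols(noise.n_hwe_violations):
        dosages[:, j] = 1  # universal heterozygosity: extreme HWE violation
        variants[j] = replace(variants[j], identifier=variants[j].identifier + "_hwe")
    for j in next_cols(noise.n_low_maf):
        col = np.zeros(n, dtype=np.int8)
        col[rng.choice(n, size=max(1, int(0.02 * n)), replace=False)] = 1
        dosages[:, j] = col  # MAF ~1% < 0.05
        variants[j] = replace(variants[j], identifier=variants[j].identifier + "_lowmaf")
    for j in next_cols(noise.n_duplicate_pairs):
        src = next(planted_cols)
        dosages[:, j] = dosages[:, src]  # exact duplicate: r^2 = 1 in-window
        # place the copy right after its source in map order so the
        # equal-MAF tie-break (drop the later SNP) removes the copy
        variants[j] = replace(
            variants[j],
            identifier=variants[src].identifier + "_dup",
            chromosome=variants[src].chromosome,
            position=variants[src].position + 1,
        )
    for j in next_cols(noise.n_high_missing_snps):
        k = max(1, int(np.ceil(noise.high_snp_missing_rate * n)))
        rows = rng.choice(n, size=k, replace=False)
        dosages[rows, j] = MISSING
        variants[j] = replace(variants[j], identifier=variants[j].identifier + "_himiss")
    for j in next_cols(noise.n_nonautosomal):
        variants[j] = replace(
            variants[j],
            identifier=variants[j].identifier + "_chrx",
            chromosome=23,
        )
    order = np.lexsort(
        ([v.position for v in variants], [v.chromosome for v in variants])
    )
    variants = [variants[j] for j in order]
    dosages = dosages[:, order]

    sample_pool = iter(rng.permutation(n))
    for i in (next(sample_pool) for _ in range(noise.n_low_call_samples)):
        k = max(1, int(np.ceil(noise.low_call_rate * m)))
        cols = rng.choice(m, size=k, replace=False)
        dosages[i, cols] = MISSING
    for i in (next(sample_pool) for _ in range(noise.n_nonfounder_samples)):
        samples[i] = replace(samples[i], father_id="F1", mother_id="M1")
    return dosages, variants, samples


# ---------------------------------------------------------------------------
# Presets


def western_africa_like(seed: int = 0, n_snps: int = 20000) -> GenotypeDataset:
    """Structured preset emulating a many-population chip-data study design.

    720 diploid samples over ``n_snps`` independent SNPs:

    * six closely related sedentary-like populations (``SED1..SED6``,
      85 samples each) at branch drift 0.0090-0.0105 (pairwise Hudson FST
      about 0.009-0.0105);
    * one strongly diverged nomadic-like population (``NOM``, 55 samples) at
      branch drift 0.28, i.e. pairwise FST >= 0.14 against everything else;
    * two diaspora-like admixed groups (``DIA1``/``DIA2``, 75 samples each):
      own local lineages at drift 0.014 plus a per-individual 5-15% ancestry
      fraction from a distant out-group (branch drift 0.30), giving the
      larger within-group PC dispersion characteristic of admixed cohorts;
    * five singleton outliers (``OUT1..OUT5``), each the sole sample of its
      own heavily drifted lineage (branch drift 0.95) — strong enough to be
      resolvable as individual outliers in PC space.

    Truth labels are stored in ``population_label`` and are never consumed
    by the clustering engine.  Deterministic per seed.
    """
    sed = [
        PopulationNode(name=f"SED{i + 1}", F=f, n_samples=85)
        for i, f in enumerate((0.0090, 0.0093, 0.0096, 0.0099, 0.0102, 0.0105))
    ]
    local = [
        PopulationNode(name=f"LOC{i + 1}", F=0.014, n_samples=0) for i in range(2)
    ]
    # leaves need n_samples only at sampling time; sizes dict drives counts
    outlier_pops = [
        PopulationNode(name=f"OUT{i + 1}", F=0.95, n_samples=1) for i in range(5)
    ]
    root = PopulationNode(
        name="root",
        children=sed
        + [PopulationNode(name="NOM", F=0.28, n_samples=55)]
        + [PopulationNode(name="OUTGRP", F=0.30)]
        + local
        + outlier_pops,
    )
    spec = PopulationTreeSpec(root=root, n_snps=n_snps, seed=seed)
    freqs = simulate_tree(spec)
    sizes = {f"SED{i + 1}": 85 for i in range(6)}
    sizes["NOM"] = 55
    sizes.update({f"OUT{i + 1}": 1 for i in range(5)})
    admixture = [
        AdmixtureSpec(
            name=f"DIA{j + 1}",
            n_samples=75,
            proportions={f"LOC{j + 1}": 1.0},
            outgroup="OUTGRP",
            outgroup_range=(0.05, 0.15),
        )
        for j in range(2)
    ]
    return sample_genotypes(
        freqs, sizes, admixture=admixture, noise=NoiseSpec(), seed=seed + 1
    )


def qc_violation_fixture(seed: int = 0, n_snps: int = 300, n_samples: int = 150):
    """Dataset with exactly one planted violation per QC step.

    Returns ``(dataset, planted)`` where ``planted`` maps QC step names to
    the identifiers the corresponding filter should remove (samples for the
    pedigree/call-rate steps, variants otherwise).

    The background is built to be violation-free *by construction*, not just
    with high probability: every background column is a random permutation
    of a fixed genotype multiset whose counts sit at the Hardy-Weinberg
    conditional mode with mid-range MAF, so no background SNP can trip the
    HWE or MAF filters for any seed, and permuted columns are essentially
    uncorrelated (no spurious LD at the r^2 = 0.2 threshold).
    """
    rng = np.random.default_rng(seed)
    dosages = np.empty((n_samples, n_snps), dtype=np.int8)
    for j in range(n_snps):
        p = rng.uniform(0.25, 0.75)
        n_hom1 = int(round(p * p * n_samples))
        n_het = int(round(2 * p * (1 - p) * n_samples))
        n_hom2 = n_samples - n_hom1 - n_het
        column = np.concatenate(
            [
                np.full(n_hom1, 2, dtype=np.int8),
                np.ones(n_het, dtype=np.int8),
                np.zeros(n_hom2, dtype=np.int8),
            ]
        )
        dosages[:, j] = rng.permutation(column)
    variants = _make_variants(n_snps, rng)
    samples = [
        SampleRecord(family_id="POP", individual_id=f"POP_{i:04d}", population_label="POP")
        for i in range(n_samples)
    ]
    noise = NoiseSpec(
        n_hwe_violations=1,
        n_low_maf=1,
        n_duplicate_pairs=1,
        n_high_missing_snps=1,
        n_low_call_samples=1,
        n_nonfounder_samples=1,
        n_nonautosomal=1,
    )
    dosages, variants, samples = _apply_noise(dosages, variants, samples, noise, rng)
    dataset = GenotypeDataset(samples=samples, variants=variants, dosages=dosages)
    planted = {
        "founders": [s.individual_id for s in dataset.samples if not s.is_founder],
        "autosomes": [
            v.identifier for v in dataset.variants if v.identifier.endswith("_chrx")
        ],
        "ld_prune": [
            v.identifier for v in dataset.variants if v.identifier.endswith("_dup")
        ],
        "hwe": [
            v.identifier for v in dataset.variants if v.identifier.endswith("_hwe")
        ],
        "sample_call_rate": [
            s.individual_id
            for i, s in enumerate(dataset.samples)
            if (dataset.dosages[i] == MISSING).mean() > 0.05
        ],
        "snp_missingness": [
            v.identifier for v in dataset.variants if v.identifier.endswith("_himiss")
        ],
        "maf": [
            v.identifier for v in dataset.variants if v.identifier.endswith("_lowmaf")
        ],
    }
    return dataset, planted
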