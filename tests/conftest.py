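import numpy as np
import pytest

import finestrat as fs

ACCEPTANCE_SEED = 1


@pytest.fixture
def make_dataset():
    """Factory for small genotype datasets with auto-generated metadata."""

    def build(
        dosages,
        chromosomes=None,
        positions=None,
        parents=None,
        labels=None,
    ):
        dosages = np.asarray(dosages, dtype=np.int8)
        n, m = dosages.shape
        chromosomes = chromosomes if chromosomes is not None else [1] * m
        positions = positions if positions is not None else list(range(1000, 1000 + 1000 * m, 1000))
        variants = [
            fs.Variant(
                chromosome=int(chromosomes[j]),
                position=int(positions[j]),
                identifier=f"v{j}",
                allele1="A",
                allele2="G",
            )
            for j in range(m)
        ]
        samples = []
        for i in range(n):
            father, mother = ("0", "0") if parents is None else parents[i]
            samples.append(
                fs.SampleRecord(
                    family_id="fam",
                    individual_id=f"s{i}",
                    father_id=father,
                    mother_id=mother,
                    population_label=None if labels is None else labels[i],
                )
            )
        return fs.GenotypeDataset(samples=samples, variants=variants, dosages=dosages)

    return build


def _simulate_pops(n_pops, F, n_per_pop, n_snps, seed, names=None, ancestral=(0.05, 0.95)):
    names = names or [f"P{i}" for i in range(n_pops)]
    root = fs.PopulationNode(
        name="root",
        children=[fs.PopulationNode(name=nm, F=F, n_samples=n_per_pop) for nm in names],
    )
    freqs = fs.simulate_tree(
        fs.PopulationTreeSpec(
            root=root,
            n_snps=n_snps,
            seed=seed,
            ancestral_low=ancestral[0],
            ancestral_high=ancestral[1],
        )
    )
    return fs.sample_genotypes(freqs, {nm: n_per_pop for nm in names}, seed=seed + 1)


@pytest.fixture
def simulate_pops():
    return _simulate_pops


@pytest.fixture(scope="session")
def western_dataset():
    return fs.western_africa_like(seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def western_trees(western_dataset):
    """Clustering of the structured preset at both ends of the threshold range."""
    out = {}
    for thr in (0.18, 0.03):
        tree, assignment = fs.ipcaps(
            western_dataset,
            fs.IPCAPSParams(threshold=thr, seed=ACCEPTANCE_SEED),
        )
        out[thr] = (tree, assignment)
    return out
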