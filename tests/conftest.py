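import numpy as np
import pytest

from mothroutes.genotype_data import GenotypeDataset, Individual, LocusInfo


def make_dataset(pop_genos: dict[str, list[list[tuple[int, int] | None]]],
                 locus_names: list[str] | None = None) -> GenotypeDataset:
    """Build a dataset from {pop: [per-individual genotype lists]}."""
    n_loci = len(next(iter(pop_genos.values()))[0])
    loci = [LocusInfo(n) for n in (locus_names or [f"L{j + 1}" for j in range(n_loci)])]
    pops = list(pop_genos)
    inds = [
        [Individual(f"{p}_{i + 1}", list(genos)) for i, genos in enumerate(pop_genos[p])]
        for p in pops
    ]
    return GenotypeDataset(loci, pops, inds)


def random_dataset(rng: np.random.Generator, n_pops=3, n_loci=5, n_ind=8,
                   max_allele=99, missing_rate=0.1) -> GenotypeDataset:
    pop_genos = {}
    for p in range(n_pops):
        inds = []
        for _ in range(n_ind):
            genos = []
            for _ in range(n_loci):
                if rng.random() < missing_rate:
                    genos.append(None)
                else:
                    a, b = rng.integers(1, max_allele + 1, size=2)
                    genos.append((int(a), int(b)))
            inds.append(genos)
        pop_genos[f"p{p + 1}"] = inds
    return make_dataset(pop_genos)


@pytest.fixture(scope="session")
def study_dataset():
    """Study-shaped synthetic dataset (12 pops, 10 loci, 229 diploids)."""
    from mothroutes.synthetic_data import generate_study_like_dataset

    ds, truth = generate_study_like_dataset(seed=2024)
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
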