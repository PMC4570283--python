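"""Shared fixtures: small synthetic datasets with known demographic truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

import isodrift as iso

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from isodrift.simulate import _variant_map


@pytest.fixture(scope="session")
def triple_tree():
    """(focal, sister, outgroup) topology with a strongly drifted focal branch."""
    return iso.PopulationTree.from_dict(
        "root",
        {
            "anc": ("root", 200, 5000),
            "Focal": ("anc", 500, 2471),
            "Sister": ("anc", 500, 10000),
            "Out": ("root", 700, 10000),
        },
    )


@pytest.fixture(scope="session")
def triple_dataset(triple_tree):
    dataset, truth = iso.generate_tree_genotypes(triple_tree, n_loci=8000, n_per_pop=20, seed=11)
    return dataset, truth


@pytest.fixture(scope="session")
def star_dataset():
    """Symmetric star tree: equal drift on every branch, no shared history."""
    tree = iso.star_tree(400, 2471, ["A", "B", "C"])
    dataset, truth = iso.generate_tree_genotypes(tree, n_loci=10000, n_per_pop=20, seed=23)
    return dataset, truth


@pytest.fixture()
def single_pop_dataset():
    """One panmictic Balding-Nichols population (for relatedness tests)."""
    rng = np.random.default_rng(42)
    n, n_loci = 40, 10000
    p = rng.uniform(0.05, 0.95, n_loci)
    dosages = rng.binomial(2, p, size=(n, n_loci)).astype(np.int8)
    samples = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(n)], "population": "P"}
    )
    return iso.GenotypeDataset(dosages, _variant_map(n_loci), samples), p, rng


def make_dataset(dosages, chrom=None, pos_cM=None, populations=None):
    """Small helper to build a GenotypeDataset from a raw dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = _variant_map(m, n_chrom=1)
    if chrom is not None:
        variants["chrom"] = chrom
    if pos_cM is not None:
        variants["pos_cM"] = pos_cM
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": populations if populations is not None else ["P"] * n,
        }
    )
    return iso.GenotypeDataset(dosages, variants, samples)
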