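"""Synthetic genotype and haplotype generators with known demographic truth.

Two generators cover the downstream analyses:

* :func:`generate_tree_genotypes` draws unlinked chip-like SNPs on a
  :class:`~isodrift.trees.PopulationTree` under the Balding-Nichols drift
  model, so pairwise FST, branch lengths and shared-drift orderings are known
  exactly.  :func:`spike_selected_loci` plants selected loci on one branch to
  create positives for the PBS scan.
* :func:`simulate_ld_haplotypes` runs a discrete-locus forward Wright-Fisher
  population with recombination and mutation, giving haplotypes whose r²
  decay follows the Sved expectation ``E[r²] ≈ 1/(2 + 4·Ne·c)`` for
  LD-based Ne recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import VARIANT_COLUMNS, GenotypeDataset
from .trees import PopulationTree

__all__ = [
    "SyntheticTruth",
    "generate_tree_genotypes",
    "spike_selected_loci",
    "simulate_ld_haplotypes",
]


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    tree: PopulationTree
    expected_fst: dict[tuple[str, str], float]
    seed: int
    leaf_frequencies: dict[str, np.ndarray]
    spiked_loci: list[dict] = field(default_factory=list)
    monomorphic: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        for pair, fst in self.expected_fst.items():
            if not (0.0 <= fst < 1.0):
                raise ValueError(f"expected FST out of [0, 1) for {pair}")

    @property
    def spiked_indices(self) -> np.ndarray:
        return np.array(sorted({s["locus"] for s in self.spiked_loci}), dtype=int)


def _root_frequencies(tree: PopulationTree, n_loci: int, rng: np.random.Generator) -> np.ndarray:
    name, *params = tree.root_spectrum
    if name == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, n_loci)
    if name == "beta":
        a, b = params
        return rng.beta(a, b, n_loci)
    raise ValueError(f"unknown root spectrum {name!r}")


def balding_nichols_draw(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: Beta(p(1-F)/F, (1-p)(1-F)/F) around ``p``.

    ``F = 0`` passes frequencies through unchanged; ``F >= 1`` is invalid.
    Frequencies already fixed at 0 or 1 stay fixed (the Beta is degenerate).
    """
    if f < 0 or f >= 1:
        raise ValueError("drift coefficient F must be in [0, 1)")
    if f == 0:
        return p.copy()
    scale = (1.0 - f) / f
    out = np.empty_like(p)
    interior = (p > 0) & (p < 1)
    out[~interior] = p[~interior]
    pi = p[interior]
    out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def _leaf_frequencies(
    tree: PopulationTree, n_loci: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    freqs = {tree.root: _root_frequencies(tree, n_loci, rng)}
    # breadth-first down the tree so parents are always drawn first
    queue = list(tree.children(tree.root))
    while queue:
        node = queue.pop(0)
        br = tree.branches[node]
        freqs[node] = balding_nichols_draw(freqs[br.parent], br.drift_f, rng)
        queue.extend(tree.children(node))
    return {leaf: freqs[leaf] for leaf in tree.leaves}


def _variant_map(n_loci: int, n_chrom: int = 22, spacing_bp: int = 50_000) -> pd.DataFrame:
    """Chip-like variant map: loci spread evenly over ``n_chrom`` chromosomes.

    Positions are ``spacing_bp`` apart with genetic positions at 1 cM/Mb, so
    physical-block jackknives and chromosome-block jackknives both have
    multiple blocks to work with.
    """
    n_chrom = min(n_chrom, n_loci)
    chrom_of = np.arange(n_loci) * n_chrom // n_loci  # contiguous runs
    offsets = np.zeros(n_loci, dtype=np.int64)
    for c in range(n_chrom):
        m = chrom_of == c
        offsets[m] = np.arange(m.sum())
    pos = (offsets + 1) * spacing_bp
    return pd.DataFrame(
        {
            "id": [f"snp{i}" for i in range(n_loci)],
            "chrom": [str(c + 1) for c in chrom_of],
            "pos_bp": pos,
            "pos_cM": pos / 1e6,
            "ancestral": "A",
            "derived": "G",
        },
        columns=VARIANT_COLUMNS,
    )


def generate_tree_genotypes(
    tree: PopulationTree,
    n_loci: int,
    n_per_pop: int,
    seed: int,
    n_chrom: int = 22,
    spacing_bp: int = 50_000,
) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Draw unlinked diploid genotypes for every leaf population of ``tree``.

    Each locus takes a root frequency from the tree's root spectrum, drifts
    down every branch by a Balding-Nichols Beta step with
    ``F = 1 - exp(-t/(2 Ne))``, and leaf genotypes are Binomial(2, p_leaf).
    Loci that come out fixed in every leaf are flagged in
    ``truth.monomorphic`` (they carry no information but keep indices stable).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if n_per_pop < 2:
        raise ValueError("n_per_pop must be >= 2")
    rng = np.random.default_rng(seed)
    leaf_freqs = _leaf_frequencies(tree, n_loci, rng)
    leaves = tree.leaves

    dosages = np.concatenate(
        [rng.binomial(2, leaf_freqs[leaf], size=(n_per_pop, n_loci)) for leaf in leaves]
    ).astype(np.int8)
    samples = pd.DataFrame(
        {
            "sample_id": [f"{leaf}_{i}" for leaf in leaves for i in range(n_per_pop)],
            "population": [leaf for leaf in leaves for _ in range(n_per_pop)],
        }
    )
    dataset = GenotypeDataset(dosages, _variant_map(n_loci, n_chrom, spacing_bp), samples)
    monomorphic = np.all(dosages == dosages[0], axis=0) & np.isin(dosages[0], (0, 2))
    truth = SyntheticTruth(
        tree=tree,
        expected_fst=tree.expected_pairwise_fst(),
        seed=seed,
        leaf_frequencies=leaf_freqs,
        monomorphic=monomorphic,
    )
    return dataset, truth


def spike_selected_loci(
    dataset: GenotypeDataset,
    truth: SyntheticTruth,
    branch: str,
    n_spiked: int,
    shift: float,
    seed: int | None = None,
) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Plant selection signals: shift derived frequency below ``branch`` by ``shift``.

    For ``n_spiked`` randomly chosen loci, the leaf frequencies of every
    population descending from ``branch`` are moved toward derived fixation
    (``p -> min(p + shift, 1)``) and those populations' genotypes at the
    spiked loci are redrawn.  ``shift = 0`` returns the inputs unchanged.
    """
    if branch not in truth.tree.nodes or branch == truth.tree.root:
        raise KeyError(f"branch {branch!r} not in tree")
    if not 0 <= shift <= 1:
        raise ValueError("shift must be in [0, 1]")
    if n_spiked > dataset.n_variants:
        raise ValueError("n_spiked exceeds number of loci")
    if shift == 0 or n_spiked == 0:
        return dataset, truth

    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    loci = np.sort(rng.choice(dataset.n_variants, size=n_spiked, replace=False))
    affected = truth.tree.leaves_below(branch)

    new_freqs = {k: v.copy() for k, v in truth.leaf_frequencies.items()}
    dosages = dataset.dosages.copy()
    for leaf in affected:
        p = new_freqs[leaf]
        p[loci] = np.minimum(p[loci] + shift, 1.0)
        idx = dataset.sample_indices(leaf)
        dosages[np.ix_(idx, loci)] = rng.binomial(2, p[loci], size=(idx.size, loci.size)).astype(np.int8)

    spiked = truth.spiked_loci + [
        {"locus": int(i), "branch": branch, "shift": float(shift)} for i in loci
    ]
    return (
        replace(dataset, dosages=dosages),
        replace(truth, leaf_frequencies=new_freqs, spiked_loci=spiked),
    )


def _crossover_probs(positions_cM: np.ndarray) -> np.ndarray:
    """Adjacent-pair recombination fractions via the inverse Haldane map."""
    d_morgans = np.diff(positions_cM) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def simulate_ld_haplotypes(
    ne: int,
    n_loci: int,
    map_length_cM: float,
    n_generations: int,
    mutation_rate: float,
    sample_size: int,
    seed: int,
    chrom: str = "1",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Forward Wright-Fisher haplotype simulation with recombination.

    A diploid population of size ``ne`` evolves for ``n_generations``
    (recommended >= 4*Ne for burn-in from the random starting state).  Loci
    are evenly spaced on a ``map_length_cM`` map; each gamete recombines
    between adjacent loci with the inverse-Haldane crossover probability, and
    alleles flip symmetrically at ``mutation_rate`` per locus per generation.

    Returns ``(haplotypes, variant_map)`` where ``haplotypes`` is a
    ``(2*sample_size, n_loci)`` 0/1 array of phased haplotypes drawn from the
    final generation.
    """
    if map_length_cM <= 0:
        raise ValueError("map_length_cM must be > 0")
    if sample_size > ne:
        raise ValueError("sample_size cannot exceed the population size")
    rng = np.random.default_rng(seed)
    positions = np.linspace(0.0, map_length_cM, n_loci)
    r = _crossover_probs(positions)  # (n_loci - 1,)
    n_hap = 2 * ne

    if mutation_rate == 0:
        pop = np.zeros((n_hap, n_loci), dtype=np.uint8)  # monomorphic start
    else:
        pop = rng.integers(0, 2, size=(n_hap, n_loci), dtype=np.uint8)

    for _ in range(n_generations):
        parents = rng.integers(0, ne, size=n_hap)
        # Which parental haplotype each locus comes from: Bernoulli switch at
        # every interval, XOR-accumulated from a random starting chromosome.
        switch = np.empty((n_hap, n_loci), dtype=bool)
        switch[:, 0] = rng.integers(0, 2, size=n_hap, dtype=np.uint8).astype(bool)
        switch[:, 1:] = rng.random((n_hap, n_loci - 1)) < r
        origin = np.logical_xor.accumulate(switch, axis=1)
        pop = np.where(origin, pop[2 * parents + 1], pop[2 * parents])
        if mutation_rate > 0:
            n_mut = rng.binomial(n_hap * n_loci, mutation_rate)
            if n_mut:
                flat = rng.integers(0, n_hap * n_loci, size=n_mut)
                pop.ravel()[flat] ^= 1

    freqs = pop.mean(axis=0)
    if np.all((freqs == 0) | (freqs == 1)):
        warnings.warn(
            "all loci are monomorphic after simulation; r^2 is undefined",
            stacklevel=2,
        )

    keep = rng.choice(ne, size=sample_size, replace=False)
    hap_idx = np.sort(np.concatenate([2 * keep, 2 * keep + 1]))
    variant_map = pd.DataFrame(
        {
            "id": [f"L{i}" for i in range(n_loci)],
            "chrom": chrom,
            "pos_bp": np.round(positions * 1e6).astype(np.int64) + 1,
            "pos_cM": positions,
            "ancestral": "A",
            "derived": "G",
        },
        columns=VARIANT_COLUMNS,
    )
    return pop[hap_idx].copy(), variant_map


def haplotypes_to_genotypes(haplotypes: np.ndarray) -> np.ndarray:
    """Pair consecutive haplotype rows into diploid dosages (0/1/2)."""
    if haplotypes.shape[0] % 2:
        raise ValueError("need an even number of haplotypes")
    return (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
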