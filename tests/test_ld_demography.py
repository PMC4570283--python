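"""LD binning, Sved-relation Ne inversion, divergence dating and UPGMA."""

import numpy as np
import pytest

import isodrift as iso
from isodrift.ld_ne import LdBin

from conftest import make_dataset


class TestBinR2:
    def test_duplicated_variants_max_ld(self):
        """Identical columns in the first bin: mean adjusted r² ~ 1 - 1/n."""
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 40).astype(np.int8)
        ds = make_dataset(
            np.column_stack([col, col]),
            pos_cM=np.array([0.0, 0.02]),  # 0.0002 M apart, well inside first bin
        )
        bins = iso.bin_r2(ds, bins=np.array([0.0001, 0.01]), maf=0.0, min_pairs=1)
        assert len(bins) == 1
        assert bins[0].mean_r2_adj == pytest.approx(1 - 1 / 40, abs=1e-9)

    def test_free_recombination_near_zero(self):
        """Independently drawn loci labelled far apart: mean adjusted r² ~ 0."""
        rng = np.random.default_rng(1)
        n, m = 200, 60
        ds = make_dataset(
            rng.binomial(2, 0.5, size=(n, m)).astype(np.int8),
            pos_cM=np.arange(m) * 50.0,  # 0.5 M between neighbours
        )
        bins = iso.bin_r2(
            ds, bins=np.array([0.25, 50.0]), maf=0.05, min_pairs=10
        )
        n_pairs = sum(b.n_pairs for b in bins)
        mean = sum(b.mean_r2_adj * b.n_pairs for b in bins) / n_pairs
        assert mean == pytest.approx(0.0, abs=2 / np.sqrt(n_pairs))

    def test_empty_bins_dropped_midpoints_increase(self, star_dataset):
        dataset, _ = star_dataset
        bins = iso.bin_r2(dataset, min_pairs=1)
        mids = [b.c_mid for b in bins]
        assert mids == sorted(mids) and len(set(mids)) == len(mids)


class TestNeFromBin:
    def _bin(self, c, r2):
        return LdBin(c_lo=c * 0.9, c_hi=c * 1.1, c_mid=c, mean_r2_adj=r2, n_pairs=100, n_diploid=50)

    def test_algebraic_inversion_example(self):
        """c=0.01 M and adjusted r²=1/42 invert to Ne=1000 at t=50 generations."""
        t, ne = iso.ne_from_bin(self._bin(0.01, 1 / 42))
        assert ne == pytest.approx(1000.0)
        assert t == pytest.approx(50.0)

    def test_boundary_r2_undefined(self):
        _, ne = iso.ne_from_bin(self._bin(0.01, 0.5))
        assert np.isnan(ne)

    @pytest.mark.parametrize("ne_true", [100.0, 1000.0, 25000.0])
    @pytest.mark.parametrize("c", [0.001, 0.01, 0.1])
    def test_exact_inverse_of_sved_relation(self, ne_true, c):
        r2 = 1.0 / (2.0 + 4.0 * ne_true * c)
        _, ne = iso.ne_from_bin(self._bin(c, r2))
        assert ne == pytest.approx(ne_true, rel=1e-9)


class TestPairwiseDivergence:
    def test_identical_populations_time_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 3000)
        d = rng.binomial(2, p, size=(60, 3000)).astype(np.int8)
        ds = make_dataset(d, populations=["A"] * 30 + ["B"] * 30)
        res = iso.pairwise_divergence(ds.freq_table(), "A", "B", 2471, 2471)
        # same underlying frequencies: estimate within a few generations of 0
        assert res["t_gen"] < 20

    def test_doubling_generation_time_doubles_years(self, triple_dataset):
        dataset, _ = triple_dataset
        ft = dataset.freq_table()
        r25 = iso.pairwise_divergence(ft, "Focal", "Sister", 2471, 2471, generation_years=25)
        r50 = iso.pairwise_divergence(ft, "Focal", "Sister", 2471, 2471, generation_years=50)
        assert r50["t_years"] == pytest.approx(2 * r25["t_years"], rel=1e-12)
        assert r50["t_gen"] == r25["t_gen"]

    def test_recovers_generating_split_in_years(self):
        """A t=472 / Ne=2471 pair dates to ~11,800 years at 25 years/generation."""
        tree = iso.two_population_tree(472, 2471)
        dataset, _ = iso.generate_tree_genotypes(tree, 20000, 25, seed=41)
        res = iso.pairwise_divergence(dataset.freq_table(), "A", "B", 2471, 2471)
        lo, hi = res["ci_gen"]
        assert lo < 472 < hi
        assert res["t_years"] == pytest.approx(11800, rel=0.1)

    def test_invalid_ne_rejected(self, triple_dataset):
        dataset, _ = triple_dataset
        with pytest.raises(ValueError):
            iso.pairwise_divergence(dataset.freq_table(), "Focal", "Sister", 0, 2471)


def _random_ultrametric(rng, labels):
    """Random ultrametric matrix built from a random merge sequence (known tree)."""
    clusters = [{lab} for lab in labels]
    heights = {}
    clades = []
    h = 0.0
    while len(clusters) > 1:
        h += rng.uniform(1.0, 5.0)
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        merged = clusters[i] | clusters[j]
        for a in clusters[i]:
            for b in clusters[j]:
                heights[frozenset((a, b))] = h
        clades.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    n = len(labels)
    m = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            m[x, y] = m[y, x] = 2 * heights[frozenset((labels[x], labels[y]))]
    return m, set(clades)


def _newick_clades(newick):
    """Clade sets of a Newick string (leaf-label sets of internal nodes)."""
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(newick), "newick")
    return {
        frozenset(t.name for t in clade.get_terminals())
        for clade in tree.get_nonterminals()
    }


class TestUpgma:
    def test_textbook_three_taxa(self):
        m = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        assert iso.upgma(m, ["A", "B", "C"]) == "((A:1,B:1):2,C:3);"

    def test_ultrametric_input_reproduced_exactly(self):
        rng = np.random.default_rng(5)
        labels = list("ABCDE")
        m, _ = _random_ultrametric(rng, labels)
        newick = iso.upgma(m, labels)
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        depths = tree.depths()
        # ultrametric: all leaves at the same depth (root height)
        leaf_depths = [d for c, d in depths.items() if c.is_terminal()]
        assert np.ptp(leaf_depths) < 1e-9 * max(leaf_depths)
        # path distances reproduce the input matrix
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                d = tree.distance(labels[x], labels[y])
                assert d == pytest.approx(m[x, y], rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_six_taxon_topology_matches_generating_tree(self, seed):
        """Random 6-taxon ultrametric matrices: UPGMA recovers the generating
        topology (checked against the merge sequence that built the matrix)."""
        rng = np.random.default_rng(seed)
        labels = list("ABCDEF")
        m, true_clades = _random_ultrametric(rng, labels)
        clades = _newick_clades(iso.upgma(m, labels))
        non_trivial = {c for c in true_clades if 1 < len(c) < len(labels)}
        assert {c for c in clades if 1 < len(c) < len(labels)} == non_trivial

    def test_nan_rejected(self):
        m = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            iso.upgma(m, ["A", "B"])

    def test_divergence_matrix_tree_is_ultrametric(self, triple_dataset):
        dataset, _ = triple_dataset
        dm = iso.divergence_matrix(dataset.freq_table(), ne=2471)
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(dm.newick), "newick")
        depths = [d for c, d in tree.depths().items() if c.is_terminal()]
        assert np.ptp(depths) <= 1e-9 * max(depths)
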