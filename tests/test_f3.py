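"""Outgroup/admixture f3 statistics, block jackknife, ternary shares."""

import numpy as np
import pandas as pd
import pytest

import isodrift as iso
from isodrift.datasets import FreqTable
from isodrift.f3 import jackknife_mean
from isodrift.simulate import _variant_map

from conftest import make_dataset


def freq_table(freqs: dict, counts: dict | None = None, n_chrom=22) -> FreqTable:
    n = len(next(iter(freqs.values())))
    return FreqTable(
        frequencies={k: np.asarray(v, dtype=float) for k, v in freqs.items()},
        counts={
            k: (np.full(n, 100) if counts is None else np.asarray(counts[k]))
            for k in freqs
        },
        variants=_variant_map(n, n_chrom=n_chrom),
    )


class TestF3Outgroup:
    def test_single_snp_arithmetic(self):
        ft = freq_table({"O": [0.5], "A": [0.2], "B": [0.8]})
        res = iso.f3_outgroup(ft, "O", "A", "B")
        assert res.f3 == pytest.approx((0.5 - 0.2) * (0.5 - 0.8))
        assert res.se is None and res.z is None  # single block

    def test_a_equals_b_is_nonnegative_mean_square(self):
        rng = np.random.default_rng(0)
        o, a = rng.uniform(0.1, 0.9, 500), rng.uniform(0.1, 0.9, 500)
        ft = freq_table({"O": o, "A": a, "B": a})
        res = iso.f3_outgroup(ft, "O", "A", "B")
        assert res.f3 == pytest.approx(np.mean((o - a) ** 2))
        assert res.f3 >= 0

    def test_symmetric_in_a_and_b(self, triple_dataset):
        dataset, _ = triple_dataset
        r1 = iso.f3_outgroup(dataset, "Out", "Focal", "Sister")
        r2 = iso.f3_outgroup(dataset, "Out", "Sister", "Focal")
        assert r1.f3 == r2.f3 and r1.se == r2.se

    def test_shared_branch_ordering_matches_tree(self):
        """f3(O;A,B) ranks pairs by shared drift on the generating tree:
        A and B share a long internal branch relative to O; C splits basally."""
        tree = iso.PopulationTree.from_dict(
            "root",
            {
                "internal": ("root", 600, 2000),  # long shared branch for A,B
                "A": ("internal", 100, 5000),
                "B": ("internal", 100, 5000),
                "C": ("root", 100, 5000),
                "O": ("root", 100, 5000),
            },
        )
        dataset, _ = iso.generate_tree_genotypes(tree, 15000, 20, seed=13)
        f_ab = iso.f3_outgroup(dataset, "O", "A", "B")
        f_ac = iso.f3_outgroup(dataset, "O", "A", "C")
        assert f_ab.f3 > f_ac.f3
        assert (f_ab.f3 - f_ac.f3) > 3 * max(f_ab.se, f_ac.se)

    def test_star_tree_pairs_statistically_equal(self, star_dataset):
        """No shared internal branches: all outgroup-f3 pairs agree within 3 SE."""
        dataset, _ = star_dataset
        tree = iso.star_tree(400, 2471, ["A", "B", "C", "D"])
        ds, _ = iso.generate_tree_genotypes(tree, 10000, 20, seed=29)
        vals = {
            pair: iso.f3_outgroup(ds, "D", *pair)
            for pair in [("A", "B"), ("A", "C"), ("B", "C")]
        }
        results = list(vals.values())
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                diff = abs(results[i].f3 - results[j].f3)
                se = np.hypot(results[i].se, results[j].se)
                assert diff < 3 * se


class TestF3Admixture:
    def test_target_same_population_as_source_not_significant(self):
        """Target drawn from the same population as source A: the bias-corrected
        f3 sits at ~0 and is not significantly negative."""
        rng = np.random.default_rng(1)
        n_loci, n_c = 5000, 60
        p = rng.uniform(0.1, 0.9, n_loci)
        b = rng.uniform(0.1, 0.9, n_loci)
        c = rng.binomial(n_c, p) / n_c
        a = rng.binomial(1000, p) / 1000
        ft = freq_table(
            {"C": c, "A": a, "B": b},
            counts={"C": [n_c] * n_loci, "A": [1000] * n_loci, "B": [1000] * n_loci},
        )
        res = iso.f3_admixture(ft, "C", "A", "B")
        assert abs(res.f3) < 0.001
        assert res.z > -3

    def test_fifty_fifty_mixture_strongly_negative(self):
        """Target frequencies midway between two diverged sources: Z < -3."""
        tree = iso.two_population_tree(1500, 2000, ("A", "B"))
        dataset, truth = iso.generate_tree_genotypes(tree, 20000, 25, seed=31)
        rng = np.random.default_rng(32)
        p_mix = 0.5 * (truth.leaf_frequencies["A"] + truth.leaf_frequencies["B"])
        mixed = rng.binomial(2, p_mix, size=(25, 20000)).astype(np.int8)
        ds = iso.GenotypeDataset(
            np.vstack([dataset.dosages, mixed]),
            dataset.variants,
            pd.concat(
                [
                    dataset.samples,
                    pd.DataFrame(
                        {"sample_id": [f"M_{i}" for i in range(25)], "population": "M"}
                    ),
                ],
                ignore_index=True,
            ),
        )
        res = iso.f3_admixture(ds, "M", "A", "B")
        assert res.f3 < 0 and res.z < -3

    def test_drifted_isolate_positive(self, triple_dataset):
        """An unadmixed long-branch isolate shows f3 > 0 (no admixture signal)."""
        dataset, _ = triple_dataset
        res = iso.f3_admixture(dataset, "Focal", "Sister", "Out")
        assert res.f3 > 0

    def test_low_target_counts_excluded(self):
        ft = freq_table(
            {"C": [0.5, 0.5], "A": [0.2, 0.2], "B": [0.8, 0.8]},
            counts={"C": [1, 50], "A": [50, 50], "B": [50, 50]},
        )
        res = iso.f3_admixture(ft, "C", "A", "B")
        assert res.n_snps == 1


class TestJackknife:
    def test_se_shrinks_with_genome_size(self):
        """With fixed 5 Mb blocks, quadrupling the genome halves the SE (~1/sqrt(blocks))."""
        rng = np.random.default_rng(3)
        ses = {}
        for n_blocks in (10, 40, 160):
            n = n_blocks * 50
            values = rng.normal(0.1, 0.05, n)
            blocks = np.repeat(np.arange(n_blocks), 50)
            _, se = jackknife_mean(values, blocks)
            ses[n_blocks] = se
        assert ses[40] == pytest.approx(ses[10] / 2, rel=0.5)
        assert ses[160] == pytest.approx(ses[10] / 4, rel=0.5)

    def test_matches_simple_jackknife_for_equal_blocks(self):
        """Weighted form reduces to the textbook delete-one jackknife when
        every block has the same size."""
        rng = np.random.default_rng(4)
        values = rng.normal(size=200)
        blocks = np.repeat(np.arange(20), 10)
        est, se = jackknife_mean(values, blocks)
        loo = np.array([values[blocks != b].mean() for b in range(20)])
        se_simple = np.sqrt(19 / 20 * ((loo - loo.mean()) ** 2).sum())
        assert est == pytest.approx(values.mean())
        assert se == pytest.approx(se_simple, rel=1e-9)

    def test_fewer_than_two_blocks_gives_no_se(self):
        _, se = jackknife_mean(np.ones(10), np.zeros(10, dtype=int))
        assert se is None


class TestTernaryShares:
    def test_symmetry(self):
        assert iso.ternary_shares(0.1, 0.1, 0.1) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_arithmetic(self):
        assert iso.ternary_shares(0.2, 0.1, 0.1) == pytest.approx((0.5, 0.25, 0.25))

    def test_sums_to_one(self):
        shares = iso.ternary_shares(0.123, 0.456, 0.789)
        assert sum(shares) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            iso.ternary_shares(0.1, -0.2, 0.3)
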