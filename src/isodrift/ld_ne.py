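"""LD-decay demography: Ne from binned r² (Sved relation) and UPGMA dating.

Under the Sved approximation the expected composite r² between loci at
recombination fraction ``c`` in a population of constant diploid size Ne is

    E[r²] ≈ 1/(2 + 4*Ne*c) + 1/n,

where ``1/n`` is the inflation from a sample of n diploids.  Inverting bin
means gives an Ne estimate per bin, and the LD at recombination fraction c
reflects drift roughly ``t = 1/(2c)`` generations ago, yielding an Ne
trajectory.  Genome-wide FST between population pairs, transformed with
``T = log(1-FST)/log(1-1/(2*Ne))`` and a generation time ``g``, gives a
divergence-time matrix that UPGMA turns into a dated ultrametric dendrogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .branch import divergence_time_T, hudson_fst_components
from .datasets import MISSING, FreqTable, GenotypeDataset
from .simulate import haplotypes_to_genotypes

__all__ = [
    "LdBin",
    "NeTrajectory",
    "DivergenceMatrix",
    "bin_r2",
    "ne_from_bin",
    "ne_trajectory",
    "pairwise_divergence",
    "divergence_matrix",
    "upgma",
]

#: 25 logarithmic recombination-distance bins over [0.0005, 0.25] Morgans.
DEFAULT_BINS = np.geomspace(0.0005, 0.25, 26)
DEFAULT_MIN_PAIRS = 50
R2_FLOOR = 1e-6


@dataclass
class LdBin:
    """Mean adjusted r² of variant pairs in one recombination-distance bin.

    ``chrom_sums``/``chrom_counts`` hold the per-chromosome contributions so
    a delete-one-chromosome jackknife can put a CI on the bin mean.
    """

    c_lo: float
    c_hi: float
    c_mid: float
    mean_r2_adj: float
    n_pairs: int
    n_diploid: int
    chrom_sums: dict | None = None
    chrom_counts: dict | None = None

    def __post_init__(self) -> None:
        if not self.c_lo < self.c_hi:
            raise ValueError("bin edges must satisfy c_lo < c_hi")

    def r2_ci(self) -> tuple[float, float]:
        """95% CI on the bin mean by leave-one-chromosome-out jackknife."""
        if not self.chrom_sums or len(self.chrom_sums) < 2:
            return (float("nan"), float("nan"))
        total = sum(self.chrom_sums.values())
        n = sum(self.chrom_counts.values())
        loo = np.array(
            [
                (total - self.chrom_sums[c]) / (n - self.chrom_counts[c])
                for c in self.chrom_sums
                if n > self.chrom_counts[c]
            ]
        )
        g = loo.size
        if g < 2:
            return (float("nan"), float("nan"))
        se = np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
        return (self.mean_r2_adj - 1.96 * se, self.mean_r2_adj + 1.96 * se)


@dataclass
class NeTrajectory:
    """Per-bin (generations ago, Ne) estimates; NaN where r²_adj >= 0.5."""

    table: pd.DataFrame  # t_gen, ne, c, mean_r2_adj, n_pairs
    method: str = "sved-r2-decay"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def ne_median(self, c_min: float = 0.0, c_max: float = np.inf) -> float:
        """Median Ne over bins whose midpoint lies in [c_min, c_max]."""
        t = self.table
        sel = t[(t["c"] >= c_min) & (t["c"] <= c_max) & np.isfinite(t["ne"])]
        return float(sel["ne"].median())


def _as_dosages(data: np.ndarray | GenotypeDataset, population: str | None) -> np.ndarray:
    if isinstance(data, GenotypeDataset):
        d = data.dosages
        if population is not None:
            d = d[data.sample_indices(population)]
        return d
    d = np.asarray(data)
    if d.max(initial=0) <= 1:  # phased haplotypes: pair rows into diploids
        return haplotypes_to_genotypes(d)
    return d


def bin_r2(
    data: np.ndarray | GenotypeDataset,
    pos_cM: np.ndarray | None = None,
    chrom: np.ndarray | None = None,
    bins: np.ndarray = DEFAULT_BINS,
    population: str | None = None,
    maf: float = 0.05,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[LdBin]:
    """Bin pairwise composite r², adjusted for sample size, by map distance.

    ``data`` is a GenotypeDataset (then ``pos_cM``/``chrom`` come from its
    variant map) or a raw dosage/haplotype matrix with explicit positions.
    Only same-chromosome pairs within the bin range enter; each pair's
    ``r² - 1/n`` (n = diploid sample size) is clipped at 1e-6 and averaged
    per bin.  Bins with fewer than ``min_pairs`` pairs are dropped with a
    warning.
    """
    if isinstance(data, GenotypeDataset):
        pos_cM = data.variants["pos_cM"].to_numpy()
        chrom = data.variants["chrom"].to_numpy()
    geno = _as_dosages(data, population)
    if pos_cM is None:
        raise ValueError("pos_cM required for raw matrices")
    pos_cM = np.asarray(pos_cM, dtype=float)
    chrom = np.asarray(chrom) if chrom is not None else np.zeros(pos_cM.size, dtype=int)

    n_dip = geno.shape[0]
    g = geno.astype(float)
    g[geno == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    poly = np.isfinite(freq) & (np.minimum(freq, 1 - freq) >= maf)

    bins = np.asarray(bins, dtype=float)
    sums = np.zeros(bins.size - 1)
    counts = np.zeros(bins.size - 1, dtype=np.int64)
    per_chrom: dict = {}
    for c in pd.unique(chrom):
        sel = np.flatnonzero((chrom == c) & poly)
        if sel.size < 2:
            continue
        sub = g[:, sel]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.isnan(sub).any():
                r = pd.DataFrame(sub).corr().to_numpy()
            else:
                r = np.corrcoef(sub, rowvar=False)
        r2 = r * r
        d = np.abs(pos_cM[sel, None] - pos_cM[None, sel]) / 100.0  # Morgans
        iu = np.triu_indices(sel.size, k=1)
        dist, vals = d[iu], r2[iu]
        ok = np.isfinite(vals)
        dist, vals = dist[ok], vals[ok]
        adj = np.maximum(vals - 1.0 / n_dip, R2_FLOOR)
        which = np.digitize(dist, bins) - 1
        inside = (which >= 0) & (which < bins.size - 1)
        np.add.at(sums, which[inside], adj[inside])
        np.add.at(counts, which[inside], 1)
        c_sums = np.zeros(bins.size - 1)
        c_counts = np.zeros(bins.size - 1, dtype=np.int64)
        np.add.at(c_sums, which[inside], adj[inside])
        np.add.at(c_counts, which[inside], 1)
        per_chrom[c] = (c_sums, c_counts)

    out: list[LdBin] = []
    for k in range(bins.size - 1):
        if counts[k] < min_pairs:
            if counts[k] > 0:
                warnings.warn(f"bin [{bins[k]:.4g}, {bins[k+1]:.4g}) dropped "
                              f"({counts[k]} < {min_pairs} pairs)", stacklevel=2)
            continue
        out.append(
            LdBin(
                c_lo=float(bins[k]),
                c_hi=float(bins[k + 1]),
                c_mid=float(np.sqrt(bins[k] * bins[k + 1])),  # geometric mid of log bins
                mean_r2_adj=float(sums[k] / counts[k]),
                n_pairs=int(counts[k]),
                n_diploid=n_dip,
                chrom_sums={c: float(s[k]) for c, (s, n) in per_chrom.items() if n[k] > 0},
                chrom_counts={c: int(n[k]) for c, (s, n) in per_chrom.items() if n[k] > 0},
            )
        )
    return out


def ne_from_bin(bin: LdBin) -> tuple[float, float]:
    """Invert the Sved relation for one bin: ``Ne = (1/r²_adj - 2)/(4c)``.

    Returns ``(t_generations_ago, Ne)`` with ``t = 1/(2c)``; ``Ne`` is NaN
    (undefined) when the adjusted r² is at or above the 0.5 boundary.
    """
    c = bin.c_mid
    if c == 0:
        raise ValueError("recombination distance c must be > 0")
    if not 0 < bin.mean_r2_adj < 1:
        raise ValueError("bin mean adjusted r^2 must be in (0, 1)")
    t = 1.0 / (2.0 * c)
    ne = (1.0 / bin.mean_r2_adj - 2.0) / (4.0 * c)
    return t, (float("nan") if ne <= 0 else ne)


def ne_trajectory(ld_bins: list[LdBin]) -> NeTrajectory:
    """Assemble an Ne(t) trajectory from a list of LD bins.

    Per-bin CI bounds come from the jackknife CI on the bin's mean r²
    inverted through the Sved relation (higher r² -> lower Ne).
    """

    def _invert(r2: float, c: float) -> float:
        if not np.isfinite(r2) or r2 <= 0:
            return float("nan")
        ne = (1.0 / r2 - 2.0) / (4.0 * c)
        return ne if ne > 0 else float("nan")

    rows = []
    for b in ld_bins:
        t, ne = ne_from_bin(b)
        r2_lo, r2_hi = b.r2_ci()
        rows.append((t, ne, _invert(r2_hi, b.c_mid), _invert(r2_lo, b.c_mid),
                     b.c_mid, b.mean_r2_adj, b.n_pairs))
    table = pd.DataFrame(
        rows, columns=["t_gen", "ne", "ne_lo", "ne_hi", "c", "mean_r2_adj", "n_pairs"]
    )
    return NeTrajectory(table.sort_values("t_gen", ignore_index=True))


# ------------------------------------------------------------------ divergence times
def genomewide_fst(
    freqs: FreqTable, pop_a: str, pop_b: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Ratio-of-averages Hudson FST plus per-variant components for jackknife."""
    pa, pb = freqs[pop_a], freqs[pop_b]
    na, nb = freqs.counts[pop_a].astype(float), freqs.counts[pop_b].astype(float)
    usable = np.isfinite(pa) & np.isfinite(pb) & (na >= 2) & (nb >= 2)
    num, den = hudson_fst_components(pa[usable], na[usable], pb[usable], nb[usable])
    ok = den > 0
    fst = num[ok].sum() / den[ok].sum()
    return float(np.clip(fst, 0.0, 1.0 - 1e-6)), num[ok], den[ok]


def pairwise_divergence(
    freqs: FreqTable,
    pop_a: str,
    pop_b: str,
    ne_a: float,
    ne_b: float,
    generation_years: float = 25.0,
) -> dict:
    """Divergence time between two populations from genome-wide FST.

    ``T = log(1 - FST)/log(1 - 1/(2*Ne_pair))`` with ``Ne_pair`` the harmonic
    mean of the two populations' recent effective sizes; the 95% CI comes
    from a delete-one-chromosome jackknife on the ratio-of-averages FST.
    Returns a dict with ``t_gen``, ``t_years`` and CI bounds in both units.
    """
    if ne_a <= 0 or ne_b <= 0:
        raise ValueError("Ne values must be positive")
    ne_pair = 2.0 / (1.0 / ne_a + 1.0 / ne_b)
    pa, pb = freqs[pop_a], freqs[pop_b]
    na, nb = freqs.counts[pop_a].astype(float), freqs.counts[pop_b].astype(float)
    usable = np.isfinite(pa) & np.isfinite(pb) & (na >= 2) & (nb >= 2)
    num, den = hudson_fst_components(pa[usable], na[usable], pb[usable], nb[usable])
    ok = den > 0
    num, den = num[ok], den[ok]
    chroms = freqs.variants["chrom"].to_numpy()[usable][ok]
    fst = float(np.clip(num.sum() / den.sum(), 0.0, 1.0 - 1e-6))
    t_gen = divergence_time_T(fst, ne_pair)

    uniq = pd.unique(chroms)
    if uniq.size >= 2:
        loo = np.array(
            [
                np.clip(num[chroms != c].sum() / den[chroms != c].sum(), 0.0, 1.0 - 1e-6)
                for c in uniq
            ]
        )
        g = uniq.size
        se_fst = np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
        lo = divergence_time_T(max(fst - 1.96 * se_fst, 0.0), ne_pair)
        hi = divergence_time_T(min(fst + 1.96 * se_fst, 1.0 - 1e-6), ne_pair)
    else:
        lo = hi = float("nan")
    return {
        "fst": fst,
        "t_gen": t_gen,
        "t_years": t_gen * generation_years,
        "ci_gen": (lo, hi),
        "ci_years": (lo * generation_years, hi * generation_years),
        "ne_pair": ne_pair,
        "n_snps": int(ok.sum()),
    }


@dataclass
class DivergenceMatrix:
    """Pairwise divergence times (generations and years) with a UPGMA tree."""

    populations: list[str]
    t_gen: np.ndarray
    t_years: np.ndarray
    ci_years: dict[tuple[str, str], tuple[float, float]]
    generation_years: float
    newick: str = ""

    def to_frame(self, years: bool = True) -> pd.DataFrame:
        m = self.t_years if years else self.t_gen
        return pd.DataFrame(m, index=self.populations, columns=self.populations)


def divergence_matrix(
    freqs: FreqTable,
    ne: dict[str, float] | float,
    generation_years: float = 25.0,
    populations: list[str] | None = None,
) -> DivergenceMatrix:
    """All pairwise divergence times plus the UPGMA dendrogram (heights in years).

    ``ne`` is either one shared diploid effective size or a per-population
    mapping (pairs then use the harmonic mean of the two values).
    """
    pops = populations or freqs.populations
    k = len(pops)
    t_gen = np.zeros((k, k))
    ci: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            ne_i = ne[pops[i]] if isinstance(ne, dict) else ne
            ne_j = ne[pops[j]] if isinstance(ne, dict) else ne
            res = pairwise_divergence(freqs, pops[i], pops[j], ne_i, ne_j, generation_years)
            t_gen[i, j] = t_gen[j, i] = res["t_gen"]
            ci[(pops[i], pops[j])] = res["ci_years"]
    t_years = t_gen * generation_years
    newick = upgma(t_years, pops)
    return DivergenceMatrix(
        populations=list(pops),
        t_gen=t_gen,
        t_years=t_years,
        ci_years=ci,
        generation_years=generation_years,
        newick=newick,
    )


# ------------------------------------------------------------------ UPGMA
def upgma(matrix: np.ndarray, labels: list[str]) -> str:
    """Average-linkage (UPGMA) ultrametric tree from a symmetric distance matrix.

    Node height is half the merged distance, so leaf-to-leaf path lengths
    reproduce an ultrametric input exactly.  Taxa are pre-sorted
    lexicographically so equal-distance merges resolve deterministically.
    Returns a Newick string with branch lengths in the input units.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("need a square distance matrix")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    if np.isnan(matrix).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    order = np.argsort(labels, kind="stable")
    labels = [labels[i] for i in order]
    matrix = matrix[np.ix_(order, order)]
    link = average(squareform(matrix, checks=False))

    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    first_leaf = {i: labels[i] for i in range(n)}  # canonical child order
    for k, (a, b, dist, _cnt) in enumerate(link):
        a, b = int(a), int(b)
        if first_leaf[b] < first_leaf[a]:
            a, b = b, a
        h = dist / 2.0
        node = n + k
        newick[node] = (
            f"({newick[a]}:{h - height[a]:.10g},{newick[b]}:{h - height[b]:.10g})"
        )
        height[node] = h
        first_leaf[node] = first_leaf[a]
    return newick[2 * n - 2] + ";"
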