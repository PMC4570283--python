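"""Per-SNP FST, the Ne-corrected divergence-time transform, and the PBS scan.

The transform

    T = log(1 - FST) / log(1 - 1/(2*Ne))

converts an FST value into an estimate of the divergence time in generations
for a population of diploid effective size Ne drifting as a Wright-Fisher
population.  The population branch statistic for a (focal, sister, outgroup)
triple,

    PBS = (T_fs + T_fo - T_so) / 2,

is the drift accumulated on the focal branch since its splits; per-SNP
outliers in the upper tail are candidates for positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FreqTable, GenotypeDataset

__all__ = [
    "hudson_fst",
    "weir_cockerham_fst",
    "divergence_time_T",
    "pbs",
    "pbs_scan",
    "call_outliers",
    "BranchScoreTable",
]

#: FST ceiling applied before the log transform (keeps T finite at fixed differences).
FST_CLAMP = 1.0 - 1e-6


def hudson_fst(pA, nA, pB, nB):
    """Hudson's per-SNP FST with sample-size correction (Bhatia et al. form).

    ``pA``/``pB`` are derived-allele frequencies and ``nA``/``nB`` allele-copy
    counts.  The estimator is clamped to ``[0, 1 - 1e-6]``; sites fixed for
    the same allele in both populations (denominator 0) return NaN and must
    be excluded by the caller.
    """
    pA, nA, pB, nB = (np.asarray(x, dtype=float) for x in (pA, nA, pB, nB))
    if np.any(nA < 2) or np.any(nB < 2):
        raise ValueError("need at least 2 allele copies per population")
    num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
    den = pA * (1 - pB) + pB * (1 - pA)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return np.clip(fst, 0.0, FST_CLAMP)


def hudson_fst_components(pA, nA, pB, nB):
    """Hudson numerator and denominator separately (for ratio-of-averages FST)."""
    pA, nA, pB, nB = (np.asarray(x, dtype=float) for x in (pA, nA, pB, nB))
    num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
    den = pA * (1 - pB) + pB * (1 - pA)
    return num, den


def weir_cockerham_fst(pA, nA, pB, nB):
    """Weir & Cockerham theta-hat per SNP for two populations (haploid-count form).

    Provided as a config-switchable alternative to :func:`hudson_fst`; same
    clamping and NaN conventions.
    """
    pA, nA, pB, nB = (np.asarray(x, dtype=float) for x in (pA, nA, pB, nB))
    n_bar = (nA + nB) / 2.0
    n_c = nA + nB - (nA**2 + nB**2) / (nA + nB)  # (r*n_bar - sum n_i^2/(r*n_bar)) / (r-1), r=2
    p_bar = (nA * pA + nB * pB) / (nA + nB)
    s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / n_bar  # (r-1)*n_bar = n_bar
    within = p_bar * (1 - p_bar) - s2 / 2.0
    a = n_bar / n_c * (s2 - within / (n_bar - 1))
    b = n_bar / (n_bar - 1) * within
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(a + b > 0, a / (a + b), np.nan)
    return np.clip(fst, 0.0, FST_CLAMP)


def divergence_time_T(fst, ne: float):
    """Divergence time in generations from FST at diploid effective size Ne.

    Exact inverse of ``FST = 1 - (1 - 1/(2*Ne))**T``.  Negative FST (possible
    after estimator correction, clamped upstream) maps to T = 0.
    """
    if ne <= 0.5:
        raise ValueError("Ne must exceed 0.5")
    fst = np.asarray(fst, dtype=float)
    if np.any(fst >= 1):
        raise ValueError("FST must be < 1 (clamp upstream)")
    t = np.log1p(-np.maximum(fst, 0.0)) / np.log1p(-1.0 / (2.0 * ne))
    return t if t.ndim else float(t)


def fst_from_time(t, ne: float):
    """Forward map ``T -> FST = 1 - (1 - 1/(2*Ne))**T`` (inverse of the above)."""
    return -np.expm1(np.asarray(t, dtype=float) * np.log1p(-1.0 / (2.0 * ne)))


def pbs(t_focal_sister, t_focal_out, t_sister_out):
    """Population branch statistic: ``(T_fs + T_fo - T_so) / 2``.

    May be negative; rank-based outlier calling keeps the full distribution.
    """
    return (
        np.asarray(t_focal_sister, dtype=float)
        + np.asarray(t_focal_out, dtype=float)
        - np.asarray(t_sister_out, dtype=float)
    ) / 2.0


@dataclass
class BranchScoreTable:
    """Per-variant FST, branch lengths T and PBS for one population triple."""

    table: pd.DataFrame  # id, chrom, pos_bp, fst_*, t_*, pbs, outlier
    focal: str
    sister: str
    outgroup: str
    ne: float
    n_excluded: int = 0

    @property
    def pbs_values(self) -> np.ndarray:
        return self.table["pbs"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def outliers_to_bed(self, path) -> None:
        """Write outlier positions as BED (0-based half-open)."""
        out = self.table[self.table["outlier"]]
        bed = pd.DataFrame(
            {
                "chrom": out["chrom"],
                "start": out["pos_bp"] - 1,
                "end": out["pos_bp"],
                "name": out["id"],
                "score": out["pbs"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


def pbs_scan(
    dataset: GenotypeDataset | FreqTable,
    focal: str,
    sister: str,
    outgroup: str,
    ne: float = 2471.0,
    ne_per_pair: dict[str, float] | None = None,
    percentile: float = 99.0,
    estimator: str = "hudson",
) -> BranchScoreTable:
    """Per-SNP PBS scan over a (focal, sister, outgroup) triple.

    All three pairwise FSTs are converted to branch lengths with the focal
    population's ``ne`` by default (override per pair with ``ne_per_pair``
    keys ``"focal_sister"``, ``"focal_out"``, ``"sister_out"``).  Variants
    with undefined FST in any pair are excluded and counted in
    ``n_excluded``.  Outliers are the variants at or above the
    ``percentile``-th nearest-rank PBS value.
    """
    if len({focal, sister, outgroup}) != 3:
        raise ValueError("focal, sister and outgroup must be three distinct populations")
    freqs = dataset if isinstance(dataset, FreqTable) else dataset.freq_table([focal, sister, outgroup])
    for pop in (focal, sister, outgroup):
        if pop not in freqs.populations:
            raise KeyError(f"population {pop!r} not present")
    est = {"hudson": hudson_fst, "weir_cockerham": weir_cockerham_fst}[estimator]
    ne_pair = {"focal_sister": ne, "focal_out": ne, "sister_out": ne}
    ne_pair.update(ne_per_pair or {})

    p = {x: freqs[x] for x in (focal, sister, outgroup)}
    n = {x: freqs.counts[x] for x in (focal, sister, outgroup)}
    usable = (n[focal] >= 2) & (n[sister] >= 2) & (n[outgroup] >= 2)
    fst_fs = est(p[focal], n[focal], p[sister], n[sister])
    fst_fo = est(p[focal], n[focal], p[outgroup], n[outgroup])
    fst_so = est(p[sister], n[sister], p[outgroup], n[outgroup])
    usable &= np.isfinite(fst_fs) & np.isfinite(fst_fo) & np.isfinite(fst_so)

    t_fs = divergence_time_T(fst_fs[usable], ne_pair["focal_sister"])
    t_fo = divergence_time_T(fst_fo[usable], ne_pair["focal_out"])
    t_so = divergence_time_T(fst_so[usable], ne_pair["sister_out"])
    scores = pbs(t_fs, t_fo, t_so)

    v = freqs.variants.loc[usable, ["id", "chrom", "pos_bp"]].reset_index(drop=True)
    table = v.assign(
        fst_focal_sister=fst_fs[usable],
        fst_focal_out=fst_fo[usable],
        fst_sister_out=fst_so[usable],
        t_focal_sister=t_fs,
        t_focal_out=t_fo,
        t_sister_out=t_so,
        pbs=scores,
    )
    table["outlier"] = call_outliers(scores, percentile)
    return BranchScoreTable(
        table=table,
        focal=focal,
        sister=sister,
        outgroup=outgroup,
        ne=ne,
        n_excluded=int((~usable).sum()),
    )


def call_outliers(scores: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Flag scores at or above the nearest-rank empirical percentile.

    The threshold is the ``ceil(percentile/100 * N)``-th smallest score
    (nearest-rank definition); every score >= threshold is flagged.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    rank = max(1, int(np.ceil(percentile / 100.0 * n)))
    threshold = np.sort(scores)[rank - 1]
    return scores >= threshold
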