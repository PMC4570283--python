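"""Genotype QC: LD pruning and IBD-based relatedness filtering.

Follows PLINK conventions: composite (Rogers-Huff) r² on unphased dosages,
greedy sliding-window pruning dropping the lower-MAF variant of a violating
pair, and method-of-moments PI_HAT from observed identity-by-state counts.
All statistics use pairwise-complete samples (missing dosages excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset

__all__ = ["QCReport", "genotype_r2", "ld_prune", "ibd_pihat", "remove_related"]


@dataclass
class QCReport:
    """Record of what QC removed and at which thresholds."""

    pruned_variants: list[str] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("variant_pruned", v, "") for v in self.pruned_variants]
        rows += [("sample_removed", s, "") for s in self.removed_samples]
        rows += [("ibd_pair", f"{a},{b}", f"{pihat:.4f}") for a, b, pihat in self.flagged_pairs]
        return pd.DataFrame(rows, columns=["event", "item", "value"])


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = (x != MISSING) & (y != MISSING)
    return x[keep].astype(float), y[keep].astype(float)


def genotype_r2(dataset: GenotypeDataset, i: int, j: int) -> float:
    """Composite (Rogers-Huff) r² between two variants.

    Squared Pearson correlation of the dosage vectors over samples
    non-missing at both variants.  Returns NaN if either variant is
    monomorphic among the shared samples.
    """
    x, y = _pairwise_complete(dataset.dosages[:, i], dataset.dosages[:, j])
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _window_r2(dosages: np.ndarray) -> np.ndarray:
    """Pairwise composite r² matrix for a block of variant columns."""
    d = dosages.astype(float)
    d[dosages == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = pd.DataFrame(d).corr().to_numpy()  # pairwise-complete
    return r * r


def ld_prune(
    dataset: GenotypeDataset,
    r2_threshold: float = 0.4,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypeDataset, QCReport]:
    """Greedy sliding-window LD pruning (PLINK ``--indep-pairwise`` style).

    Windows of ``window`` variants advance by ``step`` along each chromosome.
    Within a window, pairs are scanned left to right; when a retained pair
    exceeds ``r2_threshold`` the member with the lower minor-allele frequency
    is dropped (tie: the larger index).  After pruning, no retained pair
    within any window exceeds the threshold.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    maf = dataset.minor_allele_frequencies()
    keep = np.ones(dataset.n_variants, dtype=bool)
    chrom = dataset.variants["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for start in range(0, len(idx), step):
            win = idx[start : start + window]
            if win.size < 2:
                continue
            r2 = _window_r2(dataset.dosages[:, win])
            for a in range(win.size):
                if not keep[win[a]]:
                    continue
                for b in range(a + 1, win.size):
                    if not keep[win[b]]:
                        continue
                    v = r2[a, b]
                    if np.isnan(v) or v <= r2_threshold:
                        continue
                    ia, ib = win[a], win[b]
                    if maf[ia] < maf[ib] or (maf[ia] == maf[ib] and ia > ib):
                        keep[ia] = False
                        break  # variant a gone; stop scanning its pairs
                    keep[ib] = False
            if start + window >= len(idx):
                break
    report = QCReport(
        pruned_variants=dataset.variants.loc[~keep, "id"].tolist(),
        thresholds={"r2_threshold": r2_threshold, "window": window, "step": step},
    )
    return dataset.take_variants(np.flatnonzero(keep)), report


def ibd_pihat(dataset: GenotypeDataset, sample_a: str, sample_b: str) -> float:
    """PLINK-style method-of-moments PI_HAT between two samples.

    Observed IBS0/IBS1/IBS2 counts over shared non-missing variants are
    equated with their expectations given the pooled allele frequencies to
    solve for P(IBD=0,1,2); PI_HAT = P(IBD=2) + P(IBD=1)/2, clipped to
    [0, 1].  Warns below 100 shared polymorphic variants.
    """
    ia = int(np.flatnonzero((dataset.samples["sample_id"] == sample_a).to_numpy())[0])
    ib = int(np.flatnonzero((dataset.samples["sample_id"] == sample_b).to_numpy())[0])
    return _pihat_from_rows(dataset.dosages[ia], dataset.dosages[ib], dataset.allele_frequencies())


def _pihat_from_rows(da: np.ndarray, db: np.ndarray, p: np.ndarray) -> float:
    shared = (da != MISSING) & (db != MISSING) & (p > 0) & (p < 1)
    if not shared.any():
        raise ValueError("no shared non-missing polymorphic variants")
    if shared.sum() < 100:
        warnings.warn("fewer than 100 shared polymorphic variants; PI_HAT unstable", stacklevel=2)
    x, y, pf = da[shared], db[shared], p[shared]
    q = 1.0 - pf
    ibs = 2 - np.abs(x - y)
    n_ibs0 = float((ibs == 0).sum())
    n_ibs1 = float((ibs == 1).sum())
    n_ibs2 = float((ibs == 2).sum())
    # Expected per-locus IBS probabilities conditional on IBD state
    e0_ibd0 = (2.0 * pf**2 * q**2).sum()
    e1_ibd0 = (4.0 * pf**3 * q + 4.0 * pf * q**3).sum()
    e1_ibd1 = (2.0 * pf**2 * q + 2.0 * pf * q**2).sum()
    e2_ibd0 = (pf**4 + q**4 + 4.0 * pf**2 * q**2).sum()
    e2_ibd1 = (pf**3 + q**3 + pf**2 * q + pf * q**2).sum()
    n = float(shared.sum())
    p0 = n_ibs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (n_ibs1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (n_ibs2 - p0 * e2_ibd0 - p1 * e2_ibd1) / n
    p0, p1, p2 = (max(0.0, v) for v in (p0, p1, p2))
    total = p0 + p1 + p2
    if total > 0:
        p1, p2 = p1 / total, p2 / total
    return float(np.clip(p2 + 0.5 * p1, 0.0, 1.0))


def pihat_matrix(dataset: GenotypeDataset) -> pd.DataFrame:
    """PI_HAT for every sample pair (long format: sample_a, sample_b, pihat)."""
    p = dataset.allele_frequencies()
    ids = dataset.samples["sample_id"].tolist()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append(
                (ids[i], ids[j], _pihat_from_rows(dataset.dosages[i], dataset.dosages[j], p))
            )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "pihat"])


def remove_related(
    dataset: GenotypeDataset, pihat_threshold: float = 0.6
) -> tuple[GenotypeDataset, QCReport]:
    """Drop individuals until no pair has PI_HAT above ``pihat_threshold``.

    Iteratively removes the individual involved in the most violating pairs
    (tie: the later sample id in the table), mirroring the high-IBD filter
    applied before population-structure analyses of inbred isolates.
    """
    pairs = pihat_matrix(dataset)
    flagged = pairs[pairs["pihat"] > pihat_threshold]
    active = set(dataset.samples["sample_id"])
    order = {s: k for k, s in enumerate(dataset.samples["sample_id"])}
    removed: list[str] = []
    live = [(r.sample_a, r.sample_b) for r in flagged.itertuples()]
    while live:
        counts: dict[str, int] = {}
        for a, b in live:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        worst = max(counts, key=lambda s: (counts[s], order[s]))
        removed.append(worst)
        active.discard(worst)
        live = [(a, b) for a, b in live if worst not in (a, b)]
    keep_idx = np.flatnonzero(dataset.samples["sample_id"].isin(active).to_numpy())
    report = QCReport(
        removed_samples=removed,
        flagged_pairs=[(r.sample_a, r.sample_b, r.pihat) for r in flagged.itertuples()],
        thresholds={"pihat_threshold": pihat_threshold},
    )
    return dataset.take_samples(keep_idx), report
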