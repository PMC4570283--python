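"""In-memory containers for genotype panels.

The central object is :class:`GenotypeDataset`: a samples x variants matrix of
derived-allele dosages (0/1/2, ``MISSING`` = -1) together with a variant map
(chromosome, bp, cM, ancestral/derived alleles) and per-sample population
labels.  Frequencies per population are summarised in a :class:`FreqTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype.
MISSING: int = -1

VARIANT_COLUMNS = ["id", "chrom", "pos_bp", "pos_cM", "ancestral", "derived"]


@dataclass
class GenotypeDataset:
    """Diploid derived-allele dosage matrix with variant map and sample table.

    Attributes
    ----------
    dosages
        ``int8`` array of shape ``(n_samples, n_variants)`` with values in
        ``{0, 1, 2, MISSING}`` counting copies of the derived allele.
    variants
        DataFrame with columns ``id, chrom, pos_bp, pos_cM, ancestral, derived``.
    samples
        DataFrame with columns ``sample_id, population``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing:
                raise ValueError(f"variant positions not sorted on chromosome {chrom}")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # ------------------------------------------------------------------ basics
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in dataset")
        return idx

    # ------------------------------------------------------------------ subsetting
    def take_variants(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            dosages=self.dosages[index, :],
            samples=self.samples.iloc[index].reset_index(drop=True),
        )

    # ------------------------------------------------------------------ statistics
    def allele_frequencies(self, population: str | None = None) -> np.ndarray:
        """Derived-allele frequency per variant (NaN where fully missing)."""
        d = self.dosages if population is None else self.dosages[self.sample_indices(population)]
        obs = d != MISSING
        n = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, np.where(obs, d, 0).sum(axis=0) / n, np.nan)

    def allele_counts(self, population: str | None = None) -> np.ndarray:
        """Number of observed allele copies (2 x non-missing samples) per variant."""
        d = self.dosages if population is None else self.dosages[self.sample_indices(population)]
        return 2 * (d != MISSING).sum(axis=0)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def freq_table(self, populations: list[str] | None = None) -> "FreqTable":
        pops = populations if populations is not None else self.populations
        return FreqTable(
            frequencies={p: self.allele_frequencies(p) for p in pops},
            counts={p: self.allele_counts(p) for p in pops},
            variants=self.variants,
        )


@dataclass
class FreqTable:
    """Per-population derived-allele frequencies and allele-copy counts."""

    frequencies: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        for pop, p in self.frequencies.items():
            with np.errstate(invalid="ignore"):
                if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
                    raise ValueError(f"frequencies out of [0, 1] for {pop!r}")

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def __getitem__(self, pop: str) -> np.ndarray:
        return self.frequencies[pop]
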