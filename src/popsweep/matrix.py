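"""Central genotype container shared by all analysis stages.

A :class:`GenotypeMatrix` holds unphased diploid dosages (counts of the
alternate allele, 0/1/2, with ``-1`` for a missing call) for ``n_samples``
individuals at ``n_variants`` biallelic SNPs, together with per-site
metadata (coordinates, alleles, depth and quality annotations) and a
sample → population map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns every variant table carries, in order
VARIANT_COLUMNS = ["contig", "pos", "ref", "alt", "depth", "mq", "base_qual"]


@dataclass
class GenotypeMatrix:
    """Samples × variants diploid dosage matrix with site metadata.

    Parameters
    ----------
    samples
        Sample identifiers, one per matrix row.
    dosages
        ``(n_samples, n_variants)`` integer array of ALT-allele dosages;
        ``-1`` encodes a missing genotype.
    variants
        Per-site metadata table with :data:`VARIANT_COLUMNS`; ``pos`` is
        1-based as in VCF.
    populations
        Mapping of sample id to population label.
    """

    samples: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples × variants array")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but dosage matrix has "
                f"{self.dosages.shape[0]} rows"
            )
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variant records but dosage matrix has "
                f"{self.dosages.shape[1]} columns"
            )
        self.variants = self.variants.reset_index(drop=True)

    # -- basic shape ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def contigs(self) -> list[str]:
        return list(dict.fromkeys(self.variants["contig"]))

    # -- population handling --------------------------------------------

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        """Row indices of samples in *population* (all rows if ``None``)."""
        if population is None:
            return np.arange(self.n_samples)
        idx = [
            i
            for i, s in enumerate(self.samples)
            if self.populations.get(s) == population
        ]
        if not idx:
            raise KeyError(f"no samples labelled {population!r}")
        return np.asarray(idx)

    def population_labels(self) -> list[str]:
        """Distinct population labels in first-seen sample order."""
        return list(dict.fromkeys(self.populations[s] for s in self.samples))

    # -- per-site summaries ----------------------------------------------

    def called_mask(self, population: str | None = None) -> np.ndarray:
        """Boolean (samples × variants) mask of non-missing calls."""
        rows = self.sample_indices(population)
        return self.dosages[rows] != MISSING

    def allele_counts(
        self, population: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-site ``(alt_allele_count, called_allele_count)`` arrays."""
        rows = self.sample_indices(population)
        d = self.dosages[rows]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def allele_freqs(self, population: str | None = None) -> np.ndarray:
        """Per-site ALT frequency among called alleles (NaN if none called)."""
        alt, n = self.allele_counts(population)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def minor_allele_freqs(self, population: str | None = None) -> np.ndarray:
        p = self.allele_freqs(population)
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotype calls."""
        return (self.dosages == MISSING).sum(axis=0) / self.n_samples

    # -- subsetting ------------------------------------------------------

    def take_variants(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given variant mask/index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            dosages=self.dosages[:, idx].copy(),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            populations=dict(self.populations),
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in pos]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        rows = [pos[s] for s in names]
        return GenotypeMatrix(
            samples=list(names),
            dosages=self.dosages[rows].copy(),
            variants=self.variants.copy(),
            populations={s: self.populations[s] for s in names if s in self.populations},
        )

    def variant_positions(self, contig: str) -> np.ndarray:
        """1-based positions of variants on *contig*."""
        return self.variants.loc[self.variants["contig"] == contig, "pos"].to_numpy()
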