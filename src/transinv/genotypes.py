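"""Genotype dosage container shared by every analysis stage.

Genotypes are stored as an (n_samples, n_sites) int8 matrix of alternate-allele
dosages (0/1/2) with ``-1`` marking a missing call.  Positions are 0-based
internally; VCF input/output converts to and from 1-based coordinates at the
boundary.  Sample metadata (population, sex, ...) travels with the matrix so
group selections cannot go out of sync with the dosage rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeTable:
    """Samples x biallelic-sites dosage matrix with site and sample metadata.

    Parameters
    ----------
    dosages
        int8 array of shape (n_samples, n_sites); entries 0, 1, 2 or -1 (missing).
    chrom
        Chromosome label per site.
    pos
        0-based position per site, strictly increasing within a chromosome.
    samples
        DataFrame indexed by sample id with at least a ``population`` column;
        a ``sex`` column ('M'/'F'/'U') is added if absent.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        n_samples, n_sites = self.dosages.shape
        if len(self.chrom) != n_sites or len(self.pos) != n_sites:
            raise ValueError("chrom/pos length must equal number of sites")
        if len(self.samples) != n_samples:
            raise ValueError("samples table length must equal number of dosage rows")
        if "population" not in self.samples.columns:
            raise ValueError("samples table requires a 'population' column")
        if self.samples["population"].isna().any():
            raise ValueError("every sample needs a population label")
        if not self.samples.index.is_unique:
            raise ValueError("sample ids must be unique")
        if "sex" not in self.samples.columns:
            self.samples = self.samples.assign(sex="U")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------ views

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def take_sites(self, mask_or_idx) -> "GenotypeTable":
        idx = np.asarray(mask_or_idx)
        return GenotypeTable(
            self.dosages[:, idx], self.chrom[idx], self.pos[idx], self.samples.copy()
        )

    def take_samples(self, ids) -> "GenotypeTable":
        ids = list(ids)
        missing = [s for s in ids if s not in self.samples.index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        pos_idx = self.samples.index.get_indexer(ids)
        return GenotypeTable(
            self.dosages[pos_idx, :], self.chrom, self.pos, self.samples.loc[ids].copy()
        )

    def restrict(self, chrom: str, start: int | None = None, end: int | None = None) -> "GenotypeTable":
        """Sites on ``chrom`` with ``start <= pos < end`` (0-based half-open)."""
        mask = self.chrom == chrom
        if start is not None:
            mask &= self.pos >= start
        if end is not None:
            mask &= self.pos < end
        return self.take_sites(mask)

    def population_samples(self, population: str) -> list[str]:
        ids = list(self.samples.index[self.samples["population"] == population])
        if not ids:
            raise KeyError(f"unknown population: {population}")
        return ids

    # ------------------------------------------------------- allele counting

    def allele_counts(self, sample_ids=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt-allele count, called-chromosome count) for a sample set."""
        if sample_ids is None:
            d = self.dosages
        else:
            pos_idx = self.samples.index.get_indexer(list(sample_ids))
            if (pos_idx < 0).any():
                raise KeyError("unknown sample id in allele_counts")
            d = self.dosages[pos_idx, :]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0).astype(np.int64)
        n_chrom = 2 * called.sum(axis=0).astype(np.int64)
        return alt, n_chrom

    def heterozygote_counts(self, sample_ids=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (het count, called-sample count)."""
        if sample_ids is None:
            d = self.dosages
        else:
            pos_idx = self.samples.index.get_indexer(list(sample_ids))
            d = self.dosages[pos_idx, :]
        called = d != MISSING
        return (d == 1).sum(axis=0), called.sum(axis=0)
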