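"""Core container for case-control genotype data.

Genotypes are additive minor-allele dosages in {0, 1, 2}; missing entries are
coded as -1 in the integer matrix and surface as NaN from :meth:`GenotypeDataset.dosages`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

SAMPLE_COLUMNS = ("sample_id", "phenotype")
SNP_COLUMNS = ("snp_id", "chrom", "pos", "minor_allele", "major_allele")


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix plus sample and SNP metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` integer array of minor-allele counts;
        ``-1`` marks a missing genotype.
    samples
        Table with columns ``sample_id`` and ``phenotype`` (1 = case,
        0 = control).
    snps
        Table with columns ``snp_id``, ``chrom``, ``pos`` (1-based),
        ``minor_allele``, ``major_allele``; optional ``call_rate`` records
        the pre-imputation call rate.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x SNPs)")
        if not np.issubdtype(self.genotypes.dtype, np.integer):
            self.genotypes = self.genotypes.astype(np.int8)
        n, p = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for {n} genotype rows"
            )
        if len(self.snps) != p:
            raise ValueError(
                f"snp table has {len(self.snps)} rows for {p} genotype columns"
            )
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample table missing column {col!r}")
        for col in SNP_COLUMNS:
            if col not in self.snps.columns:
                raise ValueError(f"snp table missing column {col!r}")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype entries must be in {-1, 0, 1, 2}")
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def phenotype(self) -> np.ndarray:
        """Binary phenotype vector (1 = case, 0 = control)."""
        return self.samples["phenotype"].to_numpy(dtype=np.int64)

    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    def dosages(self, snp_ids: list[str] | None = None) -> np.ndarray:
        """Float dosage matrix with NaN for missing entries."""
        g = self.genotypes
        if snp_ids is not None:
            idx = self._snp_indices(snp_ids)
            g = g[:, idx]
        out = g.astype(float)
        out[g == MISSING] = np.nan
        return out

    def call_rates(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        return (self.genotypes != MISSING).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        return (self.genotypes != MISSING).mean(axis=1)

    def mafs(self) -> np.ndarray:
        """Per-SNP minor allele frequency among observed genotypes.

        The dosage code counts a designated allele; after subsetting samples
        that allele may drift above frequency 0.5, so the folded frequency
        ``min(f, 1 - f)`` is returned.
        """
        obs = self.genotypes != MISSING
        counts = np.where(obs, self.genotypes, 0).sum(axis=0)
        denom = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
        return np.minimum(f, 1.0 - f)

    def allele_freqs(self) -> np.ndarray:
        """Unfolded frequency of the dosage-counted allele."""
        obs = self.genotypes != MISSING
        counts = np.where(obs, self.genotypes, 0).sum(axis=0)
        denom = 2 * obs.sum(axis=0)
        return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    # ------------------------------------------------------------------
    def _snp_indices(self, snp_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return np.asarray([lookup[s] for s in snp_ids], dtype=np.int64)

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Boolean-mask subset along either axis; metadata kept in sync."""
        g = self.genotypes
        samples = self.samples
        snps = self.snps
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask, dtype=bool)
            g = g[sample_mask]
            samples = samples.loc[sample_mask].reset_index(drop=True)
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask, dtype=bool)
            g = g[:, snp_mask]
            snps = snps.loc[snp_mask].reset_index(drop=True)
        return GenotypeDataset(g.copy(), samples.copy(), snps.copy())

    def select_snps(self, snp_ids: list[str]) -> "GenotypeDataset":
        idx = self._snp_indices(snp_ids)
        mask = np.zeros(self.n_snps, dtype=bool)
        mask[idx] = True
        return self.subset(snp_mask=mask)
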