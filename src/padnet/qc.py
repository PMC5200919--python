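"""Genotype quality control: filters, HWE screen, modal imputation,
sliding-window LD pruning and SNP-to-gene flank mapping.

Filter order is fixed: SNP missingness -> sample missingness -> MAF
(recomputed after sample removal) -> Hardy-Weinberg screen in controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dataset import MISSING, GenotypeDataset


@dataclass
class QcReport:
    """Counts and identifiers removed by each filter, plus thresholds used."""

    thresholds: dict = field(default_factory=dict)
    snps_removed_missing: list[str] = field(default_factory=list)
    samples_removed_missing: list[str] = field(default_factory=list)
    snps_removed_maf: list[str] = field(default_factory=list)
    snps_removed_hwe: list[str] = field(default_factory=list)

    @property
    def n_snps_removed(self) -> int:
        return (
            len(self.snps_removed_missing)
            + len(self.snps_removed_maf)
            + len(self.snps_removed_hwe)
        )

    @property
    def n_samples_removed(self) -> int:
        return len(self.samples_removed_missing)

    def to_json(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "snps_removed_missing": self.snps_removed_missing,
            "samples_removed_missing": self.samples_removed_missing,
            "snps_removed_maf": self.snps_removed_maf,
            "snps_removed_hwe": self.snps_removed_hwe,
            "n_snps_removed": self.n_snps_removed,
            "n_samples_removed": self.n_samples_removed,
        }


class EmptyDatasetError(ValueError):
    """All SNPs or all samples were removed by filtering."""

    def __init__(self, message: str, report: QcReport):
        super().__init__(message)
        self.report = report


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, exact: bool = False) -> float:
    """Hardy-Weinberg goodness-of-fit P value from genotype counts.

    Default is the 1-df chi-square test on observed vs expected genotype
    counts under the allele frequency estimated from the sample; ``exact=True``
    uses the conditional exact test (sum of probabilities of heterozygote
    counts no more likely than the observed one).  Monomorphic input returns 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    if (n_Aa == 0 and n_aa == 0) or (n_Aa == 0 and n_AA == 0):
        return 1.0
    if exact:
        return _hwe_exact(n_AA, n_Aa, n_aa)
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    return float(chi2.sf(stat, df=1))


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact HWE test (Wigginton-style enumeration)."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # distribution of heterozygote count given allele counts
    het_max = min(n_rare, 2 * n - n_rare)
    hets = [h for h in range(n_rare % 2, het_max + 1, 2)]
    # unnormalized probabilities by recurrence
    probs = {hets[0]: 1.0}
    for h in hets[1:]:
        prev = probs[h - 2]
        hom_r = (n_rare - (h - 2)) // 2
        hom_c = n - (h - 2) - hom_r
        probs[h] = prev * 4.0 * hom_r * hom_c / ((h - 1) * h)
    total = sum(probs.values())
    obs = probs[n_Aa]
    return float(min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    """Counts of (major-hom, het, minor-hom) among observed entries of a
    dosage column (0 = two major alleles)."""
    obs = column[column != MISSING]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def filter_dataset(
    data: GenotypeDataset,
    snp_miss_max: float = 0.05,
    sample_miss_max: float = 0.05,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-4,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the four QC filters in fixed order and report removals.

    SNPs with missing rate >= ``snp_miss_max`` are dropped, then samples with
    missing rate >= ``sample_miss_max``, then SNPs with recomputed
    MAF <= ``maf_min``, then SNPs failing the Hardy-Weinberg screen
    (P <= ``hwe_alpha``) in controls.
    """
    if data.n_samples == 0 or data.n_snps == 0:
        raise ValueError("dataset is empty")
    report = QcReport(
        thresholds={
            "snp_miss_max": snp_miss_max,
            "sample_miss_max": sample_miss_max,
            "maf_min": maf_min,
            "hwe_alpha": hwe_alpha,
        }
    )
    # 1. SNP missingness
    miss = 1.0 - data.call_rates()
    keep = miss < snp_miss_max
    report.snps_removed_missing = data.snps.loc[~keep, "snp_id"].tolist()
    data = data.subset(snp_mask=keep)
    if data.n_snps == 0:
        raise EmptyDatasetError("all SNPs removed by missingness filter", report)

    # 2. sample missingness
    smiss = 1.0 - data.sample_call_rates()
    skeep = smiss < sample_miss_max
    report.samples_removed_missing = data.samples.loc[~skeep, "sample_id"].tolist()
    data = data.subset(sample_mask=skeep)
    if data.n_samples == 0:
        raise EmptyDatasetError("all samples removed by missingness filter", report)

    # 3. MAF, recomputed after sample removal
    maf = data.mafs()
    keep = maf > maf_min
    report.snps_removed_maf = data.snps.loc[~keep, "snp_id"].tolist()
    data = data.subset(snp_mask=keep)
    if data.n_snps == 0:
        raise EmptyDatasetError("all SNPs removed by MAF filter", report)

    # 4. HWE in controls
    controls = data.phenotype() == 0
    if controls.any():
        g = data.genotypes[controls]
        keep = np.ones(data.n_snps, dtype=bool)
        for j in range(data.n_snps):
            n0, n1, n2 = _genotype_counts(g[:, j])
            if hwe_test(n0, n1, n2) <= hwe_alpha:
                keep[j] = False
        report.snps_removed_hwe = data.snps.loc[~keep, "snp_id"].tolist()
        data = data.subset(snp_mask=keep)
        if data.n_snps == 0:
            raise EmptyDatasetError("all SNPs removed by HWE filter", report)
    return data, report


def impute_most_frequent(data: GenotypeDataset) -> GenotypeDataset:
    """Replace each missing genotype by that SNP's modal observed code.

    Modal ties resolve toward the smaller dosage code.  The pre-imputation
    call rate is recorded in the SNP table (used later by the pruning
    tie-break rule).
    """
    g = data.genotypes.copy()
    call_rate = data.call_rates()
    for j in range(data.n_snps):
        col = g[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(
                f"SNP {data.snps['snp_id'].iloc[j]} has no observed genotypes"
            )
        counts = np.bincount(obs, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the smaller code on ties
        col[miss] = mode
    snps = data.snps.copy()
    snps["call_rate"] = call_rate
    return GenotypeDataset(g, data.samples.copy(), snps)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Returns 0 if either vector is constant.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have the same length")
    if g1.ndim != 1 or g1.size < 2:
        raise ValueError("need 1-D vectors of length >= 2")
    if np.isnan(g1).any() or np.isnan(g2).any():
        raise ValueError("missing values present; impute first")
    v1, v2 = g1.var(), g2.var()
    if v1 == 0 or v2 == 0:
        return 0.0
    c = np.cov(g1, g2, bias=True)[0, 1]
    return float(c * c / (v1 * v2))


def _prune_window(
    r2mat: np.ndarray,
    retained: np.ndarray,
    idx: np.ndarray,
    miss_counts: np.ndarray,
    mafs: np.ndarray,
    pos: np.ndarray,
    r2_max: float,
) -> None:
    """Remove SNPs inside one window until no retained pair has r2 > r2_max.

    Of an offending pair, the member with more pre-imputation missing data is
    removed; ties break toward the lower MAF, then toward the later position.
    Pairs are visited in index order for determinism.
    """
    m = len(idx)
    while True:
        offending = None
        for a in range(m):
            if not retained[idx[a]]:
                continue
            for b in range(a + 1, m):
                if not retained[idx[b]]:
                    continue
                if r2mat[a, b] > r2_max:
                    offending = (a, b)
                    break
            if offending:
                break
        if offending is None:
            return
        a, b = offending
        ia, ib = idx[a], idx[b]
        # more missing -> remove; tie: lower MAF; tie: later position
        if miss_counts[ia] != miss_counts[ib]:
            drop = ia if miss_counts[ia] > miss_counts[ib] else ib
        elif mafs[ia] != mafs[ib]:
            drop = ia if mafs[ia] < mafs[ib] else ib
        else:
            drop = ia if pos[ia] > pos[ib] else ib
        retained[drop] = False


def prune_tag_snps(
    data: GenotypeDataset,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.8,
) -> tuple[GenotypeDataset, list[str]]:
    """Moving-window tag-SNP selection per chromosome.

    A ``window``-SNP window slides by ``step``; inside each window SNPs are
    removed (per the deterministic rule in ``_prune_window``) until every
    retained pair has r2 <= ``r2_max``.  A SNP removed in any window stays
    removed.  Requires imputed (no-missing) data sorted by (chrom, pos).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if data.has_missing():
        raise ValueError("prune_tag_snps requires imputed data")
    order = np.lexsort((data.snps["pos"].to_numpy(), data.snps["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(data.n_snps)):
        raise ValueError("SNPs must be sorted by (chrom, pos)")
    g = data.genotypes.astype(float)
    mafs = data.mafs()
    pos = data.snps["pos"].to_numpy()
    if "call_rate" in data.snps.columns:
        miss_counts = np.round(
            (1.0 - data.snps["call_rate"].to_numpy()) * data.n_samples
        ).astype(int)
    else:
        miss_counts = np.zeros(data.n_snps, dtype=int)
    retained = np.ones(data.n_snps, dtype=bool)

    chroms = data.snps["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        n = len(cidx)
        starts = list(range(0, max(n - window, 0) + 1, step)) or [0]
        for s in starts:
            widx = cidx[s : s + window]
            sub = g[:, widx]
            sd = sub.std(axis=0)
            centered = sub - sub.mean(axis=0)
            denom = np.outer(sd, sd)
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = (centered.T @ centered) / (data.n_samples * denom)
            r2mat = np.where(denom > 0, corr**2, 0.0)
            _prune_window(
                r2mat, retained, widx, miss_counts, mafs, pos, r2_max
            )
    removed = data.snps.loc[~retained, "snp_id"].tolist()
    return data.subset(snp_mask=retained), removed


def map_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, flank: int = 5000
) -> tuple[pd.DataFrame, list[str]]:
    """Map SNPs to genes within ``flank`` bp of the gene body.

    Genes use BED 0-based half-open intervals ``[start, end)``; a SNP at
    1-based position p maps to a gene iff
    ``start + 1 - flank <= p <= end + flank``.  A SNP may map to several
    genes; unmapped SNP ids are returned separately.
    """
    rows = []
    mapped: set[str] = set()
    for gene in genes.itertuples(index=False):
        lo = gene.start + 1 - flank
        hi = gene.end + flank
        sel = snps[
            (snps["chrom"].astype(str) == str(gene.chrom))
            & (snps["pos"] >= lo)
            & (snps["pos"] <= hi)
        ]
        for sid in sel["snp_id"]:
            rows.append({"snp_id": sid, "gene_id": gene.gene_id})
            mapped.add(sid)
    unmapped = [s for s in snps["snp_id"] if s not in mapped]
    mapping = pd.DataFrame(rows, columns=["snp_id", "gene_id"])
    return mapping, unmapped
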