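"""Pairwise SNP x SNP epistasis scan over significant-pathway SNPs.

Each unordered SNP pair is tested with the full logistic interaction model

    logit P(y=1) = b0 + b1 g1 + b2 g2 + b3 g1 g2

and the Wald z-test of b3 = 0 (two-sided).  Pairs at nominal P < alpha are
retained and translated to candidate gene pairs; multiple-testing control is
deliberately deferred to the downstream PPI-support filter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .dataset import GenotypeDataset

logger = logging.getLogger(__name__)

_SEPARATION_BOUND = 15.0


@dataclass
class EpistasisResult:
    snp_a: str
    snp_b: str
    beta_int: float | None
    se: float | None
    p: float | None
    n_used: int
    status: str = "ok"  # ok | not_testable | separation
    reason: str = ""

    def __post_init__(self) -> None:
        if self.snp_a > self.snp_b:
            self.snp_a, self.snp_b = self.snp_b, self.snp_a


@dataclass
class GenePairCandidate:
    gene_a: str
    gene_b: str
    supporting_pairs: int
    min_p: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("gene pair must join distinct genes")
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a


def _logistic_fit(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS logistic fit; returns (beta, covariance, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    beta[0] = np.log(y.mean() / (1 - y.mean()))  # start at the null intercept
    cov = np.full((k, k), np.nan)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        score = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            return beta, cov, False
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return beta, cov, False
            return beta, cov, True
    return beta, cov, False


def interaction_test(
    g1: np.ndarray, g2: np.ndarray, y: np.ndarray, snp_a: str = "a", snp_b: str = "b"
) -> EpistasisResult:
    """Wald test of the g1 x g2 interaction term in a two-SNP logistic model.

    Constant predictors (including a constant product column — minor alleles
    never co-occurring) yield a not-testable result; fits escaping to
    |coefficient| > 15 are flagged as quasi-separation and excluded
    downstream.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (g1.shape == g2.shape == y.shape):
        raise ValueError("g1, g2 and y must have equal lengths")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("phenotype must contain both classes")
    n = y.size
    prod = g1 * g2
    for name, v in (("g1", g1), ("g2", g2), ("g1*g2", prod)):
        if np.ptp(v) == 0:
            return EpistasisResult(
                snp_a, snp_b, None, None, None, n,
                status="not_testable", reason=f"constant column {name}",
            )
    X = np.column_stack([np.ones(n), g1, g2, prod])
    beta, cov, converged = _logistic_fit(X, y)
    if not converged or not np.isfinite(cov).all():
        return EpistasisResult(
            snp_a, snp_b, None, None, None, n,
            status="not_testable", reason="IRLS did not converge",
        )
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        return EpistasisResult(
            snp_a, snp_b, float(beta[3]), None, None, n,
            status="separation", reason="quasi-separation (|b| > 15)",
        )
    se = float(np.sqrt(cov[3, 3]))
    z = beta[3] / se
    p = float(2.0 * norm.sf(abs(z)))
    return EpistasisResult(snp_a, snp_b, float(beta[3]), se, p, n)


def scan_significant_pathways(
    data: GenotypeDataset,
    sig_sets: list,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[EpistasisResult]:
    """Test every unordered pair of distinct SNPs in the union of the
    significant pathways' SNP sets (within- and cross-pathway) and retain
    results with p < alpha.

    By design the default is the nominal screen with no multiple-testing
    correction — downstream PPI support acts as the false positive filter;
    ``bonferroni=True`` instead retains pairs at p < alpha / n_pairs.
    """
    if not sig_sets:
        raise ValueError("no significant pathway SNP sets supplied")
    union: set[str] = set()
    for s in sig_sets:
        union.update(s.snp_ids)
    snp_ids = sorted(union)
    if len(snp_ids) < 2:
        raise ValueError("need at least two SNPs to scan for epistasis")
    Z = data.dosages(snp_ids)
    if np.isnan(Z).any():
        raise ValueError("scan requires imputed data")
    y = data.phenotype().astype(float)
    n_pairs = len(snp_ids) * (len(snp_ids) - 1) // 2
    cutoff = alpha / n_pairs if bonferroni else alpha
    retained: list[EpistasisResult] = []
    n_tested = 0
    for i, j in itertools.combinations(range(len(snp_ids)), 2):
        n_tested += 1
        res = interaction_test(Z[:, i], Z[:, j], y, snp_ids[i], snp_ids[j])
        if res.status == "ok" and res.p is not None and res.p < cutoff:
            retained.append(res)
    logger.info(
        "epistasis scan: %d pairs tested, %d retained at alpha=%s",
        n_tested, len(retained), alpha,
    )
    return retained


def pairs_to_genes(
    results: list[EpistasisResult], snp_gene_map: pd.DataFrame
) -> list[GenePairCandidate]:
    """Expand retained SNP pairs into candidate gene pairs.

    Each pair expands to all (gene-of-a x gene-of-b) combinations; same-gene
    combinations are dropped; duplicates collapse with ``supporting_pairs``
    incremented and the minimum p tracked.  SNPs absent from the map are
    dropped with a log entry.
    """
    gene_of: dict[str, list[str]] = {}
    for row in snp_gene_map.itertuples(index=False):
        gene_of.setdefault(row.snp_id, []).append(row.gene_id)
    merged: dict[tuple[str, str], list] = {}
    for res in results:
        genes_a = gene_of.get(res.snp_a)
        genes_b = gene_of.get(res.snp_b)
        if not genes_a or not genes_b:
            missing = res.snp_a if not genes_a else res.snp_b
            logger.info("dropping pair %s-%s: %s unmapped", res.snp_a, res.snp_b, missing)
            continue
        for ga in genes_a:
            for gb in genes_b:
                if ga == gb:
                    continue
                key = (ga, gb) if ga < gb else (gb, ga)
                p = res.p if res.p is not None else 1.0
                if key in merged:
                    merged[key][0] += 1
                    merged[key][1] = min(merged[key][1], p)
                else:
                    merged[key] = [1, p]
    return [
        GenePairCandidate(a, b, count, min_p)
        for (a, b), (count, min_p) in sorted(merged.items())
    ]


def candidates_to_frame(candidates: list[GenePairCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": c.gene_a,
                "gene_b": c.gene_b,
                "supporting_pairs": c.supporting_pairs,
                "min_p": c.min_p,
            }
            for c in candidates
        ],
        columns=["gene_a", "gene_b", "supporting_pairs", "min_p"],
    )


def results_to_frame(results: list[EpistasisResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_a": r.snp_a,
                "snp_b": r.snp_b,
                "beta_int": r.beta_int,
                "se": r.se,
                "p": r.p,
                "n_used": r.n_used,
                "status": r.status,
            }
            for r in results
        ],
        columns=["snp_a", "snp_b", "beta_int", "se", "p", "n_used", "status"],
    )
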