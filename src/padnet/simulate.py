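"""Synthetic case-control GWAS inputs with known planted truth.

Generates every input the pipeline consumes — gene coordinates, pathway gene
sets, genotypes with a binary phenotype from a logistic model, PPI edges and a
GO-style ontology with annotations — so that pathway main effects and SNP x SNP
interactions planted in the simulation can be recovered downstream and checked
against the truth record.

The phenotype model is

    logit P(y_i = 1) = beta0 + sum_j beta_j g_ij + sum_(a,b) gamma_ab g_ia g_ib

with g additive minor-allele dosages, per-SNP main effects ``beta_j`` applied
to all SNPs of a risk pathway's genes, and pairwise interaction effects
``gamma_ab`` for planted epistatic SNP pairs.  ``beta0`` is tuned by bisection
so the expected population prevalence matches the target case fraction, and
individuals are then sampled until the exact case/control quotas are filled —
mimicking a retrospective case-control design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import io
from .dataset import MISSING, GenotypeDataset


class SizingError(ValueError):
    """Raised when requested genes cannot be packed onto the chromosomes."""


class ConfigError(ValueError):
    """Raised for inconsistent simulation settings."""


# RNG stream tags: one independent child stream per generation stage
_STREAM_GENES = 1
_STREAM_PATHWAYS = 2
_STREAM_GENOTYPES = 3
_STREAM_PPI = 4
_STREAM_GO = 5


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults emulate a typical consortium case-control design at desk scale:
    more controls than cases (2:3 ratio), a few percent missing genotypes,
    MAFs spread over the common-variant range, and pathway sizes of a few
    to a few dozen genes.
    """

    n_cases: int = 2000
    n_controls: int = 3000
    n_genes: int = 100
    snps_per_gene: tuple[int, int] = (3, 10)
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (5, 30)
    risk_pathways: dict[str, float] = field(default_factory=dict)
    epistatic_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    ppi_background_prob: float = 0.01
    disjoint_pathways: bool = False
    ld_blocks: bool = False
    # latent Gaussian correlation; dosage r2 is attenuated (~0.85 at 0.99)
    ld_latent_rho: float = 0.99
    seed: int = 0
    chrom_length: int = 10_000_000
    n_chromosomes: int = 22

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("n_cases and n_controls must be >= 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.missing_rate < 0.5):
            raise ConfigError("missing_rate must lie in [0, 0.5)")
        if not (0 <= self.ppi_background_prob <= 1):
            raise ConfigError("ppi_background_prob must lie in [0, 1]")
        a, b = self.pathway_size_range
        if a > b:
            raise ConfigError("pathway_size_range is empty")
        if b > self.n_genes:
            raise ConfigError("pathway_size_range max exceeds n_genes")
        a, b = self.snps_per_gene
        if a < 1 or a > b:
            raise ConfigError("snps_per_gene range invalid")
        for snp_a, snp_b, _ in self.epistatic_pairs:
            if snp_a == snp_b:
                raise ConfigError(f"epistatic pair names the same SNP twice: {snp_a}")
            if _gene_of(snp_a) == _gene_of(snp_b):
                raise ConfigError(
                    f"epistatic pair {snp_a}-{snp_b} lies within one gene; "
                    "pairs must span two distinct genes"
                )


def _gene_of(snp_id: str) -> str:
    """Gene id encoded in a generated SNP id ``G####_S##``."""
    return snp_id.rsplit("_", 1)[0]


def gene_id(i: int) -> str:
    return f"G{i + 1:04d}"


def pathway_id(i: int) -> str:
    return f"PW{i + 1:02d}"


def snp_id(gene: str, j: int) -> str:
    return f"{gene}_S{j + 1:02d}"


@dataclass
class TruthRecord:
    """Planted ground truth emitted alongside the synthetic data."""

    risk_pathway_ids: list[str]
    null_pathway_ids: list[str]
    planted_pairs: list[dict]  # snp_a, snp_b, gene_a, gene_b, gamma
    snp_betas: pd.DataFrame  # snp_id, beta
    beta0: float = 0.0

    def __post_init__(self) -> None:
        if set(self.risk_pathway_ids) & set(self.null_pathway_ids):
            raise ConfigError("risk and null pathway id sets must be disjoint")

    def to_json(self) -> dict:
        return {
            "risk_pathway_ids": self.risk_pathway_ids,
            "null_pathway_ids": self.null_pathway_ids,
            "planted_pairs": self.planted_pairs,
            "snp_betas": self.snp_betas.to_dict(orient="records"),
            "beta0": self.beta0,
        }


# ------------------------------------------------------------------ genes


def generate_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals (BED, 0-based half-open) on >=1 chromosomes.

    Each gene is long enough to host its SNPs with 1 kb spacing; genes are
    placed left to right with random inter-genic gaps and wrap onto the next
    chromosome when the current one is full.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENES])
    lo, hi = config.snps_per_gene
    n_snps = rng.integers(lo, hi + 1, size=config.n_genes)
    lengths = n_snps * 1000 + 2000
    rows = []
    chrom_i, cursor = 0, 0
    for i in range(config.n_genes):
        gap = int(rng.integers(20_000, 100_000))
        start = cursor + gap
        end = start + int(lengths[i])
        if end > config.chrom_length:
            chrom_i += 1
            if chrom_i >= config.n_chromosomes:
                raise SizingError(
                    f"cannot pack {config.n_genes} genes onto "
                    f"{config.n_chromosomes} chromosomes of {config.chrom_length} bp"
                )
            cursor = 0
            start = cursor + gap
            end = start + int(lengths[i])
            if end > config.chrom_length:
                raise SizingError(f"gene {i} longer than a chromosome")
        rows.append(
            {
                "chrom": str(chrom_i + 1),
                "start": start,
                "end": end,
                "gene_id": gene_id(i),
                "n_snps": int(n_snps[i]),
            }
        )
        cursor = end
    return pd.DataFrame(rows)


# --------------------------------------------------------------- pathways


def generate_pathways(
    config: SimulationConfig, genes: pd.DataFrame
) -> dict[str, list[str]]:
    """Named gene sets; genes may belong to several pathways.

    Pathways declared in ``config.risk_pathways`` must name ids among the
    generated ``PW01..`` series; their gene sets are drawn like the rest.
    """
    lo, hi = config.pathway_size_range
    if hi > len(genes):
        raise ConfigError("pathway size range exceeds available genes")
    rng = np.random.default_rng([config.seed, _STREAM_PATHWAYS])
    all_ids = [pathway_id(i) for i in range(config.n_pathways)]
    unknown = set(config.risk_pathways) - set(all_ids)
    if unknown:
        raise ConfigError(f"risk pathways not among generated ids: {sorted(unknown)}")
    gene_ids = genes["gene_id"].tolist()
    out: dict[str, list[str]] = {}
    if config.disjoint_pathways:
        # partition genes: each gene belongs to at most one pathway, so
        # non-risk pathways are genuinely null
        sizes = [int(rng.integers(lo, hi + 1)) for _ in all_ids]
        if sum(sizes) > len(gene_ids):
            raise ConfigError(
                "disjoint pathways need sum(sizes) <= n_genes; "
                f"got {sum(sizes)} > {len(gene_ids)}"
            )
        pool = [gene_ids[k] for k in rng.permutation(len(gene_ids))]
        cursor = 0
        for pid, size in zip(all_ids, sizes):
            out[pid] = sorted(pool[cursor : cursor + size])
            cursor += size
        return out
    for pid in all_ids:
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(gene_ids), size=size, replace=False)
        out[pid] = [gene_ids[k] for k in sorted(chosen)]
    return out


# -------------------------------------------------------------- genotypes


def _snp_table(config: SimulationConfig, genes: pd.DataFrame, rng) -> pd.DataFrame:
    bases = np.array(list("ACGT"))
    rows = []
    for g in genes.itertuples(index=False):
        span = g.end - g.start
        # distinct 1-based positions inside the gene body
        pos = np.sort(rng.choice(span, size=g.n_snps, replace=False)) + g.start + 1
        for j in range(g.n_snps):
            a1, a2 = rng.choice(4, size=2, replace=False)
            rows.append(
                {
                    "snp_id": snp_id(g.gene_id, j),
                    "chrom": g.chrom,
                    "pos": int(pos[j]),
                    "minor_allele": bases[a1],
                    "major_allele": bases[a2],
                    "gene_id": g.gene_id,
                }
            )
    return pd.DataFrame(rows)


def _draw_genotypes(
    config: SimulationConfig, mafs: np.ndarray, gene_index: np.ndarray, n: int, rng
) -> np.ndarray:
    """Draw an n x p dosage matrix; optional within-gene LD via a Gaussian
    copula with a shared per-gene latent factor."""
    p = len(mafs)
    if not config.ld_blocks:
        return rng.binomial(2, mafs, size=(n, p)).astype(np.int8)
    rho = config.ld_latent_rho
    common = rng.standard_normal((n, int(gene_index.max()) + 1))
    eps = rng.standard_normal((n, p))
    x = np.sqrt(rho) * common[:, gene_index] + np.sqrt(1 - rho) * eps
    # HWE genotype thresholds on the latent normal scale
    t0 = norm.ppf((1 - mafs) ** 2)
    t1 = norm.ppf(1 - mafs**2)
    return ((x > t0).astype(np.int8) + (x > t1).astype(np.int8))


def _linear_predictor(
    G: np.ndarray, betas: np.ndarray, pairs: list[tuple[int, int, float]]
) -> np.ndarray:
    eta = G @ betas
    for ia, ib, gamma in pairs:
        eta = eta + gamma * G[:, ia] * G[:, ib]
    return eta


def _tune_intercept(
    config: SimulationConfig,
    mafs: np.ndarray,
    gene_index: np.ndarray,
    betas: np.ndarray,
    pairs: list[tuple[int, int, float]],
    rng,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """Bisection on beta0 so that mean sigmoid(beta0 + eta) hits the target
    prevalence, estimated on a fixed Monte-Carlo tuning panel."""
    target = config.n_cases / (config.n_cases + config.n_controls)
    if not pairs and not betas.any():
        # no effects: prevalence is sigmoid(beta0) exactly
        return float(np.log(target / (1.0 - target)))
    panel = _draw_genotypes(config, mafs, gene_index, 20_000, rng)
    eta = _linear_predictor(panel.astype(float), betas, pairs)

    def prev(b0: float) -> float:
        return float(expit(b0 + eta).mean())

    lo, hi = -30.0, 30.0
    if not (prev(lo) - tol <= target <= prev(hi) + tol):
        raise ConfigError(
            f"target prevalence {target:.3f} unattainable given planted effects"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    b0 = 0.5 * (lo + hi)
    if abs(prev(b0) - target) > 50 * tol:
        raise ConfigError("intercept tuning did not converge")
    return b0


def generate_genotypes(
    config: SimulationConfig,
    genes: pd.DataFrame,
    pathways: dict[str, list[str]],
) -> tuple[GenotypeDataset, TruthRecord]:
    """Sample genotypes and a binary phenotype with the planted effects.

    Individuals are drawn in batches and assigned case/control by the
    logistic model until both quotas are exactly filled; missing entries are
    then inserted completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENOTYPES])
    snps = _snp_table(config, genes, rng)
    p = len(snps)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    gene_codes, gene_index = np.unique(snps["gene_id"], return_inverse=True)

    # per-SNP main effects: SNPs of every gene in a risk pathway get that
    # pathway's per-SNP beta (summed if a gene sits in several risk pathways)
    betas = np.zeros(p)
    snp_idx = {s: i for i, s in enumerate(snps["snp_id"])}
    gene_to_snps: dict[str, list[int]] = {}
    for i, g in enumerate(snps["gene_id"]):
        gene_to_snps.setdefault(g, []).append(i)
    for pid, beta in config.risk_pathways.items():
        for g in pathways[pid]:
            for i in gene_to_snps.get(g, []):
                betas[i] += beta

    pairs: list[tuple[int, int, float]] = []
    planted = []
    for snp_a, snp_b, gamma in config.epistatic_pairs:
        for s in (snp_a, snp_b):
            if s not in snp_idx:
                raise ConfigError(f"planted epistatic SNP {s} not generated")
        pairs.append((snp_idx[snp_a], snp_idx[snp_b], gamma))
        planted.append(
            {
                "snp_a": snp_a,
                "snp_b": snp_b,
                "gene_a": _gene_of(snp_a),
                "gene_b": _gene_of(snp_b),
                "gamma": gamma,
            }
        )

    beta0 = _tune_intercept(config, mafs, gene_index, betas, pairs, rng)

    n_total = config.n_cases + config.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    batch = max(2000, n_total)
    drawn = 0
    while len(case_rows) < config.n_cases or len(control_rows) < config.n_controls:
        G = _draw_genotypes(config, mafs, gene_index, batch, rng)
        eta = beta0 + _linear_predictor(G.astype(float), betas, pairs)
        y = rng.random(batch) < expit(eta)
        for i in range(batch):
            if y[i]:
                if len(case_rows) < config.n_cases:
                    case_rows.append(G[i])
            elif len(control_rows) < config.n_controls:
                control_rows.append(G[i])
        drawn += batch
        if drawn > 500 * n_total:
            raise ConfigError("case/control quotas unreachable; check effects")

    geno = np.vstack(case_rows + control_rows).astype(np.int8)
    pheno = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )
    # deterministic shuffle so cases and controls interleave
    perm = rng.permutation(n_total)
    geno, pheno = geno[perm], pheno[perm]

    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    samples = pd.DataFrame(
        {"sample_id": [f"S{i + 1:05d}" for i in range(n_total)], "phenotype": pheno}
    )
    data = GenotypeDataset(geno, samples, snps.drop(columns=["gene_id"]))

    risk_ids = sorted(config.risk_pathways)
    null_ids = [pid for pid in pathways if pid not in config.risk_pathways]
    truth = TruthRecord(
        risk_pathway_ids=risk_ids,
        null_pathway_ids=null_ids,
        planted_pairs=planted,
        snp_betas=pd.DataFrame({"snp_id": snps["snp_id"], "beta": betas}),
        beta0=beta0,
    )
    return data, truth


# -------------------------------------------------------------------- PPI


def generate_ppi(
    config: SimulationConfig, genes: pd.DataFrame, truth: TruthRecord
) -> pd.DataFrame:
    """Undirected simple PPI edge list.

    Every planted epistatic gene pair is guaranteed an edge (so end-to-end
    recovery is well-posed); background edges are Bernoulli over the
    remaining gene pairs.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PPI])
    gene_ids = genes["gene_id"].tolist()
    edges: set[tuple[str, str]] = set()
    for rec in truth.planted_pairs:
        a, b = sorted((rec["gene_a"], rec["gene_b"]))
        if a == b:
            raise ConfigError(f"planted PPI self-pair for gene {a}")
        edges.add((a, b))
    n = len(gene_ids)
    if config.ppi_background_prob > 0:
        draw = rng.random((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if draw[i, j] < config.ppi_background_prob:
                    edges.add((gene_ids[i], gene_ids[j]))
    return pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])


# --------------------------------------------------------------------- GO


def generate_go(
    config: SimulationConfig, genes: pd.DataFrame, n_terms: int = 60
) -> tuple[pd.DataFrame, nx.DiGraph, dict]:
    """Rooted ontology DAG (>=6 levels) plus gene->term annotations.

    Returns ``(annotations, ontology, planted)`` where ``planted`` names one
    term at depth >= 4 whose annotated genes form a deliberately enriched
    set — downstream enrichment should rank it first for that gene set.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GO])
    onto = nx.DiGraph()
    root = "GO:0000001"
    onto.add_node(root, name="biological_process", namespace="biological_process")

    def tid(k: int) -> str:
        return f"GO:{k + 2:07d}"

    # guaranteed depth: a chain of 7 below the root (depths 2..8)
    chain = [root]
    for d in range(7):
        t = tid(d)
        onto.add_node(t, name=f"chain_depth_{d + 2}", namespace="biological_process")
        onto.add_edge(t, chain[-1])
        chain.append(t)
    # remaining terms attach to 1-2 random existing parents
    for k in range(7, n_terms - 1):
        t = tid(k)
        existing = sorted(onto.nodes)
        n_par = int(rng.integers(1, 3))
        parents = rng.choice(len(existing), size=min(n_par, len(existing)), replace=False)
        onto.add_node(t, name=f"term_{k}", namespace="biological_process")
        for pi in parents:
            parent = existing[pi]
            if parent != t:
                onto.add_edge(t, parent)
    onto.graph["roots"] = {"biological_process": root}

    # depths (1 + shortest path to root) to pick a planted term at depth >= 4
    lengths = nx.shortest_path_length(onto, target=root)
    depth = {t: int(l) + 1 for t, l in lengths.items()}
    deep_terms = sorted(t for t, d in depth.items() if d >= 4)
    planted_term = deep_terms[int(rng.integers(len(deep_terms)))]

    gene_ids = genes["gene_id"].tolist()
    terms = sorted(onto.nodes)
    rows = []
    for g in gene_ids:
        k = int(rng.integers(1, 4))
        for t_i in rng.choice(len(terms), size=k, replace=False):
            rows.append({"gene_id": g, "term_id": terms[t_i]})
    # planted enrichment: a dedicated slice of genes annotated to one deep term
    n_planted = min(15, len(gene_ids))
    planted_genes = [gene_ids[i] for i in range(n_planted)]
    for g in planted_genes:
        rows.append({"gene_id": g, "term_id": planted_term})
    annot = pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
    planted = {"term_id": planted_term, "genes": planted_genes, "depth": depth[planted_term]}
    return annot, onto, planted


# ------------------------------------------------------------- one-shot run


@dataclass
class SimulationBundle:
    """Everything one simulate() call produces, ready to write or analyse."""

    config: SimulationConfig
    genes: pd.DataFrame
    pathways: dict[str, list[str]]
    data: GenotypeDataset
    truth: TruthRecord
    ppi: pd.DataFrame
    annotations: pd.DataFrame
    ontology: nx.DiGraph
    planted_go: dict


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Run every generation stage with streams derived from ``config.seed``."""
    genes = generate_gene_annotation(config)
    pathways = generate_pathways(config, genes)
    data, truth = generate_genotypes(config, genes, pathways)
    ppi = generate_ppi(config, genes, truth)
    annot, onto, planted_go = generate_go(config, genes)
    return SimulationBundle(config, genes, pathways, data, truth, ppi, annot, onto, planted_go)


def write_simulation(bundle: SimulationBundle, out_dir) -> None:
    """Write every synthetic input in its exchange format under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_gene_bed(bundle.genes, out / "genes.bed")
    io.write_gmt(bundle.pathways, out / "pathways.gmt")
    io.write_dosage_tsv(bundle.data, out / "dosage.tsv", out / "snps.tsv")
    io.write_plink_text(bundle.data, out / "genotypes")
    io.write_edge_tsv(bundle.ppi, out / "ppi.tsv")
    io.write_annotations(bundle.annotations, out / "go_annotations.tsv")
    io.write_obo(bundle.ontology, out / "go.obo")
    io.write_json(bundle.truth.to_json(), out / "truth.json")
    io.write_json(bundle.planted_go, out / "planted_go.json")
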