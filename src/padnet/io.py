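"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: gene coordinates are BED (0-based half-open); SNP positions are
1-based (PLINK .map convention); dosage tables are samples x SNPs TSV with
``NA`` for missing; pathways are GMT; the ontology is OBO 1.2.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .dataset import MISSING, GenotypeDataset

# ----------------------------------------------------------------- dosage TSV


def write_dosage_tsv(data: GenotypeDataset, geno_path, snp_path) -> None:
    """Write a dosage matrix TSV plus a SNP metadata side table."""
    g = data.genotypes.astype(object)
    g[data.genotypes == MISSING] = "NA"
    df = pd.DataFrame(g, columns=data.snps["snp_id"])
    df.insert(0, "phenotype", data.samples["phenotype"].to_numpy())
    df.insert(0, "sample_id", data.samples["sample_id"].to_numpy())
    df.to_csv(geno_path, sep="\t", index=False)
    data.snps.to_csv(snp_path, sep="\t", index=False)


def read_dosage_tsv(geno_path, snp_path) -> GenotypeDataset:
    df = pd.read_csv(geno_path, sep="\t", dtype={"sample_id": str})
    snps = pd.read_csv(snp_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    samples = df[["sample_id", "phenotype"]].copy()
    geno = df.drop(columns=["sample_id", "phenotype"])
    mat = geno.to_numpy(dtype=object)
    out = np.full(mat.shape, MISSING, dtype=np.int8)
    mask = ~pd.isna(geno).to_numpy()
    out[mask] = geno.to_numpy(dtype=float)[mask].astype(np.int8)
    if list(geno.columns) != list(snps["snp_id"]):
        raise ValueError("SNP metadata table does not match dosage columns")
    return GenotypeDataset(out, samples, snps)


# ----------------------------------------------------------------- PLINK text


def write_plink_text(data: GenotypeDataset, prefix) -> None:
    """Write PLINK .ped/.map text files (positions 1-based in .map)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in data.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    minor = data.snps["minor_allele"].to_numpy()
    major = data.snps["major_allele"].to_numpy()
    # dosage -> allele pair strings per SNP
    g = data.genotypes
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, srow in enumerate(data.samples.itertuples(index=False)):
            pheno = 2 if srow.phenotype == 1 else 1  # PLINK: 2=case, 1=control
            fields = [str(srow.sample_id), str(srow.sample_id), "0", "0", "0", str(pheno)]
            gi = g[i]
            for j in range(data.n_snps):
                d = gi[j]
                if d == MISSING:
                    fields.append("0 0")
                elif d == 0:
                    fields.append(f"{major[j]} {major[j]}")
                elif d == 1:
                    fields.append(f"{major[j]} {minor[j]}")
                else:
                    fields.append(f"{minor[j]} {minor[j]}")
            fh.write("\t".join(fields) + "\n")


def read_plink_text(prefix) -> GenotypeDataset:
    """Read PLINK .ped/.map; the minor allele per SNP is taken as the rarer
    allele in the file (ties broken alphabetically)."""
    prefix = Path(prefix)
    snps = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    ).drop(columns=["cm"])
    rows = []
    sample_ids, phenos = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample_ids.append(parts[1])
            phenos.append(1 if parts[5] == "2" else 0)
            rows.append([tuple(p.split()) for p in parts[6:]])
    n, p = len(rows), len(snps)
    alleles_a = np.array([[r[j][0] for j in range(p)] for r in rows])
    alleles_b = np.array([[r[j][1] for j in range(p)] for r in rows])
    geno = np.full((n, p), MISSING, dtype=np.int8)
    minor_list, major_list = [], []
    for j in range(p):
        col = np.concatenate([alleles_a[:, j], alleles_b[:, j]])
        obs = col[col != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) == 1:
            major, minor = uniq[0], uniq[0]
        else:
            order = np.lexsort((uniq, counts))  # rarer first, ties alphabetical
            minor, major = uniq[order[0]], uniq[order[-1]]
        minor_list.append(minor)
        major_list.append(major)
        miss = (alleles_a[:, j] == "0") | (alleles_b[:, j] == "0")
        dose = (alleles_a[:, j] == minor).astype(np.int8) + (
            alleles_b[:, j] == minor
        ).astype(np.int8)
        if minor == major:  # monomorphic: dosage 0
            dose = np.zeros(n, dtype=np.int8)
        dose[miss] = MISSING
        geno[:, j] = dose
    snps["minor_allele"] = minor_list
    snps["major_allele"] = major_list
    samples = pd.DataFrame({"sample_id": sample_ids, "phenotype": phenos})
    snps = snps[["snp_id", "chrom", "pos", "minor_allele", "major_allele"]]
    return GenotypeDataset(geno, samples, snps)


# ------------------------------------------------------------------ BED / GMT


def write_gene_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )


def write_gmt(pathways: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for pid in pathways:
            genes = "\t".join(pathways[pid])
            fh.write(f"{pid}\t{description}\t{genes}\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = parts[2:]
    return out


# ------------------------------------------------------------------- edge TSV


def write_edge_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_ppi_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("PPI table needs two gene columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    return df


# ------------------------------------------------------------ GO annotations


def write_annotations(annot: pd.DataFrame, path) -> None:
    annot[["gene_id", "term_id"]].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_obo(onto: nx.DiGraph, path) -> None:
    """Write a minimal OBO 1.2 file (id, name, namespace, is_a edges)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(onto.nodes):
            attrs = onto.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {attrs.get('name', term)}\n")
            fh.write(f"namespace: {attrs.get('namespace', 'biological_process')}\n")
            for _, parent in sorted(onto.out_edges(term)):
                fh.write(f"is_a: {parent}\n")


def read_obo(path) -> nx.DiGraph:
    """Read an OBO ontology into a child->parent DiGraph (is_a edges only)."""
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, attrs in multi.nodes(data=True):
        g.add_node(node, **attrs)
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(u, v)
    return g


# ------------------------------------------------------------------- JSON etc


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
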