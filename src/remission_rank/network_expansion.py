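"""Candidate-SNP enrichment through the protein-interaction network.

The k lowest-p scan SNPs seed a gene set (intergenic SNPs contribute
both flanking genes); the set is expanded with first-degree interaction
partners; every panel SNP annotated to any such gene becomes a
candidate, tagged with its provenance (seed vs network-expanded).
Candidates are then filtered to p <= p_max and greedily LD-pruned
(r^2 > r2_max removes the higher-p member, lowest-p SNPs claim their
neighbourhoods first).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, SnpAnnotation

log = logging.getLogger(__name__)


def build_seed_gene_set(gwas_result: pd.DataFrame, annotation: SnpAnnotation,
                        k: int = 200) -> tuple:
    """Select the k smallest-p SNPs and collect their genes.

    Ties on p break by snp_id for determinism.  If fewer than k SNPs
    carry a valid p-value, all of them are returned with a warning.
    Returns (seed snp_id list, seed gene set).
    """
    valid = gwas_result.dropna(subset=["p_wald"])
    if valid.empty:
        raise ValueError("no SNP with a valid p-value")
    ordered = valid.assign(_id=valid.index).sort_values(["p_wald", "_id"])
    if k > len(ordered):
        log.warning("requested %d seeds but only %d SNPs have p-values",
                    k, len(ordered))
    seeds = ordered.index[:k].tolist()
    genes = set()
    for snp in seeds:
        genes.update(annotation.genes_of(snp))
    return seeds, genes


def ppi_expand_snps(seed_genes, network: nx.Graph,
                    annotation: SnpAnnotation,
                    gwas_result: pd.DataFrame,
                    seed_snps=()) -> pd.DataFrame:
    """All panel SNPs on seed genes or their first-degree partners.

    Seed genes absent from the network keep their own SNPs (logged).
    Returns the pre-filter candidate table: p_value, provenance
    ('seed' for the seed SNPs themselves, 'network-expanded'
    otherwise) and source genes.
    """
    seed_genes = set(seed_genes)
    seed_snps = set(seed_snps)
    absent = seed_genes - set(network.nodes)
    for g in sorted(absent):
        log.info("seed gene %s absent from interaction network; "
                 "its own SNPs are retained", g)
    expanded_genes = set(seed_genes)
    for g in seed_genes & set(network.nodes):
        expanded_genes.update(network.neighbors(g))

    rows = []
    for snp, genes in annotation.snps_in_genes(expanded_genes).items():
        if snp not in gwas_result.index:
            continue
        rows.append({
            "snp_id": snp,
            "p_value": gwas_result.loc[snp, "p_wald"],
            "provenance": "seed" if snp in seed_snps else "network-expanded",
            "source_genes": "|".join(sorted(set(genes) & expanded_genes)),
        })
    return pd.DataFrame(rows,
                        columns=["snp_id", "p_value", "provenance",
                                 "source_genes"]).set_index("snp_id")


def ld_prune_and_pfilter(candidates: pd.DataFrame,
                         genotypes: GenotypeMatrix,
                         r2_max: float = 0.8,
                         p_max: float = 0.2) -> pd.DataFrame:
    """p filter then greedy LD prune of the candidate table.

    SNPs with p > p_max drop first.  The survivors are visited in
    ascending-p order (ties by snp_id); each visited SNP is kept and
    every not-yet-kept SNP whose squared dosage correlation with it
    exceeds ``r2_max`` is removed.  r^2 uses pairwise-complete samples
    (composite LD on unphased dosages).
    """
    cand = candidates.dropna(subset=["p_value"])
    cand = cand[cand["p_value"] <= p_max]
    if cand.empty:
        return cand
    order = cand.assign(_id=cand.index).sort_values(["p_value", "_id"]).index
    cols = {s: genotypes.column(s) for s in order}
    kept, removed = [], set()
    for snp in order:
        if snp in removed:
            continue
        kept.append(snp)
        g1 = cols[snp]
        for other in order:
            if other == snp or other in removed or other in kept:
                continue
            g2 = cols[other]
            ok = ~np.isnan(g1) & ~np.isnan(g2)
            if ok.sum() < 3:
                continue
            a, b = g1[ok], g2[ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > r2_max:
                removed.add(other)
    return cand.loc[kept]


def build_candidate_set(gwas_result: pd.DataFrame,
                        annotation: SnpAnnotation,
                        network: nx.Graph,
                        genotypes: GenotypeMatrix,
                        k: int = 200, r2_max: float = 0.8,
                        p_max: float = 0.2) -> pd.DataFrame:
    """Seed selection, network expansion, p filter and LD prune in one call."""
    seeds, seed_genes = build_seed_gene_set(gwas_result, annotation, k=k)
    expanded = ppi_expand_snps(seed_genes, network, annotation, gwas_result,
                               seed_snps=seeds)
    return ld_prune_and_pfilter(expanded, genotypes,
                                r2_max=r2_max, p_max=p_max)
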