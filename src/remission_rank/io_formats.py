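"""Readers and writers for every on-disk format the pipeline touches.

All tables are plain tab-separated text with headers.  Genotypes come
either as a sample x SNP dosage table (header = SNP ids, values
0/1/2/NA) or as a VCF; in the VCF case dosages count minor alleles after
per-SNP minor-allele determination from observed frequency.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import StudyConfig
from .datatypes import (CohortTable, GenotypeMatrix, ParseError,
                        SnpAnnotation, make_ppi_network)

NA_TOKENS = ("NA", "", "nan", ".")


# ---------------------------------------------------------------- genotypes

def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = gm.to_frame()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")
    meta = {s: list(gm.allele_labels[s]) for s in gm.allele_labels}
    Path(str(path) + ".alleles.json").write_text(json.dumps(meta))


def read_genotype_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(NA_TOKENS),
                     keep_default_na=False)
    arr = df.to_numpy(dtype=float)
    bad = arr[~np.isnan(arr)]
    if not np.isin(bad, (0.0, 1.0, 2.0)).all():
        offending = sorted(set(bad[~np.isin(bad, (0.0, 1.0, 2.0))]))[:3]
        raise ParseError(f"{path}: dosage values {offending} not in {{0,1,2,NA}}")
    alleles = {}
    side = Path(str(path) + ".alleles.json")
    if side.exists():
        alleles = {k: tuple(v) for k, v in json.loads(side.read_text()).items()}
    return GenotypeMatrix(sample_ids=df.index.astype(str).tolist(),
                          snp_ids=[str(c) for c in df.columns],
                          dosage=arr, allele_labels=alleles)


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read a VCF into minor-allele dosages.

    ALT-allele counts are flipped per SNP when ALT is the major allele,
    so a heterozygote is always dosage 1 regardless of which allele is
    minor.  Ties at frequency 0.5 keep the lexicographically smaller
    allele symbol as minor.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, cols, alleles = [], [], {}
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(f"{path}: multi-allelic record at {var.POS}")
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        gts = np.array([g[0] + g[1] if g[0] >= 0 and g[1] >= 0 else np.nan
                        for g in var.genotypes], dtype=float)
        obs = gts[~np.isnan(gts)]
        alt_freq = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
        ref, alt = var.REF, var.ALT[0]
        if alt_freq > 0.5 or (alt_freq == 0.5 and not alt < ref):
            gts = 2.0 - gts  # REF is minor
            minor, major = ref, alt
        else:
            minor, major = alt, ref
        snp_ids.append(sid)
        cols.append(gts)
        alleles[sid] = (minor, major)
    if not snp_ids:
        raise ParseError(f"{path}: no records")
    return GenotypeMatrix(sample_ids=samples, snp_ids=snp_ids,
                          dosage=np.column_stack(cols), allele_labels=alleles)


# ---------------------------------------------------------------- phenotypes

def write_cohort(cohort: CohortTable, path) -> None:
    df = cohort.data.copy()
    df.index.name = "sample_id"
    # first header line declares covariate kinds so the round trip is typed
    kinds = ["label" if c == "remission"
             else cohort.covariate_kind(c) for c in df.columns]
    with open(path, "w") as fh:
        fh.write("#types\t" + "\t".join(kinds) + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA")


def read_cohort(path) -> CohortTable:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#types\t"):
            raise ParseError(f"{path}:1: expected '#types' declaration line")
        kinds = first.split("\t")[1:]
        df = pd.read_csv(fh, sep="\t", index_col=0,
                         na_values=list(NA_TOKENS), keep_default_na=False)
    if len(kinds) != df.shape[1]:
        raise ParseError(f"{path}: {len(kinds)} declared types for "
                         f"{df.shape[1]} columns")
    df.index = df.index.astype(str)
    dich = tuple(c for c, k in zip(df.columns, kinds) if k == "dichotomous")
    cont = tuple(c for c, k in zip(df.columns, kinds) if k == "continuous")
    return CohortTable(df, dichotomous=dich, continuous=cont)


# ---------------------------------------------------------------- annotation

def write_annotation(ann: SnpAnnotation, path) -> None:
    t = ann.table.copy()
    t.index.name = "snp_id"
    t.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path) -> SnpAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=list(NA_TOKENS), keep_default_na=False)
    df.index = df.index.astype(str)
    return SnpAnnotation(df)


# ---------------------------------------------------------------- network

def write_ppi(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_ppi(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_a", "gene_b"]:
        raise ParseError(f"{path}: expected header 'gene_a\\tgene_b'")
    return make_ppi_network(df.itertuples(index=False, name=None))


# ---------------------------------------------------------------- bundle

def read_study_inputs(genotype_path, phenotype_path, annotation_path,
                      ppi_path, dialect: str = "table"):
    """Load the four input objects; ``dialect`` selects the genotype format."""
    if dialect == "table":
        gm = read_genotype_table(genotype_path)
    elif dialect == "vcf":
        gm = read_genotype_vcf(genotype_path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    cohort = read_cohort(phenotype_path)
    ann = read_annotation(annotation_path)
    ppi = read_ppi(ppi_path)
    if set(cohort.sample_ids) != set(gm.sample_ids):
        raise ParseError("phenotype and genotype sample sets differ")
    return gm, cohort, ann, ppi


def write_study_inputs(gm, cohort, ann, ppi, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"genotypes": out / "genotypes.tsv",
             "phenotypes": out / "phenotypes.tsv",
             "annotation": out / "annotation.tsv",
             "ppi": out / "ppi.tsv"}
    write_genotypes(gm, paths["genotypes"])
    write_cohort(cohort, paths["phenotypes"])
    write_annotation(ann, paths["annotation"])
    write_ppi(ppi, paths["ppi"])
    return {k: str(v) for k, v in paths.items()}


def write_outputs(results: dict, out_dir, config: StudyConfig) -> dict:
    """Write result DataFrames as TSVs plus a run manifest.

    Column order is preserved as given, so identical runs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"rng_seed": config.rng_seed, "config": config.to_dict(),
                "tables": {}}
    for name, df in results.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", na_rep="NA", index=bool(df.index.name))
        manifest["tables"][name] = str(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
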