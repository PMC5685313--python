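"""In-memory containers shared by every pipeline stage.

Genotypes are minor-allele dosages held in a pandas DataFrame with a
float dtype so that missing calls can be NaN — 0 is a valid dosage and is
never used as a missing sentinel.  The clinical table distinguishes
dichotomous from continuous covariates explicitly because downstream
statistics (chi-square vs Kruskal-Wallis), the Gower coefficient and the
network encoding all branch on that distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MISSING = np.nan

#: Table-1 covariate set produced by the synthetic generator.
DICHOTOMOUS_COVARIATES = (
    "male_sex", "alcohol_use", "tobacco_use",
    "biguanides", "insulin_medication", "sulfonylureas",
    "insulin_sensitising_agents",
)
CONTINUOUS_COVARIATES = (
    "age", "weight", "bmi", "systolic_bp", "diastolic_bp",
    "pulse_pressure", "serum_glucose", "serum_insulin", "hba1c",
)


class ParseError(ValueError):
    """Raised when an input file violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()].tolist()[:3]
        raise ParseError(f"duplicated {what}: {dup}")


@dataclass
class GenotypeMatrix:
    """samples x SNPs minor-allele dosage matrix.

    ``dosage`` is an (n_samples, n_snps) float array with entries in
    {0, 1, 2, NaN}.  ``allele_labels`` maps snp_id -> (minor, major).
    """

    sample_ids: list
    snp_ids: list
    dosage: np.ndarray
    allele_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.snp_ids, "snp id")
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ParseError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} snps")
        vals = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0, 2.0))]))[:3]
            raise ParseError(f"dosage values outside {{0,1,2,missing}}: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        # cached: the matrix is treated as immutable once constructed
        if getattr(self, "_frame", None) is None:
            self._frame = pd.DataFrame(
                self.dosage, index=pd.Index(self.sample_ids, name="sample_id"),
                columns=self.snp_ids)
        return self._frame

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_ids.index(snp_id)]

    def subset(self, sample_ids=None, snp_ids=None) -> "GenotypeMatrix":
        rows = (np.arange(self.n_samples) if sample_ids is None
                else np.array([self.sample_ids.index(s) for s in sample_ids]))
        cols = (np.arange(self.n_snps) if snp_ids is None
                else np.array([self.snp_ids.index(s) for s in snp_ids]))
        keep_snps = [self.snp_ids[j] for j in cols]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            snp_ids=keep_snps,
            dosage=self.dosage[np.ix_(rows, cols)],
            allele_labels={s: self.allele_labels[s] for s in keep_snps
                           if s in self.allele_labels},
        )

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.sample_ids == other.sample_ids
                and self.snp_ids == other.snp_ids
                and np.array_equal(self.dosage, other.dosage, equal_nan=True)
                and self.allele_labels == other.allele_labels)


@dataclass
class CohortTable:
    """Per-patient clinical covariates plus the binary remission label.

    ``data`` is indexed by sample_id and holds one column per covariate
    plus ``remission`` (1 = remitter, 0 = nonremitter, never missing).
    """

    data: pd.DataFrame
    dichotomous: tuple = ()
    continuous: tuple = ()

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample id")
        if "remission" not in self.data.columns:
            raise ParseError("cohort table lacks a 'remission' column")
        y = self.data["remission"]
        if y.isna().any():
            missing = self.data.index[y.isna()].tolist()[:3]
            raise ParseError(f"remission label missing for samples {missing}")
        if not set(y.unique()) <= {0, 1}:
            raise ParseError("remission labels must be 0/1")
        self.dichotomous = tuple(self.dichotomous)
        self.continuous = tuple(self.continuous)
        declared = set(self.dichotomous) | set(self.continuous)
        undeclared = set(self.data.columns) - declared - {"remission"}
        if undeclared:
            raise ParseError(
                f"covariates without a declared type: {sorted(undeclared)}")
        for c in self.dichotomous:
            vals = set(self.data[c].dropna().unique())
            if not vals <= {0, 1, 0.0, 1.0}:
                raise ParseError(f"dichotomous covariate {c!r} has values {vals}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def remission(self) -> pd.Series:
        return self.data["remission"].astype(int)

    @property
    def covariates(self) -> list:
        return [c for c in self.data.columns if c != "remission"]

    def covariate_kind(self, name: str) -> str:
        if name in self.dichotomous:
            return "dichotomous"
        if name in self.continuous:
            return "continuous"
        raise KeyError(name)

    def subset(self, sample_ids) -> "CohortTable":
        return CohortTable(self.data.loc[list(sample_ids)].copy(),
                           self.dichotomous, self.continuous)

    def __eq__(self, other) -> bool:
        return (isinstance(other, CohortTable)
                and self.dichotomous == other.dichotomous
                and self.continuous == other.continuous
                and self.data.equals(other.data))


@dataclass
class SnpAnnotation:
    """SNP -> genomic position and gene symbol(s).

    Intergenic SNPs carry both flanking genes as ``"A|B"``; ``genes_of``
    splits that into the individual symbols.
    """

    table: pd.DataFrame  # index snp_id; columns chromosome, position, build, genes

    REQUIRED = ("chromosome", "position", "build", "genes")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "snp id")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ParseError(f"annotation lacks column {col!r}")

    @property
    def snp_ids(self) -> list:
        return self.table.index.tolist()

    def genes_of(self, snp_id: str) -> list:
        raw = self.table.loc[snp_id, "genes"]
        if pd.isna(raw) or raw == "":
            return []
        return [g for g in str(raw).split("|") if g]

    def snps_in_genes(self, genes) -> dict:
        """Map snp_id -> its gene symbols, for SNPs touching any given gene."""
        genes = set(genes)
        out = {}
        for snp in self.table.index:
            gs = self.genes_of(snp)
            if genes & set(gs):
                out[snp] = gs
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, SnpAnnotation) and self.table.equals(other.table)


def make_ppi_network(edges) -> nx.Graph:
    """Build an undirected simple gene-interaction graph.

    Self-loops are rejected, duplicate edges collapse silently.
    """
    g = nx.Graph()
    for u, v in edges:
        if u == v:
            raise ParseError(f"self-loop on gene {u!r}")
        g.add_edge(u, v)
    return g
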