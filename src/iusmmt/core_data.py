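"""Domain containers, file I/O and preprocessing for gene-centric
survival mediation analysis.

The unit of analysis is one gene: a block of DNA-methylation M-values for
the CpG sites assigned to the gene (the multivariate exposure), the gene's
expression level (the mediator), a right-censored survival outcome, and a
table of clinical covariates, all aligned on the same samples.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationBlock", "SurvivalOutcome", "CovariateTable", "GeneDataset",
    "beta_to_mvalue", "standardize", "assemble_gene_datasets",
    "read_matrix_tsv", "write_matrix_tsv", "read_clinical",
    "read_gene_annotation", "cpg_positions_from_ids",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class MethylationBlock:
    """M-values for the K CpG sites of one gene; shape (n samples, K)."""

    gene_id: str
    cpg_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("methylation values must be 2-D (n x K)")
        if self.values.shape[1] != len(self.cpg_ids):
            raise ValueError("column count does not match cpg_ids")
        if self.values.shape[1] < 1:
            raise ValueError("a methylation block needs at least one CpG")
        if np.isnan(self.values).any():
            raise ValueError("methylation block contains missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class SurvivalOutcome:
    """Right-censored survival outcome: positive times, 0/1 event status."""

    time: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.time.shape != self.status.shape:
            raise ValueError("time and status must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 (censored) or 1 (event)")

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


@dataclass
class CovariateTable:
    """n x L covariate matrix with column names (no intercept column)."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(self.values.shape[0]
                                              if self.values.ndim == 2 else 0,
                                              0)
        if not self.names:
            self.names = [f"x{j + 1}" for j in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names do not match covariate columns")

    @property
    def L(self) -> int:
        return self.values.shape[1]

    def with_intercept(self) -> np.ndarray:
        n = self.values.shape[0]
        return np.column_stack([np.ones(n), self.values])

    @classmethod
    def empty(cls, n: int) -> "CovariateTable":
        return cls(values=np.empty((n, 0)), names=[])


@dataclass
class GeneDataset:
    """All data for one gene's mediation analysis, sample-aligned."""

    methylation: MethylationBlock
    expression: np.ndarray
    outcome: SurvivalOutcome
    covariates: CovariateTable

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float).ravel()
        n = self.methylation.n
        if not (len(self.expression) == len(self.outcome.time)
                == self.covariates.values.shape[0] == n):
            raise ValueError("all components must share the sample count")

    @property
    def n(self) -> int:
        return self.methylation.n

    @property
    def gene_id(self) -> str:
        return self.methylation.gene_id


# ---------------------------------------------------------------------------
# elementary transforms

def beta_to_mvalue(beta):
    """M-value transform ``log2(beta / (1 - beta))`` of a methylation
    beta value; strictly increasing on (0, 1)."""
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0) or np.any(b >= 1):
        raise ValueError("beta values must lie strictly in (0, 1)")
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def standardize(values, names=None):
    """Center to mean 0 and scale to variance 1 (population ddof=0),
    column-wise for matrices.

    Raises on constant columns, naming the offender when `names` given.
    """
    x = np.asarray(values, dtype=float)
    vec = x.ndim == 1
    x = np.atleast_2d(x.T).T if vec else x
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    bad = np.where(sd == 0)[0]
    if bad.size:
        labels = ([names[j] for j in bad] if names is not None
                  else [f"column {j}" for j in bad])
        raise ValueError(f"cannot standardize constant column(s): "
                         f"{', '.join(map(str, labels))}")
    out = (x - mu) / sd
    return out.ravel() if vec else out


# ---------------------------------------------------------------------------
# file readers / writers (plain TSV / BED)

def read_matrix_tsv(path) -> pd.DataFrame:
    """Feature x sample matrix: first column feature id, header sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    # shortest round-trip reprs + round_trip parsing => bit-exact I/O
    df.to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    """Clinical table with required columns sample, time, status; any other
    columns are covariates.  Missing covariate values are mean-imputed."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample", "time", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must contain columns {required}")
    df = df.set_index("sample")
    covar_cols = [c for c in df.columns if c not in ("time", "status")]
    for c in covar_cols:
        if df[c].isna().any():
            df[c] = df[c].fillna(df[c].mean())
    return df


BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation in BED format (0-based half-open): chrom, start,
    end, gene_id, score, strand."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("annotation BED needs >= 4 columns")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df


_CPG_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)(:.*)?$")


def cpg_positions_from_ids(cpg_ids) -> pd.DataFrame:
    """Parse CpG coordinates from ids of the form ``chrom:pos`` or
    ``chrom:pos:name``; rows that do not parse are dropped with a log
    entry."""
    rows, dropped = [], 0
    for cid in cpg_ids:
        m = _CPG_ID_RE.match(str(cid))
        if m is None:
            dropped += 1
            continue
        rows.append((cid, m.group("chrom"), int(m.group("pos"))))
    if dropped:
        logger.warning("dropped %d CpG ids without parseable coordinates",
                       dropped)
    return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos"])


# ---------------------------------------------------------------------------
# gene-centric assembly

def _gene_window(row, promoter_bp: int) -> tuple[int, int]:
    """Gene body extended by `promoter_bp` upstream of the TSS,
    strand-aware (upstream = 5' of the TSS on the annotated strand)."""
    if str(row.strand) == "-":
        return int(row.start), int(row.end) + promoter_bp
    return int(row.start) - promoter_bp, int(row.end)


def assemble_gene_datasets(methyl_matrix: pd.DataFrame,
                           annotation: pd.DataFrame,
                           expr_matrix: pd.DataFrame,
                           clinical: pd.DataFrame,
                           promoter_bp: int = 500,
                           cpg_positions: pd.DataFrame | None = None,
                           ) -> list[GeneDataset]:
    """Build one :class:`GeneDataset` per annotated gene.

    A CpG belongs to a gene when its position falls inside the gene body
    extended ``promoter_bp`` upstream of the TSS (BED 0-based half-open
    intervals).  Samples are restricted to the intersection of the three
    tables; methylation and expression are standardized; genes with no
    mapped CpG or no expression row are skipped with a log entry.
    """
    if cpg_positions is None:
        cpg_positions = cpg_positions_from_ids(methyl_matrix.index)

    samples = sorted(set(methyl_matrix.columns)
                     & set(expr_matrix.columns) & set(clinical.index))
    if not samples:
        raise ValueError("no samples shared across methylation, expression "
                         "and clinical tables")

    methyl = methyl_matrix[samples]
    expr = expr_matrix[samples]
    clin = clinical.loc[samples]

    # drop features with missingness rather than imputing
    methyl = methyl.dropna(axis=0)
    expr = expr.dropna(axis=0)

    outcome = SurvivalOutcome(time=clin["time"].to_numpy(),
                              status=clin["status"].to_numpy())
    covar_cols = [c for c in clin.columns if c not in ("time", "status")]
    covariates = CovariateTable(values=clin[covar_cols].to_numpy(dtype=float)
                                if covar_cols else np.empty((len(samples), 0)),
                                names=list(covar_cols))

    pos = cpg_positions.set_index("cpg_id")
    datasets: list[GeneDataset] = []
    for row in annotation.sort_values("gene_id").itertuples():
        gene = str(row.gene_id)
        if gene not in expr.index:
            logger.info("gene %s skipped: no expression row", gene)
            continue
        lo, hi = _gene_window(row, promoter_bp)
        on_chrom = pos[pos["chrom"] == row.chrom]
        hit = on_chrom[(on_chrom["pos"] >= lo) & (on_chrom["pos"] < hi)]
        cpg_ids = [c for c in hit.index if c in methyl.index]
        if not cpg_ids:
            logger.info("gene %s skipped: 0 mapped CpGs", gene)
            continue
        block_values = standardize(methyl.loc[cpg_ids].to_numpy().T,
                                   names=cpg_ids)
        g = standardize(expr.loc[gene].to_numpy(dtype=float))
        datasets.append(GeneDataset(
            methylation=MethylationBlock(gene_id=gene, cpg_ids=cpg_ids,
                                         values=block_values),
            expression=g, outcome=outcome, covariates=covariates))
    return datasets
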