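"""Synthetic-data generator for the simulation study.

Each simulated "gene" is an independent dataset: an AR(1)-correlated
block of standardized methylation M-values (K ~ uniform on {10..30}),
a mediator generated from the linear mixed model
``G = M a + 0.5 x1 + 0.5 x2 + eps`` with ``a_k ~ N(0, tau2)``, and a
Weibull inverse-probability survival time driven by
``eta = M gamma_DE + G beta + 0.5 x1 + 0.5 x2`` with
``gamma_DE_k ~ N(0, tau3)``, shape lambda = 1 and scale rho = 0.01,
then 50% random censoring.  Per-gene component labels (00/01/10/11)
record which of (tau2, beta) were switched on, so mixture-proportion and
power estimates can be checked against the ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .core_data import (CovariateTable, GeneDataset, MethylationBlock,
                        SurvivalOutcome, standardize)
from .mixture_null import NullProportions

__all__ = ["ScenarioConfig", "SimulatedStudy", "SCENARIO_PROPORTIONS",
           "scenario_config", "simulate_methylation_block",
           "simulate_expression", "simulate_survival", "apply_censoring",
           "simulate_study", "write_study", "read_study"]

#: true component proportions (k00, k01, k10, k11) of the named scenarios
SCENARIO_PROPORTIONS = {
    "complete_null": (1.00, 0.00, 0.00, 0.00),
    "dense_null": (0.10, 0.85, 0.05, 0.00),
    "sparse_null": (0.99, 0.01, 0.00, 0.00),
    "dense_alternative": (0.10, 0.75, 0.05, 0.10),
    "sparse_alternative": (0.90, 0.00, 0.00, 0.10),
}

#: default nonzero effect sizes for active components in named scenarios,
#: representative of the low-to-mid region of the study's effect grids
#: (tau2 in {0.01..0.10}, beta in {0.15..0.30})
DEFAULT_TAU2 = 0.02
DEFAULT_BETA = 0.15

LABELS = ("00", "01", "10", "11")


@dataclass
class ScenarioConfig:
    name: str
    proportions: NullProportions
    tau2: float = DEFAULT_TAU2
    beta: float = DEFAULT_BETA
    n: int = 400
    S: int = 10_000
    tau3: float = 0.02
    weibull_lambda: float = 1.0
    weibull_rho: float = 0.01
    censor_rate: float = 0.5
    seed: int = 0
    ar_corr: float = 0.5
    k_range: tuple[int, int] = (10, 30)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_PROPORTIONS:
            raise ValueError(f"unknown scenario name: {self.name}")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.weibull_lambda <= 0 or self.weibull_rho <= 0:
            raise ValueError("Weibull parameters must be positive")


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig carrying the named scenario's true
    component proportions."""
    k00, k01, k10, k11 = SCENARIO_PROPORTIONS[name]
    cfg = ScenarioConfig(name=name,
                         proportions=NullProportions(k00, k01, k10, k11))
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimulatedStudy:
    genes: list[GeneDataset]
    truth_labels: list[str]
    config: ScenarioConfig
    raw_expression: list[np.ndarray] = field(default_factory=list,
                                             repr=False)


def simulate_methylation_block(n: int, rng: np.random.Generator,
                               k: int | None = None, ar_corr: float = 0.5,
                               k_range: tuple[int, int] = (10, 30),
                               gene_id: str = "gene") -> MethylationBlock:
    """AR(1)-correlated Gaussian CpG block, columns standardized;
    corr(site i, site j) = ar_corr^|i-j|."""
    if n < 10:
        raise ValueError("need n >= 10 samples")
    if k is None:
        k = int(rng.integers(k_range[0], k_range[1] + 1))
    e = rng.standard_normal((n, k))
    vals = np.empty((n, k))
    vals[:, 0] = e[:, 0]
    scale = np.sqrt(1.0 - ar_corr ** 2)
    for j in range(1, k):
        vals[:, j] = ar_corr * vals[:, j - 1] + scale * e[:, j]
    vals = standardize(vals)
    cpg_ids = [f"{gene_id}_cg{j:03d}" for j in range(k)]
    return MethylationBlock(gene_id=gene_id, cpg_ids=cpg_ids, values=vals)


def simulate_expression(M: np.ndarray, X: np.ndarray, tau2: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Mediator draw ``G = M a + 0.5 x1 + 0.5 x2 + eps`` with
    ``a_k ~ N(0, tau2)`` and standard-normal residuals."""
    if tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    alpha = rng.normal(0.0, np.sqrt(tau2), size=k) if tau2 > 0 \
        else np.zeros(k)
    eps = rng.standard_normal(n)
    return M @ alpha + 0.5 * X[:, 0] + 0.5 * X[:, 1] + eps


def simulate_survival(M: np.ndarray, G: np.ndarray, X: np.ndarray,
                      beta: float, tau3: float, rng: np.random.Generator,
                      weibull_lambda: float = 1.0,
                      weibull_rho: float = 0.01) -> np.ndarray:
    """Uncensored Weibull inverse-probability survival times.

    ``t = (-log u / (lambda exp(eta)))^(1/rho)`` with
    ``eta = M gamma_DE + G beta + 0.5 x1 + 0.5 x2`` and
    ``gamma_DE_k ~ N(0, tau3)``.
    """
    if weibull_lambda <= 0 or weibull_rho <= 0:
        raise ValueError("Weibull parameters must be positive")
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    gamma = rng.normal(0.0, np.sqrt(tau3), size=k) if tau3 > 0 \
        else np.zeros(k)
    eta = M @ gamma + np.asarray(G) * beta + 0.5 * X[:, 0] + 0.5 * X[:, 1]
    u = np.clip(rng.uniform(size=n), 1e-300, 1.0 - 1e-16)
    logt = np.log(-np.log(u) / (weibull_lambda * np.exp(eta))) / weibull_rho
    # the raw Weibull scale overflows double precision for small rho;
    # fall back to the order-preserving power transform t^rho (Cox
    # inference is invariant to monotone relabelings of the time axis)
    if np.max(np.abs(logt)) < 700.0:
        return np.exp(logt)
    return np.exp(weibull_rho * logt)


def apply_censoring(times: np.ndarray, rate: float,
                    rng: np.random.Generator) -> SurvivalOutcome:
    """Censor exactly round(rate * n) uniformly chosen subjects; each
    censored subject's observed time is uniform on (0, t_i)."""
    t = np.asarray(times, dtype=float)
    if not 0.0 <= rate < 1.0:
        raise ValueError("censoring rate must lie in [0, 1)")
    n = t.size
    status = np.ones(n, dtype=int)
    obs = t.copy()
    m = int(round(rate * n))
    if m:
        idx = rng.choice(n, size=m, replace=False)
        status[idx] = 0
        obs[idx] = t[idx] * np.clip(rng.uniform(size=m), 1e-12, None)
    return SurvivalOutcome(time=obs, status=status)


def _simulate_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Age-like continuous x1 and stage-like ordinal x2 (1..5), both
    standardized."""
    x1 = standardize(rng.standard_normal(n))
    x2 = standardize(rng.integers(1, 6, size=n).astype(float))
    return np.column_stack([x1, x2])


def simulate_study(config: ScenarioConfig) -> SimulatedStudy:
    """Generate S independent gene datasets with ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    probs = np.array(config.proportions.as_tuple())
    labels = rng.choice(4, size=config.S, p=probs)
    genes: list[GeneDataset] = []
    truth: list[str] = []
    raw_G: list[np.ndarray] = []
    width = max(4, len(str(config.S)))
    for s in range(config.S):
        label = LABELS[labels[s]]
        gene_id = f"gene{s:0{width}d}"
        tau2 = config.tau2 if label in ("10", "11") else 0.0
        beta = config.beta if label in ("01", "11") else 0.0
        M = simulate_methylation_block(config.n, rng, ar_corr=config.ar_corr,
                                       k_range=config.k_range,
                                       gene_id=gene_id)
        X = _simulate_covariates(config.n, rng)
        G = simulate_expression(M.values, X, tau2, rng)
        t_full = simulate_survival(M.values, G, X, beta, config.tau3, rng,
                                   config.weibull_lambda, config.weibull_rho)
        outcome = apply_censoring(t_full, config.censor_rate, rng)
        gd = GeneDataset(methylation=M, expression=standardize(G),
                         outcome=outcome,
                         covariates=CovariateTable(values=X,
                                                   names=["x1", "x2"]))
        genes.append(gd)
        truth.append(label)
        raw_G.append(G)
    return SimulatedStudy(genes=genes, truth_labels=truth, config=config,
                          raw_expression=raw_G)


# ---------------------------------------------------------------------------
# writers / readers (round-trip with core_data's file formats)

def write_study(study: SimulatedStudy, outdir) -> None:
    """Write a study as the TSV/BED/clinical files the assembly reader
    consumes.  Methylation/expression/annotation are shared tables; each
    gene's survival outcome is an independent draw, so clinical tables
    are emitted per gene under ``clinical/``.  CpG ids encode synthetic
    coordinates (``chr<g>:<pos>:<name>``), one chromosome per gene."""
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "clinical"), exist_ok=True)
    n = study.config.n
    samples = [f"s{i:04d}" for i in range(n)]
    meth_rows, bed_rows, expr_rows = {}, [], {}
    for g, (gd, label) in enumerate(zip(study.genes, study.truth_labels)):
        chrom = f"chr{g + 1}"
        start = 1000
        for j, _ in enumerate(gd.methylation.cpg_ids):
            pos = start + 100 * j
            rid = f"{chrom}:{pos}:cg{j:03d}"
            meth_rows[rid] = gd.methylation.values[:, j]
        bed_rows.append((chrom, start, start + 100 * gd.methylation.k,
                         gd.gene_id, 0, "+"))
        expr_rows[gd.gene_id] = gd.expression
        clin = pd.DataFrame({"sample": samples,
                             "time": gd.outcome.time,
                             "status": gd.outcome.status,
                             "x1": gd.covariates.values[:, 0],
                             "x2": gd.covariates.values[:, 1]})
        clin.to_csv(os.path.join(outdir, "clinical", f"{gd.gene_id}.tsv"),
                    sep="\t", index=False, float_format=None)
    pd.DataFrame(meth_rows, index=samples).T.to_csv(
        os.path.join(outdir, "methylation.tsv"), sep="\t",
        float_format=None)
    pd.DataFrame(expr_rows, index=samples).T.to_csv(
        os.path.join(outdir, "expression.tsv"), sep="\t",
        float_format=None)
    pd.DataFrame(bed_rows).to_csv(os.path.join(outdir, "annotation.bed"),
                                  sep="\t", index=False, header=False)
    meta = {"scenario": study.config.name,
            "proportions": list(study.config.proportions.as_tuple()),
            "tau2": study.config.tau2, "beta": study.config.beta,
            "n": n, "S": study.config.S, "tau3": study.config.tau3,
            "weibull_lambda": study.config.weibull_lambda,
            "weibull_rho": study.config.weibull_rho,
            "censor_rate": study.config.censor_rate,
            "seed": study.config.seed,
            "truth_labels": {gd.gene_id: lab for gd, lab in
                             zip(study.genes, study.truth_labels)}}
    with open(os.path.join(outdir, "scenario.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_study(outdir) -> SimulatedStudy:
    """Reconstruct a written study via the standard readers/assembly."""
    from .core_data import (assemble_gene_datasets, read_clinical,
                            read_gene_annotation, read_matrix_tsv)
    with open(os.path.join(outdir, "scenario.yaml")) as fh:
        meta = yaml.safe_load(fh)
    methyl = read_matrix_tsv(os.path.join(outdir, "methylation.tsv"))
    expr = read_matrix_tsv(os.path.join(outdir, "expression.tsv"))
    annotation = read_gene_annotation(os.path.join(outdir, "annotation.bed"))
    genes, labels = [], []
    for row in annotation.sort_values("gene_id").itertuples():
        clinical = read_clinical(
            os.path.join(outdir, "clinical", f"{row.gene_id}.tsv"))
        ds = assemble_gene_datasets(
            methyl, annotation[annotation["gene_id"] == row.gene_id],
            expr, clinical)
        genes.extend(ds)
        labels.append(meta["truth_labels"][row.gene_id])
    cfg = scenario_config(meta["scenario"], tau2=meta["tau2"],
                          beta=meta["beta"], n=meta["n"], S=meta["S"],
                          tau3=meta["tau3"],
                          weibull_lambda=meta["weibull_lambda"],
                          weibull_rho=meta["weibull_rho"],
                          censor_rate=meta["censor_rate"],
                          seed=meta["seed"])
    return SimulatedStudy(genes=genes, truth_labels=labels, config=cfg)
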