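"""Coupled synthetic single-cell / bulk / survival cohorts with a truth manifest.

The generator plants marker genes, concordant ligand-receptor differential
expression, rank-correlated bulk pairs (Gaussian copula, so the Spearman
target is planted on the rank scale exactly) and prognostic gene effects, and
records every planted signal so downstream stages can be tested by parameter
recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_core import (
    CountMatrix,
    write_annotation,
    write_bulk,
    write_counts,
    write_survival,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_cells: int
    sample_type: str  # tumor | normal


@dataclass
class SimConfig:
    """Parameters for the coupled cohort generator."""

    n_genes: int = 1000
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("tumor_cells", 200, "tumor"),
        PopulationSpec("epithelial", 200, "normal"),
        PopulationSpec("macrophage_tumor", 200, "tumor"),
        PopulationSpec("macrophage_normal", 200, "normal"),
    )
    nb_mean_log_mu: float = 0.0
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 2.0
    n_marker_genes_per_type: int = 3
    marker_fc: float = 8.0
    n_de_lr_pairs_up: int = 10
    n_de_lr_pairs_down: int = 10
    de_fc: float = 4.0
    de_population: str | None = None  # default: first tumor population
    n_bulk_samples: int = 500
    planted_rho: float = 0.5
    n_prognostic_genes: int = 5
    prognostic_beta: float = 1.0
    baseline_hazard: float = 0.02
    censor_rate: float = 0.3
    stage_logit_scale: float = 3.0  # slope of the stage-label logistic
    seed: int = 0

    def __post_init__(self) -> None:
        self.populations = tuple(
            p if isinstance(p, PopulationSpec) else PopulationSpec(*p)
            for p in self.populations
        )
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.populations:
            raise ConfigError("at least one population required")
        for p in self.populations:
            if p.n_cells <= 0:
                raise ConfigError(f"population {p.name} has non-positive cell count")
            if p.sample_type not in ("tumor", "normal"):
                raise ConfigError(f"population {p.name}: bad sample_type {p.sample_type}")
        if not 0 < self.planted_rho < 1:
            raise ConfigError("planted_rho must be in (0,1)")
        if self.de_fc <= 1:
            raise ConfigError("de_fc must exceed 1")
        if self.marker_fc <= 1:
            raise ConfigError("marker_fc must exceed 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0,1)")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        needed = (
            len(self.populations) * self.n_marker_genes_per_type
            + 2 * (self.n_de_lr_pairs_up + self.n_de_lr_pairs_down)
            + self.n_prognostic_genes
        )
        if needed > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {needed} planted genes"
            )

    @property
    def de_pop(self) -> str:
        if self.de_population is not None:
            return self.de_population
        for p in self.populations:
            if p.sample_type == "tumor":
                return p.name
        raise ConfigError("no tumor population to plant DE in")

    @property
    def normal_pop(self) -> str:
        for p in self.populations:
            if p.sample_type == "normal":
                return p.name
        raise ConfigError("no normal population")


@dataclass
class TruthManifest:
    """Record of every planted signal in a generated cohort."""

    de_genes: pd.DataFrame  # gene, contrast, direction, fold_change
    correlated_pairs: pd.DataFrame  # ligand, receptor, planted_rho
    prognostic_genes: pd.DataFrame  # gene, beta
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def validate(self, gene_symbols: list[str]) -> None:
        genes = set(gene_symbols)
        named = (
            set(self.de_genes["gene"])
            | set(self.correlated_pairs["ligand"])
            | set(self.correlated_pairs["receptor"])
            | set(self.prognostic_genes["gene"])
            | {g for gs in self.marker_genes.values() for g in gs}
        )
        missing = named - genes
        if missing:
            raise ConfigError(f"manifest names unknown genes: {sorted(missing)[:5]}")
        if not set(self.de_genes["direction"]) <= {"up", "down"}:
            raise ConfigError("de_genes direction must be up|down")
        rho = self.correlated_pairs["planted_rho"]
        if len(rho) and not ((rho > -1) & (rho < 1)).all():
            raise ConfigError("planted_rho outside (-1,1)")


def generate_lr_reference(n_pairs: int, gene_pool: list[str], seed: int) -> pd.DataFrame:
    """Draw ``n_pairs`` unique directed (ligand, receptor) rows from a gene pool.

    Genes may repeat across rows and appear in both roles, but each
    (ligand, receptor) row is unique and ligand != receptor within a row.
    """
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    pool = [str(g).strip().upper() for g in gene_pool]
    if len(set(pool)) < 2:
        raise ConfigError("gene pool must contain at least two distinct symbols")
    max_pairs = len(set(pool)) * (len(set(pool)) - 1)
    if n_pairs > max_pairs:
        raise ConfigError(
            f"gene pool of {len(set(pool))} supports at most {max_pairs} ordered pairs"
        )
    rng = np.random.default_rng(seed)
    pool = sorted(set(pool))
    rows: set[tuple[str, str]] = set()
    while len(rows) < n_pairs:
        lig, rec = rng.choice(pool, size=2, replace=False)
        rows.add((str(lig), str(rec)))
    out = pd.DataFrame(sorted(rows), columns=["ligand", "receptor"])
    return out.sample(frac=1, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(n)]


def _plan_genes(cfg: SimConfig, rng: np.random.Generator):
    """Partition the gene list into marker / DE-pair / prognostic sets."""
    genes = _gene_names(cfg.n_genes)
    order = rng.permutation(cfg.n_genes)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        sel = [genes[i] for i in order[cursor : cursor + k]]
        cursor += k
        return sel

    markers = {p.name: take(cfg.n_marker_genes_per_type) for p in cfg.populations}
    pairs_up = [(take(1)[0], take(1)[0]) for _ in range(cfg.n_de_lr_pairs_up)]
    pairs_down = [(take(1)[0], take(1)[0]) for _ in range(cfg.n_de_lr_pairs_down)]
    prognostic = take(cfg.n_prognostic_genes)
    return genes, markers, pairs_up, pairs_down, prognostic


def generate_sc_cohort(cfg: SimConfig):
    """Generate (CountMatrix, CellAnnotation, TruthManifest).

    Counts are negative binomial with log-normal baseline means. Marker genes
    are boosted by ``marker_fc`` in their own population only; planted DE
    ligand/receptor genes are multiplied (up) or divided (down) by ``de_fc``
    in ``cfg.de_pop`` only.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, markers, pairs_up, pairs_down, prognostic = _plan_genes(cfg, rng)
    gene_pos = {g: i for i, g in enumerate(genes)}

    base_mu = rng.lognormal(cfg.nb_mean_log_mu, cfg.nb_mean_log_sigma, cfg.n_genes)

    blocks = []
    ann_rows = []
    for pop in cfg.populations:
        mu = base_mu.copy()
        for g in markers[pop.name]:
            mu[gene_pos[g]] *= cfg.marker_fc
        if pop.name == cfg.de_pop:
            for lig, rec in pairs_up:
                mu[gene_pos[lig]] *= cfg.de_fc
                mu[gene_pos[rec]] *= cfg.de_fc
            for lig, rec in pairs_down:
                mu[gene_pos[lig]] /= cfg.de_fc
                mu[gene_pos[rec]] /= cfg.de_fc
        r = cfg.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p, size=(pop.n_cells, cfg.n_genes))
        blocks.append(counts)
        for i in range(pop.n_cells):
            ann_rows.append(
                {
                    "cell": f"{pop.name}.{i}",
                    "sample_id": f"{pop.name}_s0",
                    "sample_type": pop.sample_type,
                    "population": pop.name,
                }
            )

    values = np.vstack(blocks)
    annotation = pd.DataFrame(ann_rows).set_index("cell", drop=False)
    counts = CountMatrix(values, list(annotation["cell"]), genes)

    contrast = f"{cfg.de_pop}_vs_{cfg.normal_pop}"
    de_rows = []
    for lig, rec in pairs_up:
        de_rows += [
            {"gene": lig, "contrast": contrast, "direction": "up", "fold_change": cfg.de_fc},
            {"gene": rec, "contrast": contrast, "direction": "up", "fold_change": cfg.de_fc},
        ]
    for lig, rec in pairs_down:
        de_rows += [
            {"gene": lig, "contrast": contrast, "direction": "down", "fold_change": cfg.de_fc},
            {"gene": rec, "contrast": contrast, "direction": "down", "fold_change": cfg.de_fc},
        ]
    corr_rows = [
        {"ligand": lig, "receptor": rec, "planted_rho": cfg.planted_rho}
        for lig, rec in pairs_up + pairs_down
    ]
    truth = TruthManifest(
        de_genes=pd.DataFrame(de_rows, columns=["gene", "contrast", "direction", "fold_change"]),
        correlated_pairs=pd.DataFrame(corr_rows, columns=["ligand", "receptor", "planted_rho"]),
        prognostic_genes=pd.DataFrame(
            {"gene": prognostic, "beta": cfg.prognostic_beta}, columns=["gene", "beta"]
        ),
        marker_genes=markers,
    )
    truth.validate(genes)
    return counts, annotation, truth


def _latent_rho(rho_s: float) -> float:
    """Gaussian-copula latent correlation giving Spearman rho_s exactly."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def generate_bulk_cohort(cfg: SimConfig, truth: TruthManifest):
    """Generate (BulkCohort DataFrame, SurvivalTable DataFrame).

    Planted pairs get a bivariate Gaussian copula with latent correlation
    2*sin(pi*rho/6) so the population Spearman correlation equals
    ``planted_rho``; all other genes are independent. Survival is exponential
    with hazard baseline_hazard * exp(sum beta*z) over planted prognostic
    genes; censoring is independent exponential; the stage label is a
    logistic draw on the same linear predictor.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = _gene_names(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = cfg.n_bulk_samples

    z = rng.standard_normal((n, cfg.n_genes))
    r_lat = _latent_rho(cfg.planted_rho)
    for _, row in truth.correlated_pairs.iterrows():
        i, j = gene_pos[row["ligand"]], gene_pos[row["receptor"]]
        # replace receptor latent with a correlated mixture of fresh noise
        z[:, j] = r_lat * z[:, i] + np.sqrt(1 - r_lat**2) * rng.standard_normal(n)

    mu = rng.normal(7.0, 1.5, cfg.n_genes)
    sigma = rng.uniform(0.5, 2.0, cfg.n_genes)
    values = mu + sigma * z  # log2-scale marginals remain Gaussian per gene

    sample_ids = [f"S{i:04d}" for i in range(n)]
    bulk = pd.DataFrame(values, index=sample_ids, columns=genes)

    prog_idx = [gene_pos[g] for g in truth.prognostic_genes["gene"]]
    betas = truth.prognostic_genes["beta"].to_numpy(dtype=float)
    if prog_idx:
        x = values[:, prog_idx]
        zx = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        eta = zx @ betas
    else:
        eta = np.zeros(n)

    hazard = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        rate_c = cfg.baseline_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    p_high = 1.0 / (1.0 + np.exp(-cfg.stage_logit_scale * eta))
    high = rng.random(n) < p_high
    sub = rng.random(n) < 0.5
    stage = np.where(high, np.where(sub, "III", "IV"), np.where(sub, "I", "II"))

    surv = pd.DataFrame(
        {
            "sample": sample_ids,
            "time": np.maximum(time, 1e-9),
            "event": event,
            "stage": stage,
        }
    ).set_index("sample", drop=False)
    return bulk, surv


def write_truth(truth: TruthManifest, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.de_genes.to_csv(directory / "truth_de_genes.tsv", sep="\t", index=False)
    truth.correlated_pairs.to_csv(
        directory / "truth_correlated_pairs.tsv", sep="\t", index=False
    )
    truth.prognostic_genes.to_csv(
        directory / "truth_prognostic_genes.tsv", sep="\t", index=False
    )
    marker_rows = [
        {"cell_type": t, "gene": g} for t, gs in truth.marker_genes.items() for g in gs
    ]
    pd.DataFrame(marker_rows, columns=["cell_type", "gene"]).to_csv(
        directory / "truth_marker_genes.tsv", sep="\t", index=False
    )


def simulate_to_dir(cfg: SimConfig, directory: str | Path) -> None:
    """Run the full generator and write every artifact under ``directory``."""
    directory = Path(directory)
    counts, annotation, truth = generate_sc_cohort(cfg)
    bulk, surv = generate_bulk_cohort(cfg, truth)
    write_counts(counts, directory / "counts")
    write_annotation(annotation, directory / "annotation.tsv")
    write_bulk(bulk, directory / "bulk.tsv")
    write_survival(surv, directory / "survival.tsv")
    write_truth(truth, directory)
    logger.info("simulation written to %s", directory)
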