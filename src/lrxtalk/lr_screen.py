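"""Concordant ligand-receptor pair screening and crosstalk network construction.

Autocrine pairs require both partners to move in the same direction within a
single population's differential-expression table; paracrine pairs require
the ligand up in the sender population and the receptor up in the receiver.
Surviving pairs are then filtered by their Spearman coexpression in a bulk
cohort (default threshold: signed rho strictly above 0.3) and assembled into
a bipartite ligand-receptor network with degree-ranked hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ConstantInputError

logger = logging.getLogger(__name__)

AUTOCRINE_CONTEXTS = ("autocrine_tumor", "autocrine_macrophage")
PARACRINE_CONTEXTS = ("paracrine_mac_to_tumor", "paracrine_tumor_to_mac")

PAIRSET_COLUMNS = [
    "ligand", "receptor", "context", "direction", "rho", "rho_p", "passed_filter",
]


@dataclass
class ScreenConfig:
    rho_min: float = 0.3
    alpha: float = 0.05
    fc_min: float = 0.25
    abs_rho: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.rho_min < 1:
            raise ConfigError("rho_min must be in (0,1)")


def _empty_pairset() -> pd.DataFrame:
    return pd.DataFrame(columns=PAIRSET_COLUMNS)


def _direction_map(de: pd.DataFrame) -> dict[str, str]:
    return dict(zip(de["gene"], de["direction"]))


def classify_autocrine_pairs(
    de: pd.DataFrame, pairs: pd.DataFrame, context: str = "autocrine_tumor"
) -> pd.DataFrame:
    """Pairs whose ligand and receptor are concordantly up or down in ``de``."""
    if context not in AUTOCRINE_CONTEXTS:
        raise ConfigError(f"context must be one of {AUTOCRINE_CONTEXTS}")
    direction = _direction_map(de)
    rows = []
    n_skipped = 0
    for lig, rec in pairs[["ligand", "receptor"]].itertuples(index=False):
        dl, dr = direction.get(lig), direction.get(rec)
        if dl is None or dr is None:
            n_skipped += 1
            continue
        if dl == dr and dl in ("up", "down"):
            rows.append(
                {"ligand": lig, "receptor": rec, "context": context,
                 "direction": dl, "rho": np.nan, "rho_p": np.nan,
                 "passed_filter": False}
            )
    if n_skipped:
        logger.info("autocrine screen: %d pairs skipped (gene absent from DE)", n_skipped)
    return pd.DataFrame(rows, columns=PAIRSET_COLUMNS) if rows else _empty_pairset()


def classify_paracrine_pairs(
    de_sender: pd.DataFrame,
    de_receiver: pd.DataFrame,
    pairs: pd.DataFrame,
    context: str,
) -> pd.DataFrame:
    """Pairs with ligand up in the sender and receptor up in the receiver."""
    if context not in PARACRINE_CONTEXTS:
        raise ConfigError(f"context must be one of {PARACRINE_CONTEXTS}")
    dir_send = _direction_map(de_sender)
    dir_recv = _direction_map(de_receiver)
    rows = []
    n_skipped = 0
    for lig, rec in pairs[["ligand", "receptor"]].itertuples(index=False):
        dl, dr = dir_send.get(lig), dir_recv.get(rec)
        if dl is None or dr is None:
            n_skipped += 1
            continue
        if dl == "up" and dr == "up":
            rows.append(
                {"ligand": lig, "receptor": rec, "context": context,
                 "direction": "up", "rho": np.nan, "rho_p": np.nan,
                 "passed_filter": False}
            )
    if n_skipped:
        logger.info("paracrine screen: %d pairs skipped (gene absent from DE)", n_skipped)
    return pd.DataFrame(rows, columns=PAIRSET_COLUMNS) if rows else _empty_pairset()


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman correlation with average-tie ranks and t-approximation p.

    rho is the Pearson correlation of the rank vectors; p comes from
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom. Constant input
    raises :class:`ConstantInputError` (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("inputs must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ConfigError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant vector: Spearman rho undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def filter_pairs_by_bulk(
    pairs: pd.DataFrame, bulk: pd.DataFrame, cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Attach bulk Spearman rho to each pair; pass iff rho > rho_min (strict).

    With ``cfg.abs_rho`` the comparison uses |rho|. Pairs with a gene missing
    from the bulk matrix (or a constant bulk profile) get missing rho and do
    not pass; both situations are logged.
    """
    cfg = cfg or ScreenConfig()
    out = pairs.copy().reset_index(drop=True)
    rhos, ps, passed = [], [], []
    n_missing = n_constant = 0
    for lig, rec in out[["ligand", "receptor"]].itertuples(index=False):
        if lig not in bulk.columns or rec not in bulk.columns:
            n_missing += 1
            rhos.append(np.nan), ps.append(np.nan), passed.append(False)
            continue
        try:
            rho, p = spearman_rho(bulk[lig].to_numpy(), bulk[rec].to_numpy())
        except ConstantInputError:
            n_constant += 1
            rhos.append(np.nan), ps.append(np.nan), passed.append(False)
            continue
        stat = abs(rho) if cfg.abs_rho else rho
        rhos.append(rho), ps.append(p), passed.append(bool(stat > cfg.rho_min))
    if n_missing:
        logger.info("bulk filter: %d pairs with a gene absent from bulk", n_missing)
    if n_constant:
        logger.warning("bulk filter: %d pairs dropped (constant bulk vector)", n_constant)
    out["rho"] = rhos
    out["rho_p"] = ps
    out["passed_filter"] = passed
    return out


def build_network(pairs: pd.DataFrame, top_k: int = 10):
    """Build the ligand-receptor graph from passed pairs and rank hub genes.

    Returns (graph, hub_table). One node per gene; a gene seen in both roles
    gets role "both". Duplicate passed rows collapse to a single edge whose
    weight is the pair's rho.
    """
    passed = pairs[pairs["passed_filter"].astype(bool)]
    g = nx.Graph()
    roles: dict[str, set] = {}
    for lig, rec, rho in passed[["ligand", "receptor", "rho"]].itertuples(index=False):
        roles.setdefault(lig, set()).add("ligand")
        roles.setdefault(rec, set()).add("receptor")
        g.add_edge(lig, rec, weight=float(rho) if np.isfinite(rho) else 0.0)
    for gene, rs in roles.items():
        g.nodes[gene]["role"] = "both" if len(rs) > 1 else next(iter(rs))
    hub_rows = [
        {
            "gene": gene,
            "degree": g.degree(gene),
            "weight_sum": float(sum(d["weight"] for _, _, d in g.edges(gene, data=True))),
        }
        for gene in g.nodes
    ]
    hubs = pd.DataFrame(hub_rows, columns=["gene", "degree", "weight_sum"])
    if len(hubs):
        hubs = hubs.sort_values(
            ["degree", "weight_sum", "gene"], ascending=[False, False, True]
        ).head(top_k).reset_index(drop=True)
    return g, hubs


def screen_pipeline(
    de_tables: dict[str, pd.DataFrame],
    pairs: pd.DataFrame,
    bulk: pd.DataFrame,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run every context screen present in ``de_tables`` and bulk-filter.

    ``de_tables`` keys: "tumor" (tumor vs normal epithelium) and/or
    "macrophage" (tumor-associated vs normal macrophages).
    """
    cfg = cfg or ScreenConfig()
    parts = []
    if "tumor" in de_tables:
        parts.append(classify_autocrine_pairs(de_tables["tumor"], pairs, "autocrine_tumor"))
    if "macrophage" in de_tables:
        parts.append(
            classify_autocrine_pairs(de_tables["macrophage"], pairs, "autocrine_macrophage")
        )
    if {"tumor", "macrophage"} <= set(de_tables):
        parts.append(
            classify_paracrine_pairs(
                de_tables["macrophage"], de_tables["tumor"], pairs, "paracrine_mac_to_tumor"
            )
        )
        parts.append(
            classify_paracrine_pairs(
                de_tables["tumor"], de_tables["macrophage"], pairs, "paracrine_tumor_to_mac"
            )
        )
    combined = pd.concat(parts, ignore_index=True) if parts else _empty_pairset()
    return filter_pairs_by_bulk(combined, bulk, cfg)
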