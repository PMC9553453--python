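"""Gene-set scoring: module z-scores, pathway contrasts, macrophage
polarization coordinates, permutation-null ligand-receptor interaction scores
and hypergeometric over-representation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .hurdle_de import bh_adjust
from .io_core import ExprMatrix

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ConfigError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = [g.strip().upper() for g in fields[2:] if g.strip()]
    return sets


def filter_collection(
    collection: dict[str, list[str]], gene_symbols: list[str]
) -> dict[str, list[str]]:
    """Intersect each set with the matrix genes; drop empty sets with warning."""
    genes = set(gene_symbols)
    out = {}
    for name, members in collection.items():
        kept = [g for g in members if g.upper() in genes]
        if kept:
            out[name] = kept
        else:
            logger.warning("gene set %s has no genes in matrix; dropped", name)
    return out


def module_score(expr: ExprMatrix, cells, gene_set: list[str]) -> pd.Series:
    """Mean per-gene z-score over the set, per cell, across the given cells.

    Genes are z-standardized across exactly the cells supplied, so the scores
    are mean-zero over that population by construction. Constant genes are
    excluded with a warning; an empty intersection is an error.
    """
    idx = expr.cell_indices(cells)
    present = [g for g in dict.fromkeys(s.strip().upper() for s in gene_set)
               if g in set(expr.gene_symbols)]
    if not present:
        raise ConfigError("gene set does not intersect matrix genes")
    gidx = [expr.gene_index(g) for g in present]
    x = expr.values[idx][:, gidx]
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [present[i] for i in np.flatnonzero(~keep)]
        logger.warning("constant genes excluded from module score: %s", dropped[:5])
    if not keep.any():
        raise ConfigError("all set genes constant over the given cells")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    cells = list(cells)
    return pd.Series(z.mean(axis=1), index=[expr.cell_ids[i] for i in idx])


def compare_pathways(
    expr: ExprMatrix, cells_A, cells_B, collection: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-set Welch contrast of module scores between two disjoint cell groups."""
    set_a, set_b = set(cells_A), set(cells_B)
    if set_a & set_b:
        raise ConfigError("cell groups overlap")
    if not set_a or not set_b:
        raise ConfigError("both cell groups must be non-empty")
    union = list(cells_A) + list(cells_B)
    collection = filter_collection(collection, expr.gene_symbols)
    rows = []
    for name, members in collection.items():
        scores = module_score(expr, union, members)
        sa = scores.loc[list(cells_A)].to_numpy()
        sb = scores.loc[list(cells_B)].to_numpy()
        t, p = stats.ttest_ind(sa, sb, equal_var=False)
        rows.append(
            {"set": name, "delta_score": float(sa.mean() - sb.mean()),
             "t": float(t), "p": float(p)}
        )
    out = pd.DataFrame(rows, columns=["set", "delta_score", "t", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].clip(lower=np.nextafter(0, 1)))
    else:
        out["q"] = []
    return out


def polarization_scores(
    expr: ExprMatrix,
    subtype_map: pd.Series,
    axes: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-subtype mean module score along each named axis (M1/M2/pro/anti).

    ``subtype_map`` maps macrophage cell id -> subtype label; ``axes`` maps
    axis name -> gene list. Empty subtypes are dropped with a warning.
    """
    if subtype_map.empty:
        raise ConfigError("no subtypes supplied")
    cells = list(subtype_map.index)
    per_axis = {}
    for axis, gene_set in axes.items():
        per_axis[axis] = module_score(expr, cells, gene_set)
    rows = []
    for subtype, members in subtype_map.groupby(subtype_map).groups.items():
        members = list(members)
        if not members:
            logger.warning("subtype %r empty; dropped", subtype)
            continue
        row = {"subtype": subtype}
        for axis in axes:
            row[axis] = float(per_axis[axis].loc[members].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subtype", *axes])


@dataclass
class InteractionResult:
    ligand: str
    receptor: str
    sender: object
    receiver: object
    score: float
    p: float
    n_perm: int
    seed: int


def interaction_score(
    expr: ExprMatrix,
    subtype_map: pd.Series,
    pair: tuple[str, str],
    sender,
    receiver,
    n_perm: int = 1000,
    seed: int = 0,
) -> InteractionResult:
    """Product-of-means interaction score with a label-permutation null.

    score = mean ligand expression over sender cells x mean receptor
    expression over receiver cells. The null permutes subtype labels over the
    union of participating cells; p uses the add-one estimator so
    p >= 1/(n_perm+1) always.
    """
    ligand, receptor = (g.strip().upper() for g in pair)
    li = expr.gene_index(ligand)  # raises KeyError if missing
    ri = expr.gene_index(receptor)
    send_cells = list(subtype_map.index[subtype_map == sender])
    recv_cells = list(subtype_map.index[subtype_map == receiver])
    if not send_cells or not recv_cells:
        raise ConfigError("sender and receiver subtypes must be non-empty")
    union = list(dict.fromkeys(send_cells + recv_cells))
    uidx = expr.cell_indices(union)
    lig_vals = expr.values[uidx, li]
    rec_vals = expr.values[uidx, ri]
    is_send = np.array([c in set(send_cells) for c in union])
    is_recv = np.array([c in set(recv_cells) for c in union])

    def score_of(send_mask: np.ndarray, recv_mask: np.ndarray) -> float:
        return float(lig_vals[send_mask].mean() * rec_vals[recv_mask].mean())

    observed = score_of(is_send, is_recv)
    rng = np.random.default_rng(seed)
    n_ge = 0
    n_cells = len(union)
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        if score_of(is_send[perm], is_recv[perm]) >= observed - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return InteractionResult(ligand, receptor, sender, receiver, observed, p, n_perm, seed)


def ora_hypergeometric(hits, universe, annotated) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns (overlap, p) where p = P(X >= overlap) for X hypergeometric with
    population |universe|, |annotated| successes and |hits| draws.
    """
    hits, universe, annotated = set(hits), set(universe), set(annotated)
    if not hits <= universe:
        raise ConfigError("hits must be a subset of the universe")
    if not annotated <= universe:
        raise ConfigError("annotated set must be a subset of the universe")
    overlap = len(hits & annotated)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(annotated), len(hits)))
    return overlap, min(max(p, 0.0), 1.0)
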