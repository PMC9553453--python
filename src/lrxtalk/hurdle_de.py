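"""Two-part hurdle differential expression.

The test combines a binomial likelihood-ratio G-statistic on detection
(expression > 0) with a Gaussian likelihood-ratio statistic on the detected
values, each contributing one degree of freedom when defined; the sum is
referred to a chi-squared distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigError
from .io_core import ExprMatrix

logger = logging.getLogger(__name__)


def _binom_ll(k: float, n: float, p: float) -> float:
    """Binomial log-likelihood kernel with 0*log(0)=0 convention."""
    return float(special.xlogy(k, p) + special.xlogy(n - k, 1.0 - p))


def _detection_component(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """G-statistic for equal detection rates; df 0 if pooled detection degenerate."""
    na, nb = a.size, b.size
    ka, kb = int((a > 0).sum()), int((b > 0).sum())
    k, n = ka + kb, na + nb
    if k == 0 or k == n:
        return 0.0, 0
    p0 = k / n
    ll0 = _binom_ll(ka, na, p0) + _binom_ll(kb, nb, p0)
    ll1 = _binom_ll(ka, na, ka / na) + _binom_ll(kb, nb, kb / nb)
    return max(0.0, 2.0 * (ll1 - ll0)), 1


def _continuous_component(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """N*ln(RSS0/RSS1) for equal vs per-group means on detected cells only."""
    ya, yb = a[a > 0], b[b > 0]
    if ya.size < 2 or yb.size < 2:
        return 0.0, 0
    pooled = np.concatenate([ya, yb])
    n = pooled.size
    rss0 = float(((pooled - pooled.mean()) ** 2).sum())
    rss1 = float(((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum())
    if rss1 == 0.0:
        if rss0 == 0.0:
            return 0.0, 1
        return float("inf"), 1
    return max(0.0, n * float(np.log(rss0 / rss1))), 1


@dataclass
class HurdleResult:
    gene: str
    log2fc: float
    stat: float
    df: int
    p: float
    pct_A: float
    pct_B: float


def hurdle_test(
    expr: ExprMatrix, cells_A, cells_B, gene: str
) -> HurdleResult:
    """Hurdle likelihood-ratio test for one gene between two cell sets."""
    ia = expr.cell_indices(cells_A)
    ib = expr.cell_indices(cells_B)
    _check_groups(ia, ib)
    gi = expr.gene_index(gene)
    a = expr.values[ia, gi]
    b = expr.values[ib, gi]
    return _hurdle_from_vectors(expr.gene_symbols[gi], a, b)


def _check_groups(ia: np.ndarray, ib: np.ndarray) -> None:
    if ia.size < 2 or ib.size < 2:
        raise ConfigError("each group needs at least two cells")
    if np.intersect1d(ia, ib).size:
        raise ConfigError("cell groups overlap")


def _hurdle_from_vectors(gene: str, a: np.ndarray, b: np.ndarray) -> HurdleResult:
    g_disc, df_disc = _detection_component(a, b)
    g_cont, df_cont = _continuous_component(a, b)
    stat = g_disc + g_cont
    df = df_disc + df_cont
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    p = min(max(p, 0.0), 1.0)
    if df > 0 and p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return HurdleResult(
        gene=gene,
        log2fc=float(a.mean() - b.mean()),
        stat=float(stat),
        df=int(df),
        p=p,
        pct_A=float((a > 0).mean()),
        pct_B=float((b > 0).mean()),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_table(
    expr: ExprMatrix,
    cells_A,
    cells_B,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    fc_min: float = 0.25,
) -> pd.DataFrame:
    """Hurdle test per gene with BH correction and direction calls.

    direction is "up" iff q < alpha and log2fc > fc_min, "down" iff q < alpha
    and log2fc < -fc_min, else "ns".
    """
    ia = expr.cell_indices(cells_A)
    ib = expr.cell_indices(cells_B)
    _check_groups(ia, ib)
    if genes is None:
        gidx = list(range(len(expr.gene_symbols)))
    else:
        gidx = [expr.gene_index(g) for g in genes]
    if not gidx:
        return pd.DataFrame(
            columns=["gene", "log2fc", "stat", "df", "p", "q", "pct_A", "pct_B", "direction"]
        )
    sub_a = expr.values[ia][:, gidx]
    sub_b = expr.values[ib][:, gidx]
    rows = [
        _hurdle_from_vectors(expr.gene_symbols[g], sub_a[:, j], sub_b[:, j])
        for j, g in enumerate(gidx)
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["q"] = bh_adjust(df["p"])
    df["direction"] = "ns"
    df.loc[(df["q"] < alpha) & (df["log2fc"] > fc_min), "direction"] = "up"
    df.loc[(df["q"] < alpha) & (df["log2fc"] < -fc_min), "direction"] = "down"
    return df[["gene", "log2fc", "stat", "df", "p", "q", "pct_A", "pct_B", "direction"]]
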