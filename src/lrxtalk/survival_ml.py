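"""Survival analysis and the stage-label risk classifier.

Kaplan-Meier estimation and the log-rank test are implemented directly (they
are small, fully specified procedures and part of the tested surface); the
boosted-tree classifier is scikit-learn's gradient boosting, invoked as a
component behind a fixed split/label/metric protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import precision_score, recall_score
from sklearn.model_selection import train_test_split

from .errors import ConfigError
from .hurdle_de import bh_adjust

logger = logging.getLogger(__name__)

HIGH_RISK_STAGES = ("III", "IV")


@dataclass
class KMCurve:
    """Product-limit estimate: step times, survival, at-risk counts."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) with right-continuous steps."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ConfigError("empty survival input")
    if np.any(times <= 0):
        raise ConfigError("times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ConfigError("events must be 0 or 1")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv = []
    at_risk = []
    n_ev = []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_ev.append(d)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times_A, events_A, times_B, events_B) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) from the O-E statistic.

    At each pooled event time the group-A event count is compared with its
    hypergeometric expectation and variance. With no events at all the
    statistic is 0 and p = 1 (with a warning).
    """
    ta = np.asarray(times_A, dtype=float)
    ea = np.asarray(events_A, dtype=int)
    tb = np.asarray(times_B, dtype=float)
    eb = np.asarray(events_B, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ConfigError("both groups must be non-empty")
    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(pooled_t[pooled_e == 1])
    if event_times.size == 0:
        logger.warning("log-rank: no events in either group")
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = pooled_t >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group_a).sum())
        d_mask = (pooled_t == t) & (pooled_e == 1)
        d = int(d_mask.sum())
        d1 = int((d_mask & group_a).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        logger.warning("log-rank: zero variance (degenerate risk sets)")
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def prognostic_screen(
    bulk: pd.DataFrame,
    surv: pd.DataFrame,
    genes: list[str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Median-split log-rank screen per gene.

    High group: expression strictly above the cohort median (ties go low).
    ``prognostic`` is p < alpha, unadjusted by default; with ``fdr`` the BH
    q-value is compared with alpha instead.
    """
    common = bulk.index.intersection(surv.index)
    dropped = len(bulk.index) - len(common)
    if dropped:
        logger.info("prognostic screen: %d bulk samples without survival dropped", dropped)
    if len(common) == 0:
        raise ConfigError("no overlapping samples between bulk and survival tables")
    sub_bulk = bulk.loc[common]
    sub_surv = surv.loc[common]
    t = sub_surv["time"].to_numpy(dtype=float)
    e = sub_surv["event"].to_numpy(dtype=int)
    rows = []
    for gene in genes:
        g = str(gene).strip().upper()
        if g not in sub_bulk.columns:
            raise ConfigError(f"gene {g} absent from bulk matrix")
        x = sub_bulk[g].to_numpy(dtype=float)
        high = x > np.median(x)
        if high.all() or not high.any():
            logger.warning("gene %s: degenerate median split", g)
            rows.append({"gene": g, "logrank_p": np.nan})
            continue
        _, p = logrank_test(t[high], e[high], t[~high], e[~high])
        rows.append({"gene": g, "logrank_p": p})
    out = pd.DataFrame(rows, columns=["gene", "logrank_p"])
    if fdr:
        ok = out["logrank_p"].notna()
        q = pd.Series(np.nan, index=out.index)
        if ok.any():
            q[ok] = bh_adjust(out.loc[ok, "logrank_p"].clip(lower=np.nextafter(0, 1)))
        out["logrank_q"] = q
        out["prognostic"] = (q < alpha).fillna(False)
    else:
        out["prognostic"] = (out["logrank_p"] < alpha).fillna(False)
    return out


@dataclass
class RiskModel:
    features: list[str]
    classifier: GradientBoostingClassifier
    split_ratio: float
    realized_ratio: float
    seed: int
    precision: float
    recall: float
    metadata: dict = field(default_factory=dict)

    def predict_high_risk(self, bulk: pd.DataFrame) -> pd.Series:
        """Predict the high-risk class; missing feature genes imputed as
        cohort column mean (i.e. zero information) with a warning."""
        x = pd.DataFrame(index=bulk.index)
        missing = []
        for g in self.features:
            if g in bulk.columns:
                x[g] = bulk[g]
            else:
                missing.append(g)
                x[g] = 0.0
        if missing:
            logger.warning("validation: %d feature genes missing, imputed: %s",
                           len(missing), missing[:5])
        # standardize per cohort so imputed columns sit at the mean
        vals = x.to_numpy(dtype=float)
        sd = vals.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        vals = (vals - vals.mean(axis=0)) / sd
        return pd.Series(self.classifier.predict(vals).astype(int), index=bulk.index)


def _stage_labels(surv: pd.DataFrame) -> pd.Series:
    stage = surv["stage"]
    if stage.isna().any():
        bad = surv.loc[stage.isna(), "sample"].tolist()[:5]
        raise ConfigError(f"stage missing for samples: {bad}")
    return stage.isin(HIGH_RISK_STAGES).astype(int)


def train_risk_model(
    bulk: pd.DataFrame,
    surv: pd.DataFrame,
    genes: list[str],
    split_ratio: float = 2 / 3,
    seed: int = 0,
    n_estimators: int = 300,
    max_depth: int = 3,
    learning_rate: float = 0.1,
    subsample: float = 0.5,
    max_features: str | None = "sqrt",
) -> RiskModel:
    """Fit the stage-risk boosted-tree classifier with a stratified split.

    High risk = stage III-IV. The cohort splits into training and held-out
    parts at ``split_ratio`` (default 2:1), stratified on the label; held-out
    precision and recall of the high-risk class are recorded on the model.
    """
    genes = [str(g).strip().upper() for g in genes]
    if not genes:
        raise ConfigError("feature gene list is empty")
    missing = [g for g in genes if g not in bulk.columns]
    if missing:
        raise ConfigError(f"feature genes absent from bulk: {missing[:5]}")
    common = bulk.index.intersection(surv.index)
    if len(common) < 10:
        raise ConfigError("too few overlapping samples to train")
    x_df = bulk.loc[common, genes]
    y = _stage_labels(surv.loc[common]).to_numpy()
    if len(np.unique(y)) < 2:
        raise ConfigError("both risk classes must be present")
    vals = x_df.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    vals = (vals - vals.mean(axis=0)) / sd
    x_tr, x_te, y_tr, y_te = train_test_split(
        vals, y, train_size=split_ratio, stratify=y, random_state=seed
    )
    if len(np.unique(y_tr)) < 2:
        raise ConfigError("a risk class is absent from the training split")
    # row/column subsampling regularizes the fit, mirroring the subsampled
    # tree boosting the classifier stands in for
    clf = GradientBoostingClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        subsample=subsample,
        max_features=max_features,
        random_state=seed,
    )
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    precision = float(precision_score(y_te, pred, pos_label=1, zero_division=0))
    recall = float(recall_score(y_te, pred, pos_label=1, zero_division=0))
    return RiskModel(
        features=genes,
        classifier=clf,
        split_ratio=split_ratio,
        realized_ratio=len(y_tr) / max(len(y_te), 1),
        seed=seed,
        precision=precision,
        recall=recall,
        metadata={"n_train": int(len(y_tr)), "n_test": int(len(y_te))},
    )


def validate_risk_model(
    model: RiskModel, bulk_ext: pd.DataFrame, surv_ext: pd.DataFrame
):
    """Apply the model to an external cohort; KM per predicted group + log-rank p.

    Returns (curves: dict group -> KMCurve, p or None). If every sample lands
    in one predicted class, p is None with a warning.
    """
    common = bulk_ext.index.intersection(surv_ext.index)
    if len(common) == 0:
        raise ConfigError("no overlapping samples in external cohort")
    pred = model.predict_high_risk(bulk_ext.loc[common])
    sub = surv_ext.loc[common]
    curves = {}
    for label, name in ((1, "high"), (0, "low")):
        mask = pred == label
        if mask.any():
            curves[name] = km_curve(
                sub.loc[mask.to_numpy(), "time"], sub.loc[mask.to_numpy(), "event"]
            )
    if len(curves) < 2:
        logger.warning("all external samples predicted one class; p undefined")
        return curves, None
    hi = pred == 1
    _, p = logrank_test(
        sub.loc[hi.to_numpy(), "time"], sub.loc[hi.to_numpy(), "event"],
        sub.loc[(~hi).to_numpy(), "time"], sub.loc[(~hi).to_numpy(), "event"],
    )
    return curves, p
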