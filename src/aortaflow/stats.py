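"""Cohort comparison statistics for regional hemodynamic-parameter tables.

The battery mirrors how 4D-flow biomarker studies rank candidate parameters:
a global MANOVA (Pillai's trace) across all parameters, region-wise
Mann-Whitney U maps with a direction sign, ROC/AUC with Youden-point
sensitivity/specificity, greedy minimum-redundancy-maximum-relevance (MRMR)
feature ranking, and Spearman correlation against the ascending-aorta
diameter with the qualitative bins good / strong / excellent.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatReport",
    "classify_morphotype",
    "non_aaod",
    "manova_pillai",
    "mann_whitney",
    "mwu_map",
    "roc_auc",
    "mrmr_rank",
    "spearman_bins",
]


# ---------------------------------------------------------------------------
# morphotype classification

def classify_morphotype(zsinus: float, zAAo: float,
                        tie: str = "AAoD") -> str:
    """Dilation morphotype from aortic z-scores.

    Non-dilated: zsinus <= 2 and zAAo <= 2; root-dilated: zsinus > 2 and
    zsinus > zAAo; ascending-dilated: zAAo > 2 and zAAo > zsinus.  The one
    uncovered corner (zsinus == zAAo > 2) falls to ``tie`` (default AAoD).
    """
    if not (np.isfinite(zsinus) and np.isfinite(zAAo)):
        raise ValueError("z-scores must be finite")
    if zsinus <= 2 and zAAo <= 2:
        return "NonD"
    if zsinus > 2 and zsinus > zAAo:
        return "RootD"
    if zAAo > 2 and zAAo > zsinus:
        return "AAoD"
    return tie


def non_aaod(morphotype: str) -> bool:
    """The study's two-way grouping: Non-AAoD pools NonD and RootD."""
    return morphotype in ("NonD", "RootD")


# ---------------------------------------------------------------------------
# MANOVA / Pillai

def manova_pillai(X: np.ndarray, groups: np.ndarray) -> dict:
    """Pillai's trace V = tr(H (H+E)^-1) with the standard F approximation.

    ``X`` is (n, p) responses, ``groups`` the group label per row.  When any
    group has fewer subjects than p + 1, the response set is reduced (most
    univariately separating variables first) and a warning is issued.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    labels, idx = np.unique(groups, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    n, p = X.shape
    min_n = np.bincount(idx).min()
    if min_n <= p:
        fstat = np.array([
            sps.f_oneway(*(X[idx == k, j] for k in range(g))).statistic
            for j in range(p)
        ])
        keep = np.argsort(-np.nan_to_num(fstat))[: max(1, min_n - 1)]
        warnings.warn(
            f"group size {min_n} <= {p} responses; reduced to {len(keep)} "
            "most separating variables")
        X = X[:, keep]
        p = X.shape[1]

    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for k in range(g):
        xk = X[idx == k]
        mk = xk.mean(axis=0)
        d = (mk - grand)[:, None]
        H += len(xk) * d @ d.T
        r = xk - mk
        E += r.T @ r
    HE = H + E
    try:
        V = float(np.trace(np.linalg.solve(HE, H)))
    except np.linalg.LinAlgError:
        warnings.warn("singular within+between matrix; using pseudo-inverse")
        V = float(np.trace(np.linalg.pinv(HE) @ H))

    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or V >= s:
        F, pval = np.inf, 0.0
    else:
        F = (df2 / df1) * (V / (s - V))
        pval = float(sps.f.sf(F, df1, df2))
    return {"pillai": V, "F": float(F), "df1": float(df1), "df2": float(df2),
            "p": pval, "s": s}


# ---------------------------------------------------------------------------
# Mann-Whitney maps

def mann_whitney(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided Mann-Whitney U with direction sign.

    Exact p when combined n <= 20 and there are no ties, normal
    approximation with tie correction otherwise.  Sign is '-' when the
    second sample's median is below the first's.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = len(x) * len(y) / 2.0
        return {"U": u, "p": 1.0, "sign": "+"}
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    sign = "-" if np.median(y) < np.median(x) else "+"
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0)),
            "sign": sign}


def mwu_map(cohort_wide: pd.DataFrame, grouping: pd.Series,
            group_pair: tuple[str, str],
            alpha: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney p-value and direction per (parameter, region) cell.

    ``cohort_wide`` is indexed by subject with MultiIndex columns
    (parameter, region); ``grouping`` maps subject to group.  Returns a tidy
    frame with columns parameter, region, U, p, sign, significant.
    """
    g1, g2 = group_pair
    rows = []
    for (param, region) in cohort_wide.columns:
        vals = cohort_wide[(param, region)]
        x = vals[grouping == g1].dropna().to_numpy()
        y = vals[grouping == g2].dropna().to_numpy()
        r = mann_whitney(x, y)
        rows.append((param, region, r["U"], r["p"], r["sign"],
                     r["p"] < alpha))
    return pd.DataFrame(rows, columns=["parameter", "region", "U", "p",
                                       "sign", "significant"])


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(values: np.ndarray, labels: np.ndarray) -> dict:
    """AUC via the rank (Mann-Whitney) identity with tie correction, plus the
    ROC curve and Youden-point sensitivity/specificity.

    ``labels`` is boolean-like, True = positive class; higher values are
    scored as predicting the positive class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(values)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, values)
    j = int(np.argmax(tpr - fpr))
    return {"auc": float(auc), "fpr": fpr, "tpr": tpr, "thresholds": thr,
            "sensitivity": float(tpr[j]), "specificity": float(1 - fpr[j]),
            "youden_threshold": float(thr[j])}


# ---------------------------------------------------------------------------
# MRMR (FCQ variant: F-test relevance / correlation-quotient redundancy)

def mrmr_rank(features: pd.DataFrame, labels: np.ndarray,
              k: int | None = None) -> pd.DataFrame:
    """Greedy MRMR ranking of continuous features against a class label.

    Relevance is the one-way ANOVA F statistic; redundancy is the mean
    absolute Pearson correlation with already-selected features; the greedy
    score is relevance / redundancy.  Constant features get zero relevance
    and sink to the bottom; ties break on column order.
    """
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    labels = np.asarray(labels)
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    k = X.shape[1] if k is None else min(k, X.shape[1])
    classes = np.unique(labels)
    rel = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            rel[j] = 0.0
            continue
        f = sps.f_oneway(*(col[labels == c] for c in classes)).statistic
        rel[j] = 0.0 if not np.isfinite(f) else float(f)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.nan_to_num(corr, nan=1.0)   # constant features: fully redundant

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(X.shape[1]))
    while remaining and len(selected) < k:
        if not selected:
            cand = np.array([rel[j] for j in remaining])
        else:
            red = np.array([corr[j, selected].mean() for j in remaining])
            cand = np.array([rel[j] for j in remaining]) / np.maximum(red, 1e-12)
        best = int(np.argmax(cand))          # first max wins ties
        scores.append(float(cand[best]))
        selected.append(remaining.pop(best))
    return pd.DataFrame({
        "feature": [names[j] for j in selected],
        "score": scores,
        "relevance": [rel[j] for j in selected],
        "rank": np.arange(1, len(selected) + 1),
    })


# ---------------------------------------------------------------------------
# Spearman bins

_BINS = (("excellent", 0.9), ("strong", 0.7), ("good", 0.5))


def spearman_bins(values: np.ndarray, diameters: np.ndarray) -> dict:
    """Spearman S against diameter with the qualitative bin label.

    good: 0.5 < |S| <= 0.7; strong: 0.7 < |S| <= 0.9; excellent:
    0.9 < |S| <= 1; otherwise none.  The sign is retained (negative =
    inverse correlation).  Constant input yields a missing result.
    """
    values = np.asarray(values, dtype=float)
    diameters = np.asarray(diameters, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(values == values[0]) or np.all(diameters == diameters[0]):
        return {"S": np.nan, "bin": "missing", "negative": False}
    s = float(sps.spearmanr(values, diameters).statistic)
    label = "none"
    for name, lo in _BINS:
        if abs(s) > lo:
            label = name
            break
    return {"S": s, "bin": label, "negative": s < 0}


# ---------------------------------------------------------------------------
# report container

@dataclasses.dataclass
class StatReport:
    """Bundle of the statistical battery's outputs for one comparison."""

    pillai: dict | None = None
    mwu: pd.DataFrame | None = None
    auc_table: pd.DataFrame | None = None
    mrmr: pd.DataFrame | None = None
    spearman: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out: dict = {}
        if self.pillai is not None:
            out["pillai"] = self.pillai
        for name in ("mwu", "auc_table", "mrmr", "spearman"):
            df = getattr(self, name)
            if df is not None:
                out[name] = df.to_dict(orient="records")
        return out
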