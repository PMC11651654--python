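"""Promoter-interacting DHS clustering, enhancer enrichment, and contact-strength modeling.

Promoter-interacting DHSs are characterized by which transcription-related
factors (TRFs) bind them.  Binding is binarized (DHS overlaps >= 1 peak of a
factor), columns restricted to well-represented, PIR-enriched factors, and
rows clustered by Ward's minimum-variance agglomeration.  Cluster enhancer
enrichment is scored with a one-sided binomial test against the cluster-size
null.

Contact strength between viewpoints and DHSs is modeled with random-forest
regression (or classification above/below the median signal), and candidate
ChIP-seq features are ranked by greedy forward selection under 3-fold
cross-validation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .intervals import BED3, overlaps_any
from .viewpoints import DepthTrack

logger = logging.getLogger("nucleocall")

DEFAULT_MIN_BOUND = 1000   # strict: column sum must exceed this
DEFAULT_MIN_ENRICH = 2.0   # strict: log2 PIR enrichment must exceed this
DEFAULT_K = 4
DEFAULT_TOP_TRFS = 20
DEFAULT_N_ADD = 10
DEFAULT_FOLDS = 3
RF_TREES = 100
RF_MTRY = 3


# ---------------------------------------------------------------------------
# binding matrix & clustering
# ---------------------------------------------------------------------------

def build_binding_matrix(dhs: pd.DataFrame, trf_sets: dict[str, pd.DataFrame],
                         enrichment: dict[str, float] | None = None,
                         min_bound: int = DEFAULT_MIN_BOUND,
                         min_enrich: float = DEFAULT_MIN_ENRICH) -> pd.DataFrame:
    """Binary DHS x TRF matrix, columns filtered by representation and enrichment.

    Cell = 1 iff the DHS overlaps >= 1 peak of the factor.  A column survives
    iff its sum exceeds ``min_bound`` and (when enrichment values are given)
    its PIR enrichment exceeds ``min_enrich``.
    """
    cols = {}
    for name, feats in trf_sets.items():
        cols[name] = overlaps_any(dhs, feats).astype(np.int8)
    mat = pd.DataFrame(cols, index=dhs.index)
    keep = mat.sum(axis=0) > min_bound
    if enrichment is not None:
        for name in mat.columns:
            keep[name] &= enrichment.get(name, float("-inf")) > min_enrich
    dropped = [c for c in mat.columns if not keep[c]]
    if dropped:
        logger.info("build_binding_matrix: dropped %d factor columns", len(dropped))
    return mat.loc[:, keep[mat.columns]]


def cluster_dhs(matrix: pd.DataFrame, k: int = DEFAULT_K,
                top_n: int = DEFAULT_TOP_TRFS):
    """Ward clustering of binary binding rows, cut at ``k`` clusters.

    Returns (labels 1..k per row, {cluster: top-N factors by bound count},
    union of the per-cluster top lists).
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds {len(matrix)} rows")
    if k == 1:
        labels = pd.Series(1, index=matrix.index, name="cluster")
    else:
        Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="ward")
        labels = pd.Series(hierarchy.fcluster(Z, t=k, criterion="maxclust"),
                           index=matrix.index, name="cluster")
    top = {}
    union: list[str] = []
    for c in sorted(labels.unique()):
        counts = matrix.loc[labels == c].sum(axis=0).sort_values(ascending=False)
        top[c] = list(counts.index[:top_n])
        for name in top[c]:
            if name not in union:
                union.append(name)
    return labels, top, union


def cluster_enhancer_test(labels: pd.Series, enhancer_hit: pd.Series) -> pd.DataFrame:
    """One-sided binomial enrichment of enhancer-overlapping rows per cluster.

    For cluster c: n = total enhancer-overlapping rows, x = those in c,
    p0 = |c| / total rows; p = P(X >= x | Binomial(n, p0)).
    """
    total = len(labels)
    n = int(enhancer_hit.sum())
    rows = []
    for c in sorted(labels.unique()):
        size = int((labels == c).sum())
        x = int(enhancer_hit[labels == c].sum())
        p0 = size / total
        pval = 1.0 if size == 0 else float(sps.binom.sf(x - 1, n, p0))
        rows.append({"cluster": int(c), "size": size, "enhancer_hits": x,
                     "p0": p0, "p_value": pval})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outliers & correlation utilities
# ---------------------------------------------------------------------------

def iqr_outlier_filter(values, t: float) -> np.ndarray:
    """Keep-mask dropping values above Q3 + t*IQR (quartiles by linear interpolation)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 values")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # default 'linear' interpolation
    iqr = q3 - q1
    if iqr == 0:
        logger.warning("iqr_outlier_filter: zero IQR, nothing dropped")
        return np.ones(len(x), dtype=bool)
    return x <= q3 + t * iqr


def coverage_correlation(track_a: DepthTrack, track_b: DepthTrack,
                         regions: pd.DataFrame) -> float:
    """Pearson correlation of per-region mean coverages of two depth tracks."""
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    a = np.array([track_a.mean_depth(c, s, e)
                  for c, s, e in regions[BED3].itertuples(index=False)])
    b = np.array([track_b.mean_depth(c, s, e)
                  for c, s, e in regions[BED3].itertuples(index=False)])
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in region coverages")
    r, _ = sps.pearsonr(a, b)
    return float(r)


# ---------------------------------------------------------------------------
# greedy forward feature selection with random forests
# ---------------------------------------------------------------------------

def _cv_score(X: pd.DataFrame, y: np.ndarray, mode: str, folds: int, seed: int) -> float:
    """Mean per-fold CV score: R^2 (regression) or AUC (median-split classification)."""
    if mode == "regression":
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        y_fit = y
        strat = None
    else:
        y_fit = (y > np.median(y)).astype(int)
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        strat = y_fit
    scores = []
    Xv = X.to_numpy(dtype=float)
    mtry = min(RF_MTRY, Xv.shape[1])
    for fold, (tr, te) in enumerate(splitter.split(Xv, strat) if strat is not None
                                    else splitter.split(Xv)):
        if mode == "regression":
            model = RandomForestRegressor(n_estimators=RF_TREES, max_features=mtry,
                                          random_state=seed + fold, n_jobs=1)
            model.fit(Xv[tr], y_fit[tr])
            # a zero-variance test fold has no variance to explain: score 0
            if np.var(y_fit[te]) == 0:
                scores.append(0.0)
            else:
                scores.append(r2_score(y_fit[te], model.predict(Xv[te])))
        else:
            model = RandomForestClassifier(n_estimators=RF_TREES, max_features=mtry,
                                           random_state=seed + fold, n_jobs=1)
            model.fit(Xv[tr], y_fit[tr])
            scores.append(roc_auc_score(y_fit[te], model.predict_proba(Xv[te])[:, 1]))
    return float(np.mean(scores))


def greedy_rf_selection(table: pd.DataFrame, base_features: list[str],
                        candidates: list[str], target: str,
                        n_add: int = DEFAULT_N_ADD, folds: int = DEFAULT_FOLDS,
                        mode: str = "regression", seed: int = 0) -> pd.DataFrame:
    """Greedy forward selection of candidate features on top of the base model.

    At each step every remaining candidate is scored by retraining the random
    forest (100 trees, 3 features per split) with base + selected + candidate
    under ``folds``-fold CV; the best scorer is appended.  Returns the trace
    (step, feature, score).  Deterministic given ``seed``.
    """
    if mode not in ("regression", "classification"):
        raise ValueError(f"bad mode {mode!r}")
    remaining = list(candidates)
    if n_add > len(remaining):
        logger.warning("greedy_rf_selection: only %d candidates for n_add=%d",
                       len(remaining), n_add)
        n_add = len(remaining)
    y = table[target].to_numpy(dtype=float)
    selected: list[str] = []
    rows = [{"step": 0, "feature": "<base>",
             "score": _cv_score(table[base_features], y, mode, folds, seed)}]
    for step in range(1, n_add + 1):
        best_feat, best_score = None, -np.inf
        for feat in remaining:
            cols = base_features + selected + [feat]
            s = _cv_score(table[cols], y, mode, folds, seed)
            if s > best_score:
                best_feat, best_score = feat, s
        selected.append(best_feat)
        remaining.remove(best_feat)
        rows.append({"step": step, "feature": best_feat, "score": best_score})
    return pd.DataFrame(rows)
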