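"""Minimal-optimal feature selection cascade.

Stages, in order:

1. **Significance screen** — omnibus Kruskal-Wallis across the hoarseness
   levels H; features with p > 0.05 are dropped.
2. **Combined relevance ranking** — the mean of four min-max-normalized
   scores: the Kruskal-Wallis statistic, ReliefF, |Spearman rho(feature, H)|,
   and mutual information with H (equal-frequency 10-bin discretization).
3. **Redundancy pruning** — features with pairwise |Spearman rho| >= 0.9 are
   grouped by graph connectivity; the most relevant member of each group is
   retained.
4. **Top-k truncation** — keep the k = 10 highest combined scores.
5. **Embedded ranking + greedy forward selection** — rank by a model's own
   importances (|coefficients| for linear models, total information gain for
   gradient-boosted trees), then grow prefixes of the ranking while the mean
   negative log loss over a stratified 5-fold CV keeps improving.

The final set is by construction a prefix of the embedded ranking, nested
inside the top-k set, the pruned set, and the screened set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import log_loss, mutual_info_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RelevanceResult",
    "SelectionResult",
    "kruskal_screen",
    "relieff",
    "relevance_scores",
    "redundancy_prune",
    "top_k",
    "embedded_rank",
    "greedy_forward_select",
    "select_features",
]


@dataclass
class RelevanceResult:
    """Per-feature relevance: raw method scores plus the combined score."""

    table: pd.DataFrame  # index = feature names; columns = kw_stat, kw_p,
    # relieff_score, spearman_rho, mutual_information, combined_score

    def ranking(self) -> list:
        """Feature names by decreasing combined score (ties lexicographic)."""
        t = self.table.sort_index().sort_values("combined_score", ascending=False, kind="stable")
        return list(t.index)


@dataclass
class SelectionResult:
    """Outcome of the full cascade; each stage is a subset of the previous."""

    retained_after_screen: list
    retained_after_redundancy: list
    top_k_set: list
    forward_selection_path: list  # [(feature, cv_objective_after_adding)]
    final_set: list
    relevance: RelevanceResult | None = None
    redundancy_groups: list = field(default_factory=list)

    def validate_nesting(self) -> None:
        assert set(self.final_set) <= set(self.top_k_set)
        assert set(self.top_k_set) <= set(self.retained_after_redundancy)
        assert set(self.retained_after_redundancy) <= set(self.retained_after_screen)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "retained_after_screen": self.retained_after_screen,
                    "retained_after_redundancy": self.retained_after_redundancy,
                    "top_k_set": self.top_k_set,
                    "forward_selection_path": [[f, o] for f, o in self.forward_selection_path],
                    "final_set": self.final_set,
                    "redundancy_groups": [list(g) for g in self.redundancy_groups],
                },
                fh,
                indent=1,
            )


def _groups_by_level(x: np.ndarray, h: np.ndarray):
    return [x[h == level] for level in np.unique(h)]


def kruskal_screen(
    table: pd.DataFrame, h: np.ndarray, alpha: float = 0.05
) -> tuple[list, pd.Series]:
    """Omnibus Kruskal-Wallis per feature across H groups; keep p <= alpha.

    A feature identical across all groups has no rank information and is
    excluded (p = 1 by convention).
    """
    h = np.asarray(h)
    levels, counts = np.unique(h, return_counts=True)
    if len(levels) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 hoarseness levels with >= 2 observations each")
    pvals = {}
    for name in table.columns:
        x = table[name].to_numpy(float)
        if np.ptp(x) == 0:  # identical across all groups: no rank information
            pvals[name] = 1.0
            continue
        try:
            _, p = _stats.kruskal(*_groups_by_level(x, h))
        except ValueError:
            p = 1.0
        pvals[name] = p if np.isfinite(p) else 1.0
    pvals = pd.Series(pvals)
    retained = [name for name in table.columns if pvals[name] <= alpha]
    return retained, pvals


def relieff(
    table: pd.DataFrame, y: np.ndarray, k: int = 10, seed: int = 0
) -> pd.Series:
    """Multiclass ReliefF feature weights.

    Every instance contributes: weights decrease with the mean per-feature
    distance to its k nearest same-class neighbors (hits) and increase with
    the distance to the k nearest neighbors of each other class (misses),
    the latter weighted by the class priors P(c)/(1 - P(class(i))).
    Distances use Manhattan metric on min-max-scaled features.
    """
    y = np.asarray(y)
    x = table.to_numpy(float)
    n, m = x.shape
    rng_span = x.max(axis=0) - x.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    xs = (x - x.min(axis=0)) / rng_span

    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}

    w = np.zeros(m)
    for i in range(n):
        ci = y[i]
        denom = 1.0 - priors[ci] if len(classes) > 1 else 1.0
        for c in classes:
            cand = idx_by_class[c]
            cand = cand[cand != i]
            if len(cand) == 0:
                continue
            d = np.abs(xs[cand] - xs[i]).sum(axis=1)
            nn = cand[np.argsort(d, kind="stable")[: min(k, len(cand))]]
            diff = np.abs(xs[nn] - xs[i]).mean(axis=0)
            if c == ci:
                w -= diff
            else:
                w += (priors[c] / denom) * diff
    return pd.Series(w / n, index=table.columns)


def _minmax(s: pd.Series) -> pd.Series:
    lo, hi = s.min(), s.max()
    if hi - lo <= 0:
        return pd.Series(1.0, index=s.index)  # degenerate: everything maximal
    return (s - lo) / (hi - lo)


def _equal_freq_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    ranks = _stats.rankdata(x, method="average")
    return np.ceil(ranks * n_bins / len(x)).astype(int)


def relevance_scores(
    table: pd.DataFrame, h: np.ndarray, relieff_k: int = 10, seed: int = 0
) -> RelevanceResult:
    """Combined relevance: mean of four min-max-normalized method scores.

    Constant features score 0 on every method before normalization.
    """
    h = np.asarray(h)
    _, kw_p = kruskal_screen(table, h, alpha=1.1)  # statistics only, keep all
    kw_stat = {}
    for name in table.columns:
        x = table[name].to_numpy(float)
        if np.ptp(x) == 0:
            kw_stat[name] = 0.0
            continue
        try:
            stat, _ = _stats.kruskal(*_groups_by_level(x, h))
        except ValueError:
            stat = 0.0
        kw_stat[name] = stat if np.isfinite(stat) else 0.0
    rel = relieff(table, h, k=relieff_k, seed=seed)
    spear = {}
    mi = {}
    for name in table.columns:
        x = table[name].to_numpy(float)
        if np.ptp(x) == 0:
            spear[name] = 0.0
            mi[name] = 0.0
            continue
        rho, _ = _stats.spearmanr(x, h)
        spear[name] = abs(float(rho)) if np.isfinite(rho) else 0.0
        mi[name] = float(mutual_info_score(_equal_freq_bins(x), h))

    tbl = pd.DataFrame(
        {
            "kw_stat": pd.Series(kw_stat),
            "kw_p": kw_p,
            "relieff_score": rel,
            "spearman_rho": pd.Series(spear),
            "mutual_information": pd.Series(mi),
        }
    ).loc[list(table.columns)]
    norm = pd.concat(
        [
            _minmax(tbl["kw_stat"]),
            _minmax(tbl["relieff_score"]),
            _minmax(tbl["spearman_rho"]),
            _minmax(tbl["mutual_information"]),
        ],
        axis=1,
    )
    tbl["combined_score"] = norm.mean(axis=1)
    return RelevanceResult(table=tbl)


def redundancy_prune(
    table: pd.DataFrame, combined_scores: pd.Series, rho_threshold: float = 0.9
) -> tuple[list, list]:
    """Group features with |Spearman rho| >= threshold; keep the best of each.

    Groups are connected components of the correlation graph; within a group
    the feature with the highest combined score wins (ties lexicographic).
    Returns (retained feature names in original column order, groups).
    """
    names = list(table.columns)
    n = len(names)
    if n == 1:
        return names, [names]
    corr, _ = _stats.spearmanr(table.to_numpy(float))
    corr = np.atleast_2d(corr)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) >= rho_threshold:
                parent[find(i)] = find(j)

    groups_map: dict[int, list] = {}
    for i in range(n):
        groups_map.setdefault(find(i), []).append(names[i])
    groups = list(groups_map.values())
    keep = set()
    for group in groups:
        best = sorted(group, key=lambda f: (-combined_scores[f], f))[0]
        keep.add(best)
    return [f for f in names if f in keep], groups


def top_k(combined_scores: pd.Series, k: int = 10) -> list:
    """The k features with the highest combined scores (ties lexicographic)."""
    order = sorted(combined_scores.index, key=lambda f: (-combined_scores[f], f))
    return order[: min(k, len(order))]


def embedded_rank(model_id: str, table: pd.DataFrame, labels: np.ndarray, seed: int = 0) -> list:
    """Rank features by a model's own importance notion, descending.

    Linear models rank by |coefficient| on standardized features; gradient-
    boosted trees by total information-gain importance.  Ties (including the
    all-zero case) resolve lexicographically.
    """
    from .modeling import LINEAR_MODELS, TREE_MODELS, class_weights, make_estimator

    labels = np.asarray(labels)
    x = table.to_numpy(float)
    names = list(table.columns)
    cw = class_weights(labels)
    sw = np.array([cw[int(v)] for v in labels])

    if model_id in LINEAR_MODELS:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        est = make_estimator(model_id, params={}, seed=seed)
        est.fit((x - mu) / sd, labels, sample_weight=sw)
        importance = np.abs(np.ravel(est.coef_))
    elif model_id in TREE_MODELS:
        est = make_estimator(model_id, params={}, seed=seed)
        est.fit(x, labels, sample_weight=sw)
        if hasattr(est, "get_booster"):  # xgboost: total gain
            gain = est.get_booster().get_score(importance_type="total_gain")
            importance = np.array([gain.get(f"f{i}", 0.0) for i in range(len(names))])
        elif hasattr(est, "booster_"):  # lightgbm
            importance = est.booster_.feature_importance(importance_type="gain").astype(float)
        elif hasattr(est, "feature_importances_"):
            importance = np.asarray(est.feature_importances_, dtype=float)
        else:
            raise ValueError(f"model '{model_id}' exposes no importance notion")
    else:
        raise ValueError(f"unsupported model for embedded ranking: {model_id}")

    order = sorted(range(len(names)), key=lambda i: (-importance[i], names[i]))
    return [names[i] for i in order]


def _cv_objective(
    model_id: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int,
    seed: int,
) -> float:
    """Mean negative log loss over a seeded stratified CV (higher is better)."""
    from .modeling import class_weights, make_estimator

    x = table.to_numpy(float)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = []
    for tr, va in skf.split(x, labels):
        cw = class_weights(labels[tr])
        sw = np.array([cw[int(v)] for v in labels[tr]])
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        est = make_estimator(model_id, params={}, seed=seed)
        est.fit((x[tr] - mu) / sd, labels[tr], sample_weight=sw)
        proba = est.predict_proba((x[va] - mu) / sd)
        losses.append(log_loss(labels[va], proba, labels=[0, 1]))
    return -float(np.mean(losses))


def greedy_forward_select(
    ranked: list,
    model_id: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list, list]:
    """Grow prefixes of the embedded ranking while CV log loss improves.

    Stops at the first prefix whose successor does not increase the mean
    negative log loss; always returns at least one feature.  Returns
    (final prefix, path of (feature, objective-after-adding)).
    """
    if not ranked:
        raise ValueError("ranked feature list must be nonempty")
    path = []
    best_obj = _cv_objective(model_id, table[[ranked[0]]], labels, folds, seed)
    path.append((ranked[0], best_obj))
    k = 1
    while k < len(ranked):
        obj = _cv_objective(model_id, table[ranked[: k + 1]], labels, folds, seed)
        path.append((ranked[k], obj))
        if obj <= best_obj:
            break
        best_obj = obj
        k += 1
    return ranked[:k], path


def select_features(
    table: pd.DataFrame,
    h: np.ndarray,
    labels: np.ndarray,
    model_id: str = "logistic_regression",
    alpha: float = 0.05,
    rho_threshold: float = 0.9,
    k: int = 10,
    folds: int = 5,
    relieff_k: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Run the full cascade: screen, rank, prune, truncate, forward-select."""
    screened, _ = kruskal_screen(table, h, alpha=alpha)
    if not screened:
        raise ValueError("no feature passed the significance screen")
    sub = table[screened]
    relevance = relevance_scores(sub, h, relieff_k=relieff_k, seed=seed)
    scores = relevance.table["combined_score"]
    pruned, groups = redundancy_prune(sub, scores, rho_threshold=rho_threshold)
    top = top_k(scores[pruned], k=k)
    ranked = embedded_rank(model_id, table[top], labels, seed=seed)
    final, path = greedy_forward_select(ranked, model_id, table, labels, folds=folds, seed=seed)
    result = SelectionResult(
        retained_after_screen=screened,
        retained_after_redundancy=pruned,
        top_k_set=top,
        forward_selection_path=path,
        final_set=final,
        relevance=relevance,
        redundancy_groups=groups,
    )
    result.validate_nesting()
    return result
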