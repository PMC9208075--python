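"""Type-specific marker cascade: one-vs-all DMPs -> ReliefF -> K-means
redundancy filter -> PLS-DA combination search -> integrated model.

The cascade reduces per-type one-vs-all DMPs to a compact multiclass
tissue-of-origin panel: ReliefF ranks features by their local relevance,
K-means over standardized feature profiles removes redundant (co-varying)
probes keeping two representatives per cluster — the member closest to the
centroid and the member with the highest Relief weight — and an exhaustive
PLS-DA search over fixed-size probe combinations picks, per cancer type,
the combination with the best cross-validated one-vs-rest AUC. The final
model is a single PLS-DA fit on the union of the per-type winners.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning

from .datatypes import BetaMatrix, ValidationError
from .differential import DmpThresholds, dmp_pipeline
from .evaluation import rank_auc, stratified_kfold


@dataclass
class ReliefScores:
    feature_ids: list[str]
    weights: np.ndarray
    k: int
    n_sampled: int | str = "all"

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.feature_ids, name="relief_weight")


@dataclass
class FeatureCluster:
    cluster_id: int
    member_feature_ids: list[str]
    centroid: np.ndarray
    selected_centroid_feature: str
    selected_top_relief_feature: str | None


@dataclass
class PlsdaModel:
    """PLS2 regression of the one-hot class indicator matrix on X.

    Prediction is the class with the maximal predicted indicator score;
    the continuous per-class scores are retained for ROC analysis.
    """

    predictor_ids: list[str]
    classes: list[str]
    n_components: int
    pls: PLSRegression = field(repr=False)
    x_loadings: np.ndarray = field(default=None, repr=False)

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.pls.predict(X[self.predictor_ids].to_numpy(float)))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.predict_scores(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


def call_type_specific_dmps(
    pooled_tumors: BetaMatrix,
    samples: pd.DataFrame,
    thresholds: DmpThresholds | None = None,
) -> tuple[dict[str, list[str]], dict[str, pd.DataFrame]]:
    """One-vs-all DMPs per tumor type, with exclusive membership.

    A probe is specific to type ``t`` iff it passes the DMP criteria in
    ``t``'s one-vs-rest contrast and in no other type's contrast. Returns
    the per-type specific probe lists and the full per-type DMP tables.
    """
    srows = samples.set_index("sample_id").loc[list(pooled_tumors.sample_ids)]
    if (srows["tissue"] != "TP").any():
        raise ValidationError("pooled_tumors must contain tumor (TP) samples only")
    types = sorted(srows["cancer_type"].unique())
    if len(types) < 3:
        raise ValidationError("need >= 3 tumor types for one-vs-all contrasts")
    tables: dict[str, pd.DataFrame] = {}
    dmp_sets: dict[str, set[str]] = {}
    for t in types:
        labels = (srows["cancer_type"] == t).to_numpy()
        if labels.sum() < 2 or (~labels).sum() < 2:
            raise ValidationError(f"type {t!r} needs >= 2 samples on each side")
        rec = dmp_pipeline(pooled_tumors, labels, thresholds)
        tables[t] = rec
        dmp_sets[t] = set(rec.loc[rec["is_dmp"], "probe_id"])
    specific: dict[str, list[str]] = {}
    for t in types:
        others = set().union(*(dmp_sets[u] for u in types if u != t))
        specific[t] = sorted(dmp_sets[t] - others)
    return specific, tables


def relieff_scores(
    X: pd.DataFrame | np.ndarray,
    y,
    k: int = 10,
    sampled: int | str = "all",
    seed: int = 0,
) -> ReliefScores:
    """Multiclass ReliefF feature weights.

    For each (sampled) instance the k nearest same-class hits and, per
    other class c, the k nearest misses are found under Manhattan distance
    on range-scaled features; each feature's weight accumulates the
    prior-weighted mean miss difference minus the mean hit difference.
    Ties in the neighbor search break deterministically by instance index.
    """
    feature_ids = (list(X.columns) if isinstance(X, pd.DataFrame)
                   else [f"f{i}" for i in range(np.asarray(X).shape[1])])
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = Xv.shape
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValidationError("every class needs >= 2 members for ReliefF")
    k_eff = int(k)
    if (counts - 1 < k_eff).any():
        k_new = int(counts.min() - 1)
        warnings.warn(f"truncating ReliefF neighbors from {k_eff} to {k_new}",
                      stacklevel=2)
        k_eff = k_new

    rng_range = Xv.max(axis=0) - Xv.min(axis=0)
    scale = np.where(rng_range > 0, rng_range, 1.0)
    Xs = (Xv - Xv.min(axis=0)) / scale
    D = cdist(Xs, Xs, metric="cityblock")

    prior = {c: cnt / n for c, cnt in zip(classes, counts)}
    if sampled == "all":
        instance_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        instance_idx = np.sort(rng.choice(n, size=min(int(sampled), n), replace=False))
    m = len(instance_idx)

    W = np.zeros(d)
    for i in instance_idx:
        drow = D[i]
        for c in classes:
            members = np.flatnonzero(y == c)
            if c == y[i]:
                members = members[members != i]
            # stable sort on distance; positional order = index tie-break
            nearest = members[np.argsort(drow[members], kind="stable")][:k_eff]
            mean_diff = np.abs(Xs[nearest] - Xs[i]).mean(axis=0)
            if c == y[i]:
                W -= mean_diff / m
            else:
                W += (prior[c] / (1.0 - prior[y[i]])) * mean_diff / m
    return ReliefScores(feature_ids=feature_ids, weights=W, k=k_eff,
                        n_sampled="all" if sampled == "all" else m)


def relevance_filter(scores: ReliefScores, keep_fraction: float = 0.03) -> list[str]:
    """Top ceil(keep_fraction * n) features by weight; ties by feature id."""
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must be in (0, 1]")
    n_keep = math.ceil(keep_fraction * len(scores.feature_ids))
    order = sorted(zip(scores.feature_ids, scores.weights),
                   key=lambda t: (-t[1], t[0]))
    return [fid for fid, _ in order[:n_keep]]


def redundancy_filter(
    X: pd.DataFrame,
    scores: ReliefScores,
    n_clusters: int = 10,
    seed: int = 0,
) -> tuple[list[FeatureCluster], list[str]]:
    """K-means redundancy filter over standardized feature profiles.

    Features are the clustered points (samples are the dimensions). Each
    cluster contributes its centroid-closest member and its top-Relief
    member (distinct; next-best Relief if they coincide); singleton
    clusters contribute their only member once.
    """
    feature_ids = list(X.columns)
    if n_clusters > len(feature_ids) // 2:
        raise ValidationError("n_clusters must be <= n_features / 2")
    weights = scores.as_series()
    profiles = X.to_numpy(float).T  # (features, samples)
    sd = profiles.std(axis=1, keepdims=True)
    profiles = (profiles - profiles.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(profiles)

    clusters: list[FeatureCluster] = []
    selected: list[str] = []
    for cid in range(n_clusters):
        members = [feature_ids[i] for i in np.flatnonzero(labels == cid)]
        member_idx = np.flatnonzero(labels == cid)
        dists = np.linalg.norm(profiles[member_idx] - km.cluster_centers_[cid], axis=1)
        by_dist = sorted(zip(dists, members))  # id string is the tie-break
        centroid_pick = by_dist[0][1]
        by_relief = sorted(members, key=lambda f: (-weights[f], f))
        relief_pick: str | None = None
        if len(members) > 1:
            relief_pick = by_relief[0]
            if relief_pick == centroid_pick:
                relief_pick = by_relief[1]
        clusters.append(FeatureCluster(
            cluster_id=cid,
            member_feature_ids=members,
            centroid=km.cluster_centers_[cid],
            selected_centroid_feature=centroid_pick,
            selected_top_relief_feature=relief_pick,
        ))
        selected.append(centroid_pick)
        if relief_pick is not None:
            selected.append(relief_pick)
    return clusters, selected


def plsda_fit(X: pd.DataFrame, y, n_components: int = 3,
              max_iter: int = 5000) -> PlsdaModel:
    """Fit PLS-DA: PLS2 (NIPALS) regression of one-hot labels on X.

    The inner power iteration converges linearly with the gap between the
    leading latent directions; near-tied directions need many iterations at
    the strict 1e-10 tolerance, hence the generous default cap.
    """
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    n, d = X.shape
    bound = min(d, len(classes) - 1 if len(classes) > 1 else 1, n - 1)
    if not 1 <= n_components <= max(bound, 1):
        raise ValidationError(
            f"n_components must be in [1, {bound}] for this problem")
    Y = np.column_stack([(y == c).astype(float) for c in classes])
    pls = PLSRegression(n_components=n_components, scale=True,
                        max_iter=max_iter, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            pls.fit(X.to_numpy(float), Y)
        except ConvergenceWarning as w:  # pragma: no cover - rare numeric edge
            raise ValidationError(f"PLS component failed to converge: {w}") from None
    return PlsdaModel(predictor_ids=list(X.columns), classes=classes,
                      n_components=n_components, pls=pls,
                      x_loadings=pls.x_loadings_)


def _cv_class_scores(
    X: pd.DataFrame, y, n_components: int, folds: int, seed: int
) -> tuple[np.ndarray, list[str]]:
    """Pooled held-out PLS-DA class scores under stratified k-fold CV."""
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    fold = stratified_kfold(y, k=folds, seed=seed)
    for attempt in (1, 2):
        ok = all(len(set(y[fold == f])) == len(classes) for f in np.unique(fold))
        if ok:
            break
        if attempt == 1:
            fold = stratified_kfold(y, k=folds, seed=seed + 1)
        else:
            raise ValidationError("a CV fold is missing a class even after re-seeding")
    scores = np.empty((len(y), len(classes)))
    for f in np.unique(fold):
        train, test = fold != f, fold == f
        mdl = plsda_fit(X.iloc[train], y[train], n_components=n_components)
        scores[test] = mdl.predict_scores(X.iloc[test])
    return scores, classes


def search_plsda_panels(
    X: pd.DataFrame,
    y,
    candidates: list[str],
    panel_size: int = 6,
    folds: int = 10,
    seed: int = 0,
    n_components: int = 3,
    subsample_combos: int | None = None,
) -> dict:
    """Exhaustive PLS-DA search over fixed-size probe combinations.

    Every C(len(candidates), panel_size) subset is scored by stratified
    k-fold CV; per class, the subset with the maximal one-vs-rest AUC of
    that class's continuous score wins (ties: smaller mean candidate
    index). The exact total combination count is always reported, even
    when ``subsample_combos`` restricts the evaluated subset.
    """
    candidates = list(candidates)
    if panel_size > len(candidates):
        raise ValidationError("panel_size exceeds the candidate count")
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    # a component count equal to the panel width is rank-degenerate under
    # NIPALS; keep at least one dimension of slack, and respect the
    # classes-1 bound
    if panel_size > 1:
        n_components = min(n_components, panel_size - 1)
    n_components = max(1, min(n_components, len(classes) - 1))
    total = math.comb(len(candidates), panel_size)
    combos = list(itertools.combinations(range(len(candidates)), panel_size))
    if subsample_combos is not None and subsample_combos < len(combos):
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(combos), size=subsample_combos, replace=False))
        combos = [combos[i] for i in keep]

    best: dict[str, dict] = {c: {"auc": -np.inf, "panel": None, "mean_index": np.inf}
                             for c in classes}
    for combo in combos:
        panel = [candidates[i] for i in combo]
        scores, cls = _cv_class_scores(X[panel], y, n_components, folds, seed)
        mean_index = float(np.mean(combo))
        for ci, c in enumerate(cls):
            auc = rank_auc(scores[:, ci], y == c)
            cur = best[c]
            if auc > cur["auc"] or (auc == cur["auc"] and mean_index < cur["mean_index"]):
                best[c] = {"auc": auc, "panel": tuple(panel), "mean_index": mean_index}
    table = pd.DataFrame([
        {"cancer_type": c, "panel": best[c]["panel"], "cv_auc": best[c]["auc"]}
        for c in classes
    ])
    return {
        "total_combinations": total,
        "n_evaluated": len(combos),
        "best_panels": table,
    }


def build_integrated_model(
    best_panels: pd.DataFrame,
    X: pd.DataFrame,
    y,
    n_components: int = 3,
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Union the per-type winning panels and fit one multiclass PLS-DA.

    Reports per-type one-vs-rest CV AUC plus sensitivity/specificity of the
    hard (argmax) class assignments.
    """
    if best_panels.empty:
        raise ValidationError("need at least one per-type panel")
    union: list[str] = []
    for panel in best_panels["panel"]:
        for p in panel:
            if p not in union:
                union.append(p)
    y = np.asarray(y, dtype=object)
    n_components = max(1, min(n_components, len(set(y)) - 1, len(union) - 1))
    model = plsda_fit(X[union], y, n_components=n_components)
    scores, classes = _cv_class_scores(X[union], y, n_components, folds, seed)
    pred = np.asarray(classes, dtype=object)[np.argmax(scores, axis=1)]
    rows = []
    for ci, c in enumerate(classes):
        truth = y == c
        rows.append({
            "cancer_type": c,
            "cv_auc": rank_auc(scores[:, ci], truth),
            "sensitivity": float((pred[truth] == c).mean()),
            "specificity": float((pred[~truth] != c).mean()),
        })
    return {
        "predictors": union,
        "model": model,
        "per_type_metrics": pd.DataFrame(rows),
    }
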