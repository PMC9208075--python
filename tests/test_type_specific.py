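import numpy as np
import pandas as pd
import pytest

from methpanel.datatypes import ValidationError
from methpanel.evaluation import rank_auc
from methpanel.type_specific import (
    build_integrated_model,
    call_type_specific_dmps,
    plsda_fit,
    redundancy_filter,
    relevance_filter,
    relieff_scores,
    search_plsda_panels,
)
from methpanel.simulate import SimulationConfig, generate_cohort


def relieff_reference(X, y, k):
    """Independent brute-force ReliefF: explicit loops, all-pairs distances."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape
    rng_range = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_range > 0, rng_range, 1.0)
    Xs = (X - X.min(axis=0)) / scale
    classes = sorted(set(y.tolist()))
    prior = {c: (y == c).mean() for c in classes}
    W = np.zeros(d)
    for i in range(n):
        dists = [(sum(abs(Xs[i] - Xs[j])), j) for j in range(n)]
        for c in classes:
            cand = [(dist, j) for dist, j in dists if y[j] == c and j != i]
            cand.sort()
            neigh = [j for _, j in cand[:k]]
            for f in range(d):
                mean_diff = np.mean([abs(Xs[i, f] - Xs[j, f]) for j in neigh])
                if c == y[i]:
                    W[f] -= mean_diff / n
                else:
                    W[f] += prior[c] / (1 - prior[y[i]]) * mean_diff / n
    return W


@pytest.fixture(scope="module")
def typed_cohort():
    cfg = SimulationConfig(n_probes=1200, n_types=3, n_tumor=40, n_normal=4,
                           n_pan_dmps=4, n_type_dmps=3, n_regions=0,
                           n_blocks=0, noise_sd=0.08, seed=31)
    betas, samples, truth, _ = generate_cohort(cfg)
    tp = (samples["tissue"] == "TP").to_numpy()
    tumors = betas.select_samples(tp)
    specific, tables = call_type_specific_dmps(tumors, samples)
    return truth, specific, tables


class TestTypeSpecificDmps:

    def test_planted_specific_probes_assigned_to_their_type(self, typed_cohort):
        truth, specific, _ = typed_cohort
        for t, planted in truth.specific_dmp_ids.items():
            assert set(planted) <= set(specific[t])

    def test_pan_probes_assigned_to_no_type(self, typed_cohort):
        # pan probes shift every tumor type equally: no one-vs-rest contrast
        truth, specific, _ = typed_cohort
        assigned = set().union(*specific.values())
        assert not (set(truth.pan_dmp_ids) & assigned)

    def test_exclusivity(self, typed_cohort):
        _, specific, _ = typed_cohort
        lists = list(specific.values())
        for i, a in enumerate(lists):
            for b in lists[i + 1:]:
                assert not (set(a) & set(b))

    def test_tumor_only_input_enforced(self, small_cohort):
        with pytest.raises(ValidationError, match="TP"):
            call_type_specific_dmps(small_cohort["betas"], small_cohort["samples"])


class TestReliefF:
    def test_matches_bruteforce_reference(self):
        rng = np.random.default_rng(0)
        for trial in range(3):
            n, d, k = 60, 8, 5
            y = rng.integers(0, 3, n)
            X = rng.random((n, d)) + 0.3 * y[:, None] * (np.arange(d) < 3)
            got = relieff_scores(X, y, k=k).weights
            want = relieff_reference(X, y, k)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.full(40, 0.7), rng.random(40)])
        y = np.r_[np.zeros(20), np.ones(20)]
        w = relieff_scores(X, y, k=5).weights
        assert w[0] == 0.0

    def test_duplicate_feature_gets_identical_weight(self):
        rng = np.random.default_rng(2)
        base = rng.random(40)
        X = np.column_stack([base, rng.random(40), base])
        y = np.r_[np.zeros(20), np.ones(20)]
        w = relieff_scores(X, y, k=5).weights
        assert w[0] == pytest.approx(w[2], abs=1e-15)

    def test_separating_feature_beats_noise_in_every_seed(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.r_[np.zeros(20), np.ones(20)]
            X = np.column_stack([y + rng.normal(0, 0.05, 40), rng.random(40)])
            w = relieff_scores(X, y, k=5).weights
            assert w[0] > w[1]

    def test_feature_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 5))
        y = rng.integers(0, 2, 30)
        w = relieff_scores(pd.DataFrame(X, columns=list("abcde")), y, k=4)
        w_rev = relieff_scores(pd.DataFrame(X[:, ::-1], columns=list("edcba")), y, k=4)
        np.testing.assert_allclose(w.weights, w_rev.weights[::-1], atol=1e-15)

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).random((5, 2))
        with pytest.raises(ValidationError):
            relieff_scores(X, np.array([0, 0, 0, 0, 1]), k=2)


class TestRelevanceFilter:
    def test_ceiling_rule_and_identity(self):
        rng = np.random.default_rng(0)
        scores = relieff_scores(rng.random((30, 100)),
                                rng.integers(0, 2, 30), k=3)
        assert len(relevance_filter(scores, 0.03)) == 3
        assert len(relevance_filter(scores, 1.0)) == 100

    def test_ties_break_by_feature_id(self):
        from methpanel.type_specific import ReliefScores
        s = ReliefScores(["fd", "fb", "fa", "fc"],
                         np.array([0.1, 0.5, 0.5, 0.6]), k=3)
        assert relevance_filter(s, 0.5) == ["fc", "fa"]

    def test_informative_features_survive(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, d = 60, 40
            y = np.r_[np.zeros(30), np.ones(30)]
            # methylation-like noise scale with a 0.3 beta shift
            X = np.clip(rng.normal(0.3, 0.1, (n, d)), 0, 1)
            X[:, :2] += 0.3 * y[:, None]  # two informative features
            scores = relieff_scores(X, y, k=8)
            kept = relevance_filter(scores, keep_fraction=0.1)  # keeps 4
            if {"f0", "f1"} <= set(kept):
                hits += 1
        assert hits >= 9


class TestRedundancyFilter:
    @staticmethod
    def clustered_features(n_clusters=10, per_cluster=3, n_samples=40, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, 3, (n_clusters, n_samples))
        cols, names = [], []
        for c in range(n_clusters):
            for j in range(per_cluster):
                cols.append(centers[c] + rng.normal(0, 0.05, n_samples))
                names.append(f"c{c}f{j}")
        X = pd.DataFrame(np.array(cols).T, columns=names)
        from methpanel.type_specific import ReliefScores
        weights = rng.random(len(names))
        return X, ReliefScores(names, weights, k=5)

    def test_two_picks_per_cluster(self):
        X, scores = self.clustered_features()
        clusters, selected = redundancy_filter(X, scores, n_clusters=10, seed=0)
        assert len(selected) == 20
        assert len(set(selected)) == 20
        for cl in clusters:
            assert cl.selected_centroid_feature in cl.member_feature_ids
            assert cl.selected_top_relief_feature != cl.selected_centroid_feature

    def test_single_cluster_on_five_features(self):
        X, scores = self.clustered_features(n_clusters=1, per_cluster=5)
        _, selected = redundancy_filter(X, scores, n_clusters=1, seed=0)
        assert len(selected) == 2

    def test_output_bounded_by_two_per_cluster(self):
        for seed in range(3):
            X, scores = self.clustered_features(n_clusters=4, per_cluster=2,
                                                seed=seed)
            _, selected = redundancy_filter(X, scores, n_clusters=4, seed=seed)
            assert len(selected) <= 8

    def test_too_many_clusters_rejected(self):
        X, scores = self.clustered_features(n_clusters=2, per_cluster=2)
        with pytest.raises(ValidationError):
            redundancy_filter(X, scores, n_clusters=3)


class TestPlsda:
    def test_separable_two_class_one_component(self):
        rng = np.random.default_rng(0)
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        X = pd.DataFrame({
            "f1": np.r_[rng.normal(0, 0.1, 20), rng.normal(2, 0.1, 20)],
            "f2": rng.normal(0, 1, 40),
        })
        mdl = plsda_fit(X, y, n_components=1)
        assert (mdl.predict(X) == y).all()

    def test_first_direction_aligns_with_class_mean_difference(self):
        rng = np.random.default_rng(1)
        y = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        X = rng.normal(0, 1, (60, 5))
        X[30:] += np.array([1.0, 0.5, 0.0, -0.5, 0.2])
        Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        mdl = plsda_fit(Xdf, y, n_components=1)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        direction = Xs[y == "b"].mean(0) - Xs[y == "a"].mean(0)
        w = mdl.pls.x_weights_[:, 0]
        cos = abs(np.dot(w, direction)) / (
            np.linalg.norm(w) * np.linalg.norm(direction))
        assert cos > 1 - 1e-10

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(2)
        y = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15, dtype=object)
        X = pd.DataFrame(rng.normal(0, 1, (45, 6)),
                         columns=[f"f{i}" for i in range(6)])
        X.iloc[15:30] += 1.0
        X.iloc[30:] -= 1.0
        scores_abc = plsda_fit(X, y, 2).predict_scores(X)
        relabel = {"a": "c", "b": "a", "c": "b"}
        y2 = np.array([relabel[v] for v in y], dtype=object)
        mdl2 = plsda_fit(X, y2, 2)
        scores_perm = mdl2.predict_scores(X)
        # column for class c under the new labelling matches the original
        for orig, new in relabel.items():
            oi = ["a", "b", "c"].index(orig)
            ni = mdl2.classes.index(new)
            np.testing.assert_allclose(scores_perm[:, ni], scores_abc[:, oi],
                                       atol=1e-6)

    def test_invalid_component_counts(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        y = np.array(["x"] * 10 + ["y"] * 10, dtype=object)
        with pytest.raises(ValidationError):
            plsda_fit(X, y, n_components=0)
        with pytest.raises(ValidationError):
            plsda_fit(X, y, n_components=5)


class TestPanelSearch:
    def _multiclass(self, seed, n_per=20, n_classes=3, informative=2, d=8):
        rng = np.random.default_rng(seed)
        y = np.repeat([f"T{i}" for i in range(n_classes)], n_per).astype(object)
        X = rng.normal(0.5, 0.15, (n_per * n_classes, d))
        for c in range(n_classes):
            for j in range(informative):
                X[y == f"T{c}", (c * informative + j) % d] += 0.4
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(d)]), y

    def test_small_enumeration_count(self):
        X, y = self._multiclass(0, d=4)
        res = search_plsda_panels(X, y, [f"f{i}" for i in range(4)],
                                  panel_size=2, folds=4, n_components=2)
        assert res["total_combinations"] == 6
        assert res["n_evaluated"] == 6

    def test_full_scale_count_reported_under_subsampling(self):
        X, y = self._multiclass(1, n_per=10, d=20)
        res = search_plsda_panels(X, y, [f"f{i}" for i in range(20)],
                                  panel_size=6, folds=3, n_components=2,
                                  subsample_combos=5)
        assert res["total_combinations"] == 38_760
        assert res["n_evaluated"] == 5

    def test_planted_probes_dominate_their_class_panel(self):
        hits = 0
        for seed in range(5):
            X, y = self._multiclass(seed + 10, n_per=25, n_classes=3,
                                    informative=2, d=8)
            res = search_plsda_panels(X, y, [f"f{i}" for i in range(8)],
                                      panel_size=3, folds=5, seed=seed,
                                      n_components=2)
            best = res["best_panels"].set_index("cancer_type")
            panel = set(best.loc["T0", "panel"])
            if {"f0", "f1"} <= panel:
                hits += 1
        assert hits >= 4


class TestIntegratedModel:
    def test_union_sizes(self):
        X = pd.DataFrame(np.random.default_rng(0).random((30, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10, dtype=object)
        same = pd.DataFrame({"cancer_type": list("abc"),
                             "panel": [("f0", "f1")] * 3, "cv_auc": [0.9] * 3})
        out = build_integrated_model(same, X, y, n_components=2, folds=3)
        assert out["predictors"] == ["f0", "f1"]
        disjoint = pd.DataFrame({
            "cancer_type": list("abc"),
            "panel": [("f0", "f1"), ("f2", "f3"), ("f4", "f5")],
            "cv_auc": [0.9] * 3,
        })
        out = build_integrated_model(disjoint, X, y, n_components=2, folds=3)
        assert len(out["predictors"]) == 6

    def test_integrated_auc_not_worse_than_panels(self):
        gaps = []
        for seed in range(3):
            X, y = TestPanelSearch()._multiclass(seed + 50, n_per=25,
                                                 n_classes=3, d=9,
                                                 informative=3)
            cands = [f"f{i}" for i in range(9)]
            res = search_plsda_panels(X, y, cands, panel_size=3, folds=5,
                                      seed=seed, n_components=2)
            integ = build_integrated_model(res["best_panels"], X, y,
                                           n_components=2, folds=5, seed=seed)
            merged = res["best_panels"].merge(integ["per_type_metrics"],
                                              on="cancer_type")
            gaps.append((merged["cv_auc_y"] - merged["cv_auc_x"]).min())
        assert min(gaps) >= -0.05
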