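"""Pan-cancer combinatorial logistic panel search.

Candidate probes are DMPs shared by every cancer type (with |log2 FC| >= 2
in each). All 1..k_max-probe combinations are scored exhaustively with a
batched Newton logistic screen (apparent AUC + AIC); the leading
combinations then receive the full treatment — cross-validated AUC,
covariate testing, stratified bootstrap SDs — and the final panel is the
lexicographic winner on (AUC, misclassification, bootstrap SD, AIC).
Stage-stratified performance and the methylation x stage interaction
likelihood-ratio test complete the workflow.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .datatypes import BetaMatrix, PanelModel, ValidationError
from .evaluation import (
    binary_metrics,
    rank_auc,
    stratified_bootstrap_indices,
    stratified_kfold,
)

STAGE_NUMBER = {"I": 1, "II": 2, "III": 3, "IV": 4}


def intersect_pan_dmps(
    per_type_dmps: dict[str, pd.DataFrame],
    fc_threshold: float = 2.0,
    require_concordant: bool = False,
) -> pd.DataFrame:
    """Probes that are DMPs with |log2 FC| >= fc_threshold in every type.

    Returns a table of candidate probes with a ``concordant_hyper`` flag
    (hypermethylated in every type); with ``require_concordant`` the
    candidate list is restricted to that set.
    """
    if len(per_type_dmps) < 2:
        raise ValidationError("need >= 2 types to intersect")
    passing: list[set[str]] = []
    hyper: list[set[str]] = []
    for dmps in per_type_dmps.values():
        ok = dmps["is_dmp"].to_numpy(bool) & (
            np.abs(dmps["log2_fc"].to_numpy(float)) >= fc_threshold)
        ids = dmps["probe_id"].to_numpy(object)
        passing.append(set(ids[ok]))
        hyper.append(set(ids[ok & (dmps["direction"].to_numpy(object) == "hyper")]))
    common = sorted(set.intersection(*passing))
    if not common:
        warnings.warn("no probe passes the DMP criteria in every type", stacklevel=2)
    all_hyper = set.intersection(*hyper) if common else set()
    out = pd.DataFrame({
        "probe_id": common,
        "concordant_hyper": [p in all_hyper for p in common],
    })
    if require_concordant:
        out = out[out["concordant_hyper"]].reset_index(drop=True)
    return out


def panel_count(n: int, k_max: int = 4, k_only: int | None = None) -> int:
    """Number of candidate panels: C(n, k) or the sum over 1..k_max."""
    if k_only is not None:
        return math.comb(n, k_only)
    return sum(math.comb(n, k) for k in range(1, k_max + 1))


def enumerate_panels(candidates, k_max: int = 4):
    """Yield all size-1..k_max probe combinations in deterministic order."""
    candidates = list(candidates)
    if k_max > len(candidates):
        raise ValidationError("k_max exceeds the candidate count")
    for k in range(1, k_max + 1):
        yield from itertools.combinations(candidates, k)


def _design(m: BetaMatrix, probes, samples: pd.DataFrame,
            covariates=()) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X with intercept, y, column names) aligned to the matrix samples."""
    srows = samples.set_index("sample_id").loc[list(m.sample_ids)]
    y = (srows["tissue"] == "TP").to_numpy().astype(float)
    sub = m.select_probes(list(probes))
    cols = [np.ones(m.n_samples)]
    names = ["intercept"] + list(probes)
    cols.extend(sub.values)
    for cov in covariates:
        if cov == "age":
            age = srows["age"].to_numpy(float)
            age = np.where(np.isfinite(age), age, np.nanmean(age))
            cols.append((age - age.mean()) / (age.std() or 1.0))
            names.append("age")
        elif cov == "stage":
            cols.append(_stage_numeric(srows))
            names.append("stage")
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
    return np.column_stack(cols), y, names


def _stage_numeric(srows: pd.DataFrame) -> np.ndarray:
    """Centered numeric stage for tumors; normals sit at the 0 reference.

    Coding normals as their own categorical stratum would let stage dummies
    perfectly separate tissue type, so the tumor stages enter as a centered
    score and normals at 0.
    """
    vals = np.zeros(len(srows))
    is_tp = (srows["tissue"] == "TP").to_numpy()
    stage_num = np.array([STAGE_NUMBER.get(s, np.nan) for s in srows["stage"]])
    tumor_stages = stage_num[is_tp]
    if np.isnan(tumor_stages).all():
        raise ValidationError("stage entirely missing for tumors")
    center = np.nanmean(tumor_stages)
    filled = np.where(np.isnan(stage_num), center, stage_num)
    vals[is_tp] = filled[is_tp] - center
    return vals


def _irls_fit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8,
              max_iter: int = 50, tol: float = 1e-9):
    """Newton-IRLS logistic fit with a tiny ridge; returns (beta, llf, ok)."""
    n, p = X.shape
    beta = np.zeros(p)
    ok = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.max(np.abs(step)) < tol:
            ok = True
            break
        if np.max(np.abs(beta)) > 60:  # separation: likelihood is flat out here
            break
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    llf = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
    return beta, llf, ok


def screen_panels(
    candidates,
    m: BetaMatrix,
    samples: pd.DataFrame,
    k_max: int = 4,
    ridge: float = 1e-6,
    max_iter: int = 30,
    chunk: int = 1024,
) -> pd.DataFrame:
    """Batched Newton screen of every 1..k_max combination.

    Returns one row per combination with its apparent (full-data) AUC and
    AIC, in deterministic enumeration order. This is the fast first stage of
    the exhaustive search; the leaders are re-evaluated with cross-validated
    metrics afterwards.
    """
    candidates = list(candidates)
    X_all, y, _ = _design(m, candidates, samples)
    X_feat = X_all[:, 1:]  # candidate columns only
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("outcome must contain both classes")
    rows = []
    for k in range(1, k_max + 1):
        combos = np.array(list(itertools.combinations(range(len(candidates)), k)),
                          dtype=int)
        for lo in range(0, len(combos), chunk):
            idx = combos[lo: lo + chunk]
            C = len(idx)
            Xc = np.empty((C, n, k + 1))
            Xc[:, :, 0] = 1.0
            Xc[:, :, 1:] = X_feat[:, idx].transpose(1, 0, 2)
            beta = np.zeros((C, k + 1))
            eye = ridge * np.eye(k + 1)
            for _ in range(max_iter):
                eta = np.clip(np.einsum("cnk,ck->cn", Xc, beta), -35, 35)
                mu = 1.0 / (1.0 + np.exp(-eta))
                w = np.maximum(mu * (1 - mu), 1e-12)
                grad = np.einsum("cnk,cn->ck", Xc, y[None, :] - mu) - ridge * beta
                H = np.einsum("cnk,cn,cnl->ckl", Xc, w, Xc) + eye
                step = np.linalg.solve(H, grad[..., None])[..., 0]
                beta += step
                np.clip(beta, -60, 60, out=beta)
                if np.max(np.abs(step)) < 1e-7:
                    break
            eta = np.clip(np.einsum("cnk,ck->cn", Xc, beta), -35, 35)
            mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
            llf = (y[None, :] * np.log(mu) + (1 - y)[None, :] * np.log(1 - mu)).sum(axis=1)
            aic = 2 * (k + 1) - 2 * llf
            ranks = np.argsort(np.argsort(mu, axis=1, kind="stable"),
                               axis=1, kind="stable") + 1.0
            auc = ((ranks * y[None, :]).sum(axis=1) - n_pos * (n_pos + 1) / 2) / (
                n_pos * n_neg)
            for c in range(C):
                rows.append({
                    "combo": tuple(candidates[j] for j in idx[c]),
                    "k": k,
                    "auc_apparent": float(auc[c]),
                    "aic": float(aic[c]),
                })
    return pd.DataFrame(rows)


def fit_logistic_panel(
    combo,
    m: BetaMatrix,
    samples: pd.DataFrame,
    covariates=(),
    folds: int = 10,
    seed: int = 0,
    cutoff: float = 0.5,
    covariate_alpha: float = 0.05,
) -> PanelModel:
    """Maximum-likelihood logistic fit of one panel with CV evaluation.

    Non-significant covariates (Wald p > ``covariate_alpha``) are dropped
    and the model refit. Perfect separation triggers an L2-ridge fallback
    (penalty 1e-4) and sets ``separation_flag``. CV metrics pool the
    held-out scores of a stratified k-fold split.
    """
    import statsmodels.api as sm_api

    combo = tuple(combo)
    kept_cov = tuple(covariates)
    separation = False
    while True:
        X, y, names = _design(m, combo, samples, kept_cov)
        if y.all() or not y.any():
            raise ValidationError("outcome must contain both classes")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm_api.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False)) and (
                np.max(np.abs(res.params)) < 60)
        except Exception:
            res, converged = None, False
        if not converged:
            separation = True
            break
        if kept_cov:
            pvals = dict(zip(names, res.pvalues))
            drop = [c for c in kept_cov if pvals.get(c, 1.0) > covariate_alpha]
            if drop:
                kept_cov = tuple(c for c in kept_cov if c not in drop)
                continue
        break

    if separation:
        X, y, names = _design(m, combo, samples, kept_cov)
        ridge_fit = LogisticRegression(C=1.0 / 1e-4, max_iter=2000)
        ridge_fit.fit(X[:, 1:], y)
        coefs = np.r_[ridge_fit.intercept_, ridge_fit.coef_.ravel()]
        mu = np.clip(ridge_fit.predict_proba(X[:, 1:])[:, 1], 1e-12, 1 - 1e-12)
        llf = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))
        aic = 2 * X.shape[1] - 2 * llf
    else:
        coefs = np.asarray(res.params)
        aic = float(res.aic)

    fold = stratified_kfold(y, k=folds, seed=seed)
    scores = np.empty(len(y))
    for f in np.unique(fold):
        train, test = fold != f, fold == f
        clf = LogisticRegression(C=1e6, max_iter=2000)
        clf.fit(X[train][:, 1:], y[train])
        scores[test] = clf.predict_proba(X[test][:, 1:])[:, 1]
    metrics = binary_metrics(scores, y, cutoff)
    return PanelModel(
        predictor_probe_ids=combo,
        coefficients=dict(zip(names, (float(c) for c in coefs))),
        aic=aic,
        auc_cv=rank_auc(scores, y),
        misclass=metrics["misclassification"],
        sens=metrics["sensitivity"],
        spec=metrics["specificity"],
        covariates=kept_cov,
        separation_flag=separation,
        cutoff=cutoff,
    )


def predict_panel(model: PanelModel, m: BetaMatrix, samples: pd.DataFrame) -> np.ndarray:
    """Predicted tumor probability per sample under the fitted panel."""
    X, _, names = _design(m, model.predictor_probe_ids, samples, model.covariates)
    beta = np.array([model.coefficients[n] for n in names])
    return 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -35, 35)))


def evaluate_bootstrap(
    model: PanelModel,
    m: BetaMatrix,
    samples: pd.DataFrame,
    B: int = 100,
    seed: int = 0,
) -> PanelModel:
    """Stratified bootstrap refits; records SDs of AUC and misclassification."""
    if B < 2:
        raise ValidationError("need B >= 2 bootstrap resamples")
    X, y, _ = _design(m, model.predictor_probe_ids, samples, model.covariates)
    rng = np.random.default_rng(seed)
    aucs, miscls = [], []
    for _ in range(B):
        idx = stratified_bootstrap_indices(y, rng)
        beta, _, _ = _irls_fit(X[idx], y[idx], ridge=1e-6)
        mu = 1.0 / (1.0 + np.exp(-np.clip(X[idx] @ beta, -35, 35)))
        aucs.append(rank_auc(mu, y[idx]))
        miscls.append(binary_metrics(mu, y[idx], model.cutoff)["misclassification"])
    return replace(model,
                   bootstrap_sd_auc=float(np.std(aucs, ddof=1)),
                   bootstrap_sd_misclass=float(np.std(miscls, ddof=1)))


def select_final_panel(models: list[PanelModel]) -> PanelModel:
    """Lexicographic winner: max AUC, min misclassification, min bootstrap
    SD(AUC), min AIC, then probe-id order as the deterministic tie-break."""
    if not models:
        raise ValidationError("no models to select from")
    inf = float("inf")
    return min(models, key=lambda mdl: (
        -mdl.auc_cv,
        mdl.misclass,
        mdl.bootstrap_sd_auc if mdl.bootstrap_sd_auc is not None else inf,
        mdl.aic,
        mdl.predictor_probe_ids,
    ))


def interaction_lrt(
    final: PanelModel, m: BetaMatrix, samples: pd.DataFrame
) -> dict:
    """Likelihood-ratio test of methylation x stage interaction terms.

    Compares (methylation + stage + methylation:stage) against
    (methylation + stage); the joint statistic is chi-square with one df per
    interaction term, and per-probe single-df tests are reported alongside.
    """
    probes = final.predictor_probe_ids
    X, y, _ = _design(m, probes, samples, ())
    srows = samples.set_index("sample_id").loc[list(m.sample_ids)]
    stage = _stage_numeric(srows)
    meth = X[:, 1:]
    X_red = np.column_stack([X, stage])
    _, llf_red, _ = _irls_fit(X_red, y)
    X_full = np.column_stack([X_red, meth * stage[:, None]])
    _, llf_full, _ = _irls_fit(X_full, y)
    df = len(probes)
    stat = max(0.0, 2.0 * (llf_full - llf_red))
    per_term = {}
    for j, pid in enumerate(probes):
        Xj = np.column_stack([X_red, meth[:, j] * stage])
        _, llf_j, _ = _irls_fit(Xj, y)
        per_term[pid] = float(stats.chi2.sf(max(0.0, 2.0 * (llf_j - llf_red)), 1))
    return {
        "joint_stat": float(stat),
        "joint_df": df,
        "joint_p": float(stats.chi2.sf(stat, df)),
        "per_term_p": per_term,
    }


def evaluate_by_stage(
    final: PanelModel, m: BetaMatrix, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-stage metrics: tumors of each stage vs all normals, at the
    discovery cutoff."""
    scores = predict_panel(final, m, samples)
    srows = samples.set_index("sample_id").loc[list(m.sample_ids)]
    is_tp = (srows["tissue"] == "TP").to_numpy()
    stage_arr = srows["stage"].to_numpy(object)
    rows = []
    for stage in ("I", "II", "III", "IV"):
        sel = (~is_tp) | (is_tp & (stage_arr == stage))
        y = is_tp[sel].astype(float)
        if y.sum() == 0 or y.all():
            warnings.warn(f"stage {stage}: empty stratum, metrics absent",
                          stacklevel=2)
            continue
        mets = binary_metrics(scores[sel], y, final.cutoff)
        rows.append({
            "stage": stage,
            "n_tumors": int(y.sum()),
            "n_normals": int((1 - y).sum()),
            "auc": rank_auc(scores[sel], y),
            "sensitivity": mets["sensitivity"],
            "specificity": mets["specificity"],
        })
    return pd.DataFrame(rows)


def search_pan_panels(
    candidates,
    m: BetaMatrix,
    samples: pd.DataFrame,
    k_max: int = 4,
    top_n: int = 50,
    folds: int = 10,
    bootstrap_B: int = 100,
    seed: int = 0,
    covariates=(),
) -> dict:
    """Exhaustive two-stage panel search.

    Every combination is scored by the batched screen; the ``top_n`` by
    apparent AUC (AIC tie-break) get cross-validated fits and bootstrap SDs,
    and the final model is the lexicographic winner among them.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("no candidate probes to search")
    screen = screen_panels(candidates, m, samples, k_max=k_max)
    screen = screen.sort_values(["auc_apparent", "aic"],
                                ascending=[False, True], kind="stable")
    top = screen.head(top_n)
    models = []
    for combo in top["combo"]:
        mdl = fit_logistic_panel(combo, m, samples, covariates=covariates,
                                 folds=folds, seed=seed)
        models.append(evaluate_bootstrap(mdl, m, samples, B=bootstrap_B, seed=seed))
    final = select_final_panel(models)
    return {
        "n_candidates": len(candidates),
        "total_combinations": panel_count(len(candidates), k_max),
        "combinations_by_k": {k: panel_count(len(candidates), k_only=k)
                              for k in range(1, k_max + 1)},
        "screen": screen,
        "models": models,
        "final": final,
    }
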