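"""Per-probe differential methylation, DMP calling and bump-hunting.

The per-probe statistic is the fold change of group-mean beta values,
formalized as ``log2((mean_A + eps) / (mean_B + eps))`` with a small floor
``eps`` for numerical stability, paired with a two-sided Welch t-test and
Benjamini-Hochberg FDR control. A probe is a DMP when |log2 FC| >= 2
(i.e. at least a 4-fold mean ratio) and adjusted p <= 0.01.

Regions (DMRs) and blocks (DMBs) are found with a from-scratch
bump-hunting scan: smooth the per-probe mean difference along each
chromosome with a centered running mean, threshold |smoothed| at a
genome-wide quantile, assemble same-sign runs with bounded inter-probe
gaps, and assign empirical p-values by label permutation (add-one
estimator). Blocks scan only open-sea probes and require larger widths,
matching the large hypomethylated blocks tumors show outside CpG islands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    BetaMatrix,
    FEATURE_CLASSES,
    ISLAND_RELATIONS,
    RegionCall,
    ValidationError,
)


@dataclass
class DmpThresholds:
    fc_threshold: float = 2.0  # minimal |log2 fold change| of group means
    p_threshold: float = 0.01  # maximal BH-adjusted p
    epsilon: float = 1e-3  # mean floor for fold-change stability

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or not (0 < self.p_threshold < 1) or self.epsilon <= 0:
            raise ValidationError("invalid DMP thresholds")


@dataclass
class BumpParams:
    """Tuning of the bump-hunting scan; defaults per kind via the
    :meth:`dmr` / :meth:`dmb` constructors (minimum widths 50 / 500 bp)."""

    kind: str = "DMR"
    min_width: int = 50
    min_probes: int = 5
    max_gap: int = 1_000
    smooth_window: int = 3
    cutoff_quantile: float = 0.99
    n_permutations: int = 100
    open_sea_only: bool = False

    def __post_init__(self) -> None:
        if self.min_width <= 0 or not (0.5 < self.cutoff_quantile < 1):
            raise ValidationError("invalid bump parameters")
        if self.n_permutations < 0:
            raise ValidationError("n_permutations must be >= 0")

    @classmethod
    def dmr(cls, **kw) -> "BumpParams":
        return cls(kind="DMR", **kw)

    @classmethod
    def dmb(cls, **kw) -> "BumpParams":
        kw.setdefault("min_width", 500)
        kw.setdefault("min_probes", 20)
        kw.setdefault("max_gap", 100_000)
        kw.setdefault("smooth_window", 25)
        kw.setdefault("open_sea_only", True)
        # blocks span large genome fractions: a 0.99 genome-wide cutoff can
        # never retain a >= 20-probe run once blocks cover > 1% of the
        # open-sea track, so the block preset thresholds lower
        kw.setdefault("cutoff_quantile", 0.95)
        return cls(kind="DMB", **kw)


def _group_values(m: BetaMatrix, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.shape != (m.n_samples,):
        raise ValidationError("labels must align with the matrix samples")
    if m.mask.any():
        raise ValidationError("probe_statistics requires fully observed probes "
                              "(run preprocessing first)")
    a, b = m.values[:, labels], m.values[:, ~labels]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples")
    return a, b


def probe_statistics(
    m: BetaMatrix, labels: np.ndarray, epsilon: float = 1e-3
) -> pd.DataFrame:
    """Group means, delta beta, log2 fold change and Welch-t p per probe.

    ``labels`` is a boolean sample vector, True = group A (tumor by
    convention). ``p_adj`` is left unset; apply :func:`adjust_bh` next.
    """
    a, b = _group_values(m, labels)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    delta = mean_a - mean_b
    log2_fc = np.log2((mean_a + epsilon) / (mean_b + epsilon))

    se2 = var_a / na + var_b / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
    p = np.where(
        se2 > 0,
        2.0 * stats.t.sf(np.abs(t), np.where(se2 > 0, df, 1.0)),
        np.where(delta == 0.0, 1.0, 0.0),  # degenerate zero-variance probes
    )
    return pd.DataFrame({
        "probe_id": m.probe_ids,
        "mean_beta_a": mean_a,
        "mean_beta_b": mean_b,
        "delta_beta": delta,
        "log2_fc": log2_fc,
        "p_raw": p,
        "p_adj": np.nan,
        "direction": np.where(delta > 0, "hyper", "hypo"),
        "is_dmp": False,
    })


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_dmps(records: pd.DataFrame, th: DmpThresholds | None = None) -> pd.DataFrame:
    """Set ``is_dmp`` from the fold-change and adjusted-p thresholds."""
    th = th or DmpThresholds()
    if records["p_adj"].isna().any():
        raise ValidationError("p_adj unset; run adjust_bh first")
    out = records.copy()
    out["is_dmp"] = (np.abs(out["log2_fc"]) >= th.fc_threshold) & (
        out["p_adj"] <= th.p_threshold)
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    return out


def dmp_pipeline(
    m: BetaMatrix, labels: np.ndarray, th: DmpThresholds | None = None
) -> pd.DataFrame:
    """probe_statistics -> adjust_bh -> call_dmps in one call."""
    th = th or DmpThresholds()
    rec = probe_statistics(m, labels, epsilon=th.epsilon)
    rec["p_adj"] = adjust_bh(rec["p_raw"].to_numpy())
    return call_dmps(rec, th)


def _running_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered running mean with shrinking windows at chromosome edges."""
    if w <= 1:
        return x.copy()
    h = w // 2
    c = np.r_[0.0, np.cumsum(x)]
    n = len(x)
    lo = np.maximum(0, np.arange(n) - h)
    hi = np.minimum(n, np.arange(n) + h + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def _chromosome_tracks(
    m: BetaMatrix, ann: pd.DataFrame, params: BumpParams
) -> list[dict]:
    """Per-chromosome probe order/positions (open-sea filtered for DMBs)."""
    ann_idx = pd.Index(ann["probe_id"])
    loc = ann_idx.get_indexer(m.probe_ids)
    if (loc < 0).any():
        raise ValidationError(f"probe {m.probe_ids[loc < 0][0]!r} absent from annotation")
    chrom = ann["chromosome"].to_numpy(object)[loc]
    pos = ann["position"].to_numpy(int)[loc]
    usable = np.ones(m.n_probes, dtype=bool)
    if params.open_sea_only:
        usable = (ann["island_relation"].to_numpy(object)[loc] == "OpenSea")
        if usable.sum() < params.min_probes:
            raise ValidationError("too few open-sea probes for a block scan")
    tracks = []
    for c in pd.unique(chrom):
        rows = np.flatnonzero((chrom == c) & usable)
        rows = rows[np.argsort(pos[rows], kind="stable")]
        if len(rows) >= params.smooth_window:
            tracks.append({"chrom": str(c), "rows": rows, "pos": pos[rows]})
    if not tracks:
        raise ValidationError("no chromosome carries enough probes to smooth")
    return tracks


def _smoothed_diff(diff: np.ndarray, tracks: list[dict], w: int) -> list[np.ndarray]:
    return [_running_mean(diff[t["rows"]], w) for t in tracks]


def _assemble_runs(
    sm: np.ndarray, pos: np.ndarray, cutoff: float, max_gap: int
) -> list[tuple[int, int]]:
    """Maximal index runs with |smoothed| >= cutoff, same sign, bounded gaps."""
    above = np.abs(sm) >= cutoff
    runs = []
    start = None
    for i in range(len(sm)):
        if above[i]:
            if start is None:
                start = i
            elif (np.sign(sm[i]) != np.sign(sm[i - 1])
                  or pos[i] - pos[i - 1] > max_gap):
                runs.append((start, i - 1))
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(sm) - 1))
    return runs


def find_bumps(
    m: BetaMatrix,
    labels: np.ndarray,
    ann: pd.DataFrame,
    params: BumpParams | None = None,
    seed: int = 0,
) -> list[RegionCall]:
    """Bump-hunting scan for DMRs/DMBs with permutation p-values.

    The cutoff is the ``cutoff_quantile`` of the genome-wide |smoothed
    difference| distribution. Each surviving region's empirical p is the
    add-one fraction of label permutations whose best run with at least as
    many probes reaches the observed run area (sum of |smoothed| values).
    """
    params = params or BumpParams()
    labels = np.asarray(labels).astype(bool)
    a, b = _group_values(m, labels)
    tracks = _chromosome_tracks(m, ann, params)
    diff = m.values[:, labels].mean(axis=1) - m.values[:, ~labels].mean(axis=1)
    smoothed = _smoothed_diff(diff, tracks, params.smooth_window)
    cutoff = float(np.quantile(np.abs(np.concatenate(smoothed)), params.cutoff_quantile))

    observed: list[dict] = []
    for t, sm in zip(tracks, smoothed):
        for s, e in _assemble_runs(sm, t["pos"], cutoff, params.max_gap):
            n_run = e - s + 1
            width = int(t["pos"][e] - t["pos"][s])
            if width < params.min_width or n_run < params.min_probes:
                continue
            rows = t["rows"][s: e + 1]
            observed.append({
                "chrom": t["chrom"],
                "start": int(t["pos"][s]),
                "end": int(t["pos"][e]),
                "rows": rows,
                "n": n_run,
                "area": float(np.abs(sm[s: e + 1]).sum()),
                "mean_diff": float(diff[rows].mean()),
            })

    exceed = np.zeros(len(observed), dtype=int)
    if observed and params.n_permutations > 0:
        rng = np.random.default_rng(seed)
        values = m.values
        n_samples = m.n_samples
        n_a = int(labels.sum())
        for _ in range(params.n_permutations):
            perm = rng.permutation(n_samples)
            pa, pb = perm[:n_a], perm[n_a:]
            pdiff = values[:, pa].mean(axis=1) - values[:, pb].mean(axis=1)
            psm = _smoothed_diff(pdiff, tracks, params.smooth_window)
            perm_runs: list[tuple[int, float]] = []
            for t, sm in zip(tracks, psm):
                for s, e in _assemble_runs(sm, t["pos"], cutoff, params.max_gap):
                    perm_runs.append((e - s + 1, float(np.abs(sm[s: e + 1]).sum())))
            for i, obs in enumerate(observed):
                if any(n >= obs["n"] and area >= obs["area"] for n, area in perm_runs):
                    exceed[i] += 1

    calls = [
        RegionCall(
            kind=params.kind,
            chromosome=obs["chrom"],
            start=obs["start"],
            end=obs["end"],
            n_probes=obs["n"],
            mean_diff=obs["mean_diff"],
            p_emp=float((1 + exceed[i]) / (1 + params.n_permutations)),
            member_probe_ids=tuple(m.probe_ids[obs["rows"]]),
        )
        for i, obs in enumerate(observed)
    ]
    calls.sort(key=lambda c: (c.chromosome, c.start))
    return calls


def summarize_dmps(dmps: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """DMP counts per genomic-feature and island-relation category.

    Reports, per category: analyzed probes, DMP count, proportion among all
    DMPs, the normalized proportion (DMPs in category / analyzed probes in
    category) and the hyper/hypo split.
    """
    ann_idx = pd.Index(ann["probe_id"])
    loc = ann_idx.get_indexer(dmps["probe_id"])
    if (loc < 0).any():
        raise ValidationError("DMP table contains probes absent from annotation")
    is_dmp = dmps["is_dmp"].to_numpy(bool)
    hyper = is_dmp & (dmps["direction"].to_numpy(object) == "hyper")
    n_dmps_total = int(is_dmp.sum())
    rows = []
    for col, cats in (("feature_class", FEATURE_CLASSES),
                      ("island_relation", ISLAND_RELATIONS)):
        values = ann[col].to_numpy(object)[loc]
        for cat in cats:
            in_cat = values == cat
            n_analyzed = int(in_cat.sum())
            n_dmp = int((in_cat & is_dmp).sum())
            rows.append({
                "category_type": col,
                "category": cat,
                "n_analyzed": n_analyzed,
                "n_dmps": n_dmp,
                "prop_of_dmps": n_dmp / n_dmps_total if n_dmps_total else 0.0,
                "normalized_prop": n_dmp / n_analyzed if n_analyzed else 0.0,
                "n_hyper": int((in_cat & hyper).sum()),
                "n_hypo": int((in_cat & is_dmp & ~hyper).sum()),
            })
    return pd.DataFrame(rows)
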