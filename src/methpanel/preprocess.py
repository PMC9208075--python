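"""Sample/probe quality filtering and beta-value clamping.

The pipeline order is fixed: clamp values, drop high-missingness samples
(strictly more than ``max_missing_frac`` of probes missing), drop flagged
probes (control, sex-chromosome, SNP-overlapping, multi-hit) and any probe
still carrying a missing value, then collapse repeated samples to one per
(patient, tissue). Each probe removal is attributed to exactly one reason,
with flag reasons taking precedence in a fixed order so the accounting is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, PROBE_FLAGS, ValidationError

REASON_ORDER = ("control", "sex_chromosome", "snp", "multihit", "missingness")


@dataclass
class PreprocessReport:
    n_samples_removed: int = 0
    n_probes_removed_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASON_ORDER})
    n_values_clamped_low: int = 0
    n_values_clamped_high: int = 0
    n_duplicates_collapsed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_samples_removed": self.n_samples_removed,
            "n_probes_removed_by_reason": dict(self.n_probes_removed_by_reason),
            "n_values_clamped_low": self.n_values_clamped_low,
            "n_values_clamped_high": self.n_values_clamped_high,
            "n_duplicates_collapsed": self.n_duplicates_collapsed,
        }


def clamp_betas(m: BetaMatrix) -> tuple[BetaMatrix, int, int]:
    """Set present values < 0 to 0 and > 1 to 1; the mask is untouched."""
    out = m.copy()
    present = ~out.mask
    low = present & (out.values < 0.0)
    high = present & (out.values > 1.0)
    out.values[low] = 0.0
    out.values[high] = 1.0
    return out, int(low.sum()), int(high.sum())


def filter_samples(m: BetaMatrix, max_missing_frac: float = 0.25) -> tuple[BetaMatrix, int]:
    """Drop samples whose missing fraction strictly exceeds the threshold."""
    frac = m.mask.mean(axis=0)
    keep = frac <= max_missing_frac
    if not keep.any():
        raise ValidationError(
            "all samples exceed the missingness threshold; review max_missing_frac")
    return m.select_samples(keep), int((~keep).sum())


def filter_probes(
    m: BetaMatrix, ann: pd.DataFrame
) -> tuple[BetaMatrix, dict[str, int]]:
    """Drop flagged probes, then probes with any remaining missing value.

    Returns the filtered matrix and per-reason removal counts; each removed
    probe is charged to exactly one reason (flag precedence: control,
    sex_chromosome, snp, multihit; then missingness).
    """
    ann_idx = pd.Index(ann["probe_id"])
    loc = ann_idx.get_indexer(m.probe_ids)
    if (loc < 0).any():
        missing_probe = m.probe_ids[loc < 0][0]
        raise ValidationError(f"probe {missing_probe!r} absent from annotation")
    flags = ann["flags"].to_numpy(object)[loc]
    counts = {r: 0 for r in REASON_ORDER}
    keep = np.ones(m.n_probes, dtype=bool)
    for i, fl in enumerate(flags):
        reason = next((r for r in PROBE_FLAGS if r in fl), None)
        if reason is not None:
            counts[reason] += 1
            keep[i] = False
    has_missing = m.mask.any(axis=1)
    miss_drop = keep & has_missing
    counts["missingness"] = int(miss_drop.sum())
    keep &= ~has_missing
    return m.select_probes(keep), counts


def deduplicate_patients(
    samples: pd.DataFrame, m: BetaMatrix
) -> tuple[BetaMatrix, pd.DataFrame, int]:
    """Keep one sample per (patient_id, tissue): lowest sample_id wins."""
    sub = samples[samples["sample_id"].isin(set(m.sample_ids))]
    keep_ids = (
        sub.sort_values("sample_id", kind="stable")
        .groupby(["patient_id", "tissue"], sort=False)
        .head(1)["sample_id"]
    )
    keep_set = set(keep_ids)
    n_removed = len(sub) - len(keep_set)
    keep_mask = np.array([s in keep_set for s in m.sample_ids])
    out_samples = samples[samples["sample_id"].isin(keep_set)].reset_index(drop=True)
    return m.select_samples(keep_mask), out_samples, n_removed


def run_preprocessing(
    m: BetaMatrix,
    ann: pd.DataFrame,
    samples: pd.DataFrame,
    max_missing_frac: float = 0.25,
) -> tuple[BetaMatrix, pd.DataFrame, PreprocessReport]:
    """Full preprocessing: clamp -> sample filter -> probe filter -> dedup."""
    report = PreprocessReport()
    m, report.n_values_clamped_low, report.n_values_clamped_high = clamp_betas(m)
    m, report.n_samples_removed = filter_samples(m, max_missing_frac)
    m, report.n_probes_removed_by_reason = filter_probes(m, ann)
    m, samples, report.n_duplicates_collapsed = deduplicate_patients(samples, m)
    return m, samples, report
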