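"""Readers and writers for the pipeline's tabular and genomic formats.

All tables are plain TSV with a header row. Regions are exported as BED6,
converting internal 1-based inclusive coordinates to BED's 0-based
half-open convention. Models and reports serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    DMP_COLUMNS,
    MANIFEST_COLUMNS,
    RegionCall,
    SAMPLE_COLUMNS,
    ValidationError,
    flags_from_str,
    flags_to_str,
    validate_manifest,
    validate_samples,
)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest TSV into a validated annotation table.

    The ``flags`` column holds semicolon-separated exclusion tokens
    (``control;snp`` ...); an empty cell means no flags.
    """
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str},
                      keep_default_na=False, na_values=[""])
    missing = [c for c in MANIFEST_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"manifest missing mandatory column(s): {', '.join(missing)}")
    ann["flags"] = [flags_from_str(t) for t in ann["flags"]]
    ann["gene"] = ann["gene"].where(pd.notna(ann["gene"]), None)
    ann["position"] = ann["position"].astype(int)
    return validate_manifest(ann[list(MANIFEST_COLUMNS)])


def write_manifest(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["flags"] = [flags_to_str(f) for f in out["flags"]]
    out["gene"] = out["gene"].fillna("") if out["gene"].dtype == object else out["gene"]
    out.to_csv(path, sep="\t", index=False)


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a beta-value TSV (first column probe id, rest sample columns).

    Empty cells become masked (missing) entries. Values are stored
    unclamped: out-of-range raw betas are retained until the explicit
    clamping step.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                        keep_default_na=False, na_values=[])
    vals = np.empty(frame.shape, dtype=float)
    mask = np.zeros(frame.shape, dtype=bool)
    raw = frame.to_numpy(dtype=object)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = raw[i, j].strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                mask[i, j] = True
                vals[i, j] = 0.0
            else:
                try:
                    vals[i, j] = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"non-numeric beta value {cell!r} at probe "
                        f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
                    ) from None
    return BetaMatrix(frame.index.to_numpy(object),
                      np.asarray(frame.columns, dtype=object), vals, mask)


def write_beta_matrix(m: BetaMatrix, path: str | Path, float_format: str = "%.6g") -> None:
    m.to_frame().to_csv(path, sep="\t", float_format=float_format, na_rep="")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample sheet missing column(s): {', '.join(missing)}")
    samples = samples[list(SAMPLE_COLUMNS)]
    samples = validate_samples(samples)
    samples["age"] = pd.to_numeric(samples["age"], errors="coerce")
    samples["sex"] = samples["sex"].where(samples["sex"].isin(["M", "F"]), None)
    return samples


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out["stage"] = out["stage"].fillna("") if out["stage"].dtype == object else out["stage"]
    out.to_csv(path, sep="\t", index=False)


def write_dmp_table(dmps: pd.DataFrame, path: str | Path) -> None:
    dmps[list(DMP_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dmp_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str})


def write_regions_bed(calls: Sequence[RegionCall], path: str | Path) -> None:
    """Write region calls as BED6.

    Input must be sorted by (chromosome, start); names are ``kind:index``;
    score is ``round(1000 * |mean_diff|)`` capped at 1000; strand is ``.``.
    """
    order = [(c.chromosome, c.start) for c in calls]
    if order != sorted(order):
        raise ValidationError("region calls must be sorted by (chromosome, start)")
    lines = []
    for i, c in enumerate(calls):
        score = min(1000, round(1000 * abs(c.mean_diff)))
        # 1-based inclusive -> 0-based half-open
        lines.append(f"{c.chromosome}\t{c.start - 1}\t{c.end}\t{c.kind}:{i}\t{score}\t.")
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_regions_table(calls: Sequence[RegionCall], path: str | Path) -> None:
    """TSV sidecar with the empirical p-values and member probes."""
    rows = [
        {
            "kind": c.kind,
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "n_probes": c.n_probes,
            "mean_diff": c.mean_diff,
            "p_emp": c.p_emp,
            "member_probe_ids": ",".join(c.member_probe_ids),
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["kind", "chromosome", "start", "end", "n_probes",
                                "mean_diff", "p_emp", "member_probe_ids"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
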