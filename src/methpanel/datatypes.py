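"""Shared data model for the methylation-panel pipeline.

Conventions
-----------
* Genomic coordinates are 1-based inclusive internally (Illumina manifest
  convention); BED export converts to 0-based half-open.
* Beta values live in ``[0, 1]`` after explicit clamping; missingness is an
  explicit boolean mask, never a sentinel value.
* Probe annotation and sample sheets are validated :class:`pandas.DataFrame`
  tables with fixed column sets; per-probe/region results use light
  dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
PROBE_FLAGS = ("control", "sex_chromosome", "snp", "multihit")
TISSUES = ("NT", "TP")
STAGES = ("I", "II", "III", "IV")

MANIFEST_COLUMNS = (
    "probe_id",
    "chromosome",
    "position",
    "strand",
    "gene",
    "feature_class",
    "island_relation",
    "flags",
)

SAMPLE_COLUMNS = ("sample_id", "patient_id", "tissue", "cancer_type", "stage", "age", "sex")

DMP_COLUMNS = (
    "probe_id",
    "mean_beta_a",
    "mean_beta_b",
    "delta_beta",
    "log2_fc",
    "p_raw",
    "p_adj",
    "direction",
    "is_dmp",
)


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


def validate_manifest(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe-annotation table, returning it unchanged.

    Checks probe-id uniqueness, positive positions, enum membership of
    strand / feature class / island relation and known flag tokens.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"manifest missing mandatory column(s): {', '.join(missing)}")
    dup = ann["probe_id"][ann["probe_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate probe_id in manifest: {dup.iloc[0]!r}")
    if (ann["position"] < 1).any():
        bad = ann.loc[ann["position"] < 1, "probe_id"].iloc[0]
        raise ValidationError(f"probe {bad!r} has position < 1")
    for col, allowed in (
        ("strand", ("F", "R")),
        ("feature_class", FEATURE_CLASSES),
        ("island_relation", ISLAND_RELATIONS),
    ):
        bad = ~ann[col].isin(allowed)
        if bad.any():
            val = ann.loc[bad, col].iloc[0]
            raise ValidationError(f"invalid {col} value {val!r}")
    for flags in ann["flags"]:
        unknown = set(flags) - set(PROBE_FLAGS)
        if unknown:
            raise ValidationError(f"unknown flag token(s): {sorted(unknown)}")
    return ann


def normalize_stage(token: object) -> object:
    """Normalize a clinical-stage token ('Stage I', 'stage ii', '1') to I–IV.

    Empty / NA tokens map to ``None`` (stage genuinely missing).
    """
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    s = str(token).strip()
    if not s or s.upper() in ("NA", "NAN", "NONE"):
        return None
    s = s.upper()
    if s.startswith("STAGE"):
        s = s[5:].strip()
    arabic = {"1": "I", "2": "II", "3": "III", "4": "IV"}
    s = arabic.get(s, s)
    if s not in STAGES:
        raise ValidationError(f"unrecognized stage token {token!r}")
    return s


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample sheet missing column(s): {', '.join(missing)}")
    dup = samples["sample_id"][samples["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")
    bad = ~samples["tissue"].isin(TISSUES)
    if bad.any():
        raise ValidationError(
            f"invalid tissue value {samples.loc[bad, 'tissue'].iloc[0]!r} (expected NT or TP)"
        )
    samples = samples.copy()
    samples["stage"] = [normalize_stage(s) for s in samples["stage"]]
    return samples


@dataclass
class BetaMatrix:
    """Probes x samples beta-value matrix with an explicit missing mask.

    ``values`` may hold arbitrary numbers where ``mask`` is True; consumers
    must never read masked entries. Clamping to [0, 1] is an explicit
    preprocessing step, not a construction invariant.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    mask: np.ndarray  # True = missing

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape does not match values shape")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids in beta matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in beta matrix")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            self.probe_ids.copy(), self.sample_ids.copy(), self.values.copy(), self.mask.copy()
        )

    def probe_indexer(self) -> pd.Index:
        return pd.Index(self.probe_ids)

    def select_probes(self, keep: np.ndarray | Sequence) -> "BetaMatrix":
        """Subset by boolean mask over rows or by an explicit probe-id list."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.probe_indexer().get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][0]
                raise KeyError(f"probe {missing!r} not in matrix")
        return BetaMatrix(
            self.probe_ids[idx], self.sample_ids, self.values[idx], self.mask[idx]
        )

    def select_samples(self, keep: np.ndarray | Sequence) -> "BetaMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = pd.Index(self.sample_ids).get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][0]
                raise KeyError(f"sample {missing!r} not in matrix")
        return BetaMatrix(
            self.probe_ids, self.sample_ids[idx], self.values[:, idx], self.mask[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense frame with NaN standing in for masked entries (IO only)."""
        vals = self.values.copy()
        vals[self.mask] = np.nan
        return pd.DataFrame(vals, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        vals = frame.to_numpy(dtype=float)
        mask = np.isnan(vals)
        vals = np.where(mask, 0.0, vals)
        return cls(frame.index.to_numpy(object), np.asarray(frame.columns, dtype=object),
                   vals, mask)


@dataclass(frozen=True)
class RegionCall:
    """A differentially methylated region (DMR) or block (DMB)."""

    kind: str  # "DMR" | "DMB"
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_probes: int
    mean_diff: float
    p_emp: float
    member_probe_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("DMR", "DMB"):
            raise ValidationError(f"region kind must be DMR or DMB, got {self.kind!r}")
        if self.end < self.start:
            raise ValidationError("region end < start")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PanelModel:
    """A fitted candidate logistic panel with its evaluation metrics."""

    predictor_probe_ids: tuple[str, ...]
    coefficients: dict[str, float]
    aic: float
    auc_cv: float
    misclass: float
    sens: float
    spec: float
    bootstrap_sd_auc: float | None = None
    bootstrap_sd_misclass: float | None = None
    covariates: tuple[str, ...] = ()
    separation_flag: bool = False
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        self.predictor_probe_ids = tuple(self.predictor_probe_ids)
        if len(set(self.predictor_probe_ids)) != len(self.predictor_probe_ids):
            raise ValidationError("panel predictors must be distinct")

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictor_probe_ids),
            "coefficients": self.coefficients,
            "covariates": list(self.covariates),
            "metrics": {
                "aic": self.aic,
                "auc_cv": self.auc_cv,
                "misclass": self.misclass,
                "sens": self.sens,
                "spec": self.spec,
                "bootstrap_sd_auc": self.bootstrap_sd_auc,
                "bootstrap_sd_misclass": self.bootstrap_sd_misclass,
            },
            "separation_flag": self.separation_flag,
            "cutoff": self.cutoff,
        }


def with_updated(model: PanelModel, **kw) -> PanelModel:
    return replace(model, **kw)


def flags_to_str(flags: Iterable[str]) -> str:
    return ";".join(sorted(flags))


def flags_from_str(token: object) -> frozenset:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return frozenset()
    s = str(token).strip()
    if not s:
        return frozenset()
    return frozenset(t.strip() for t in s.split(";") if t.strip())
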