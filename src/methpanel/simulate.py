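"""Synthetic 450K-style cohorts with planted differential methylation.

The generator emulates the statistical structure the downstream analysis
assumes about tumor/normal methylation arrays:

* bimodal per-probe baseline beta distributions in normal tissue (a low,
  unmethylated mode around 0.10-0.20 and a high mode around 0.80-0.90);
* shared pan-cancer hypermethylated probes, planted at unmethylated
  CpG-island-promoter-like baselines (0.03-0.08) so that a beta shift of
  ~0.3 produces the >= 4-fold mean ratio such probes show in tumors;
* per-type specific hypermethylated probes (one tumor type only);
* contiguous planted regions (hyper, intermediate baseline) and blocks
  (hypomethylation of high-baseline open-sea probes, the canonical
  large-block signature of tumors);
* tumor stages I-IV with stage-scaled effect sizes;
* optional per-entry missingness and an optional batch-shifted external
  validation cohort sharing the planted truth.

Every random draw flows from ``SimulationConfig.seed`` through named
:func:`numpy.random.default_rng` streams, so identical configs give
bit-identical cohorts and the external cohort can re-derive the planted
effect plan without carrying hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    FEATURE_CLASSES,
    ISLAND_RELATIONS,
    PROBE_FLAGS,
    STAGES,
    ValidationError,
    validate_manifest,
)

# class weights approximating genome-wide 450K design proportions
DEFAULT_FEATURE_PROPS = {
    "Body": 0.35, "IGR": 0.25, "TSS1500": 0.13, "TSS200": 0.10,
    "5'UTR": 0.09, "3'UTR": 0.04, "1stExon": 0.04,
}
DEFAULT_ISLAND_PROPS = {
    "OpenSea": 0.37, "Island": 0.31, "N_Shore": 0.13, "S_Shore": 0.10,
    "N_Shelf": 0.05, "S_Shelf": 0.04,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic discovery cohort.

    Defaults follow the emulated study design: ~8:1 tumor:normal per type,
    beta-scale within-group noise of 0.08, planted effect 0.3 and stage
    multipliers (0.8, 1.0, 1.1, 1.2) for stages I-IV.
    """

    n_probes: int = 2000
    n_types: int = 3
    n_tumor: int = 80
    n_normal: int = 10
    n_pan_dmps: int = 10
    n_type_dmps: int = 5
    n_regions: int = 2
    region_n_probes: int = 12
    n_blocks: int = 1
    block_n_probes: int = 25
    effect_delta: float = 0.3
    stage_scaling: tuple[float, float, float, float] = (0.8, 1.0, 1.1, 1.2)
    noise_sd: float = 0.08
    missing_rate: float = 0.0
    batch_shift: float = 0.0
    seed: int = 0
    type_names: tuple[str, ...] | None = None

    def types(self) -> tuple[str, ...]:
        if self.type_names is not None:
            if len(self.type_names) != self.n_types:
                raise ValidationError("type_names length must equal n_types")
            return tuple(self.type_names)
        return tuple(f"T{i + 1}" for i in range(self.n_types))

    def validate(self) -> None:
        if self.n_probes < 100:
            raise ValidationError("n_probes must be >= 100")
        planted = (self.n_pan_dmps + self.n_types * self.n_type_dmps
                   + self.n_regions * self.region_n_probes
                   + self.n_blocks * self.block_n_probes)
        if planted > self.n_probes:
            raise ValidationError(
                f"planted probe demand ({planted}) exceeds n_probes ({self.n_probes})")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.effect_delta < 0 or self.effect_delta > 1:
            raise ValidationError("effect_delta must be in [0, 1]")
        if len(self.stage_scaling) != 4:
            raise ValidationError("stage_scaling needs one multiplier per stage I-IV")


@dataclass
class PlantedTruth:
    """Machine-readable record of every planted effect (acceptance oracle)."""

    pan_dmp_ids: list[str]
    specific_dmp_ids: dict[str, list[str]]
    regions: list[dict]
    blocks: list[dict]
    direction: dict[str, str]  # probe id -> hyper|hypo

    def all_planted_probe_ids(self) -> set[str]:
        ids = set(self.pan_dmp_ids)
        for v in self.specific_dmp_ids.values():
            ids.update(v)
        for r in self.regions + self.blocks:
            ids.update(r["probe_ids"])
        return ids

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


def generate_manifest(
    n_probes: int,
    seed: int,
    n_chromosomes: int = 6,
    feature_props: dict[str, float] | None = None,
    island_props: dict[str, float] | None = None,
    flag_fraction: float = 0.03,
) -> pd.DataFrame:
    """Generate a 450K-like probe manifest on pseudo-chromosomes.

    Probes are laid down with sorted positions and exponential inter-probe
    gaps (median ~350 bp); feature and island classes are drawn from the
    configured proportions; a small fraction carries exclusion flags.
    """
    if n_probes < 100:
        raise ValidationError("n_probes must be >= 100")
    feature_props = dict(feature_props or DEFAULT_FEATURE_PROPS)
    island_props = dict(island_props or DEFAULT_ISLAND_PROPS)
    for name, props, allowed in (
        ("feature", feature_props, FEATURE_CLASSES),
        ("island", island_props, ISLAND_RELATIONS),
    ):
        if set(props) - set(allowed):
            raise ValidationError(f"unknown {name} class in proportions")
        if abs(sum(props.values()) - 1.0) > 1e-6:
            raise ValidationError(f"{name} class proportions must sum to 1")

    rng = np.random.default_rng([seed, 11])
    per_chrom = np.full(n_chromosomes, n_probes // n_chromosomes)
    per_chrom[: n_probes % n_chromosomes] += 1
    rows: dict[str, list] = {c: [] for c in ("chromosome", "position")}
    for ci, n in enumerate(per_chrom):
        gaps = 30 + rng.exponential(scale=470.0, size=n).astype(int)
        pos = 10_000 + np.cumsum(gaps)
        rows["chromosome"].extend([f"chr{ci + 1}"] * n)
        rows["position"].extend(pos.tolist())

    fc_names = list(feature_props)
    ir_names = list(island_props)
    feature = rng.choice(fc_names, size=n_probes, p=[feature_props[k] for k in fc_names])
    island = rng.choice(ir_names, size=n_probes, p=[island_props[k] for k in ir_names])
    strand = rng.choice(["F", "R"], size=n_probes)
    flagged = rng.random(n_probes) < flag_fraction
    flag_choice = rng.integers(0, len(PROBE_FLAGS), size=n_probes)
    flags = [
        frozenset([PROBE_FLAGS[flag_choice[i]]]) if flagged[i] else frozenset()
        for i in range(n_probes)
    ]
    genes = [f"GENE{g}" if feature[i] != "IGR" else None
             for i, g in enumerate(rng.integers(1, max(2, n_probes // 10), size=n_probes))]
    ann = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
            "chromosome": rows["chromosome"],
            "position": rows["position"],
            "strand": strand,
            "gene": genes,
            "feature_class": feature,
            "island_relation": island,
            "flags": flags,
        }
    )
    return validate_manifest(ann)


@dataclass
class _EffectPlan:
    """Internal: per-probe baselines and per-(probe, type) signed shifts."""

    baseline: np.ndarray  # (n_probes,)
    effect: np.ndarray  # (n_probes, n_types) signed beta shift in tumors
    truth: PlantedTruth


def _plan_effects(config: SimulationConfig, ann: pd.DataFrame) -> _EffectPlan:
    """Deterministically lay out baselines and planted effects.

    Re-derivable from (config, manifest) alone so the external-cohort
    generator reproduces the exact same plan without hidden state.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 17])
    n = len(ann)
    types = config.types()

    # bimodal normal-tissue baseline
    high_mode = rng.random(n) < 0.5
    baseline = np.where(
        high_mode,
        rng.uniform(0.80, 0.90, size=n),
        rng.uniform(0.10, 0.20, size=n),
    )

    unflagged = np.flatnonzero([len(f) == 0 for f in ann["flags"]])
    available = set(unflagged.tolist())

    def _take(k: int) -> np.ndarray:
        pool = np.fromiter(available, dtype=int)
        pool.sort()
        if k > len(pool):
            raise ValidationError("not enough unflagged probes for planted sets")
        chosen = rng.choice(pool, size=k, replace=False)
        available.difference_update(chosen.tolist())
        return np.sort(chosen)

    effect = np.zeros((n, len(types)))
    probe_ids = ann["probe_id"].to_numpy(object)
    direction: dict[str, str] = {}

    # pan-cancer hypermethylated probes: unmethylated-promoter-like baseline
    pan_idx = _take(config.n_pan_dmps)
    baseline[pan_idx] = rng.uniform(0.03, 0.08, size=len(pan_idx))
    effect[pan_idx, :] = config.effect_delta
    for i in pan_idx:
        direction[probe_ids[i]] = "hyper"

    # per-type specific hypermethylated probes
    specific: dict[str, list[str]] = {}
    for ti, t in enumerate(types):
        idx = _take(config.n_type_dmps)
        baseline[idx] = rng.uniform(0.03, 0.08, size=len(idx))
        effect[idx, ti] = config.effect_delta
        specific[t] = [probe_ids[i] for i in idx]
        for i in idx:
            direction[probe_ids[i]] = "hyper"

    # contiguous planted runs: regions (hyper, intermediate baseline) over
    # all probes, blocks (hypo, high baseline) over open-sea probes only
    chrom = ann["chromosome"].to_numpy(object)
    pos = ann["position"].to_numpy(int)
    open_sea = (ann["island_relation"] == "OpenSea").to_numpy(bool)

    def _take_run(length: int, restrict_open_sea: bool,
                  max_internal_gap: int | None = None) -> np.ndarray:
        candidates = []
        for c in pd.unique(chrom):
            on_c = np.flatnonzero(
                (chrom == c) & (open_sea if restrict_open_sea else True))
            on_c = on_c[np.argsort(pos[on_c], kind="stable")]
            for s in range(0, len(on_c) - length + 1):
                run = on_c[s: s + length]
                if max_internal_gap is not None and len(run) > 1:
                    if np.diff(pos[run]).max() > max_internal_gap:
                        continue
                if all(int(i) in available for i in run):
                    candidates.append(run)
        if not candidates:
            what = "open-sea " if restrict_open_sea else ""
            raise ValidationError(
                f"cannot plant a run of {length} contiguous {what}probes")
        run = candidates[rng.integers(0, len(candidates))]
        available.difference_update(int(i) for i in run)
        return run

    regions = []
    for _ in range(config.n_regions):
        # DMR-like runs are densely probed (CpG-island scale): cap the
        # internal inter-probe gap so the planted span is one contiguous
        # bump under the default scan gap of 1 kb
        run = _take_run(config.region_n_probes, restrict_open_sea=False,
                        max_internal_gap=900)
        baseline[run] = rng.uniform(0.25, 0.45, size=len(run))
        effect[run, :] = config.effect_delta
        for i in run:
            direction[probe_ids[i]] = "hyper"
        regions.append({
            "chromosome": str(chrom[run[0]]),
            "start": int(pos[run].min()),
            "end": int(pos[run].max()),
            "probe_ids": [probe_ids[i] for i in run],
            "direction": "hyper",
        })

    blocks = []
    for _ in range(config.n_blocks):
        run = _take_run(config.block_n_probes, restrict_open_sea=True)
        baseline[run] = rng.uniform(0.75, 0.92, size=len(run))
        effect[run, :] = -config.effect_delta
        for i in run:
            direction[probe_ids[i]] = "hypo"
        blocks.append({
            "chromosome": str(chrom[run[0]]),
            "start": int(pos[run].min()),
            "end": int(pos[run].max()),
            "probe_ids": [probe_ids[i] for i in run],
            "direction": "hypo",
        })

    truth = PlantedTruth(
        pan_dmp_ids=[probe_ids[i] for i in pan_idx],
        specific_dmp_ids=specific,
        regions=regions,
        blocks=blocks,
        direction=direction,
    )
    return _EffectPlan(baseline=baseline, effect=effect, truth=truth)


def _sample_sheet(config: SimulationConfig, rng: np.random.Generator,
                  prefix: str = "") -> pd.DataFrame:
    rows = []
    for t in config.types():
        for tissue, count in (("NT", config.n_normal), ("TP", config.n_tumor)):
            stages = rng.integers(0, 4, size=count)
            ages = np.clip(rng.normal(60, 10, size=count), 30, 90).round(1)
            sexes = rng.choice(["M", "F"], size=count)
            for i in range(count):
                sid = f"{prefix}{t}-{tissue}-{i:03d}"
                rows.append({
                    "sample_id": sid,
                    "patient_id": f"{prefix}{t}-P{tissue}{i:03d}",
                    "tissue": tissue,
                    "cancer_type": t,
                    "stage": STAGES[stages[i]] if tissue == "TP" else None,
                    "age": ages[i],
                    "sex": sexes[i],
                })
    return pd.DataFrame(rows)


def _draw_betas(config: SimulationConfig, ann: pd.DataFrame, plan: _EffectPlan,
                samples: pd.DataFrame, rng: np.random.Generator,
                batch_shift: float = 0.0) -> BetaMatrix:
    n_probes, n_samples = len(ann), len(samples)
    type_index = {t: i for i, t in enumerate(config.types())}
    stage_mult = dict(zip(STAGES, config.stage_scaling))

    mean = np.tile(plan.baseline[:, None], (1, n_samples))
    is_tp = (samples["tissue"] == "TP").to_numpy()
    for j in range(n_samples):
        if is_tp[j]:
            ti = type_index[samples["cancer_type"].iloc[j]]
            mean[:, j] += plan.effect[:, ti] * stage_mult[samples["stage"].iloc[j]]
    values = mean + rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    values += batch_shift
    np.clip(values, 0.0, 1.0, out=values)
    mask = rng.random((n_probes, n_samples)) < config.missing_rate
    return BetaMatrix(ann["probe_id"].to_numpy(object),
                      samples["sample_id"].to_numpy(object), values, mask)


def generate_cohort(
    config: SimulationConfig, ann: pd.DataFrame | None = None
) -> tuple[BetaMatrix, pd.DataFrame, PlantedTruth, pd.DataFrame]:
    """Generate a discovery cohort.

    Returns ``(betas, samples, truth, manifest)``; the manifest is generated
    from ``config.seed`` when not supplied.
    """
    if ann is None:
        ann = generate_manifest(config.n_probes, config.seed)
    plan = _plan_effects(config, ann)
    rng = np.random.default_rng([config.seed, 23])
    samples = _sample_sheet(config, rng)
    betas = _draw_betas(config, ann, plan, samples, rng)
    return betas, samples, plan.truth, ann


def generate_external_cohort(
    config: SimulationConfig, truth: PlantedTruth, ann: pd.DataFrame | None = None
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Generate an independent validation cohort sharing the planted truth.

    Baselines and planted effects are re-derived deterministically from the
    config; samples are freshly drawn and ``config.batch_shift`` is added to
    every value before clamping (a crude between-study batch effect).
    """
    if ann is None:
        ann = generate_manifest(config.n_probes, config.seed)
    plan = _plan_effects(config, ann)
    if plan.truth.pan_dmp_ids != truth.pan_dmp_ids:
        raise ValidationError("supplied truth does not match this config/manifest")
    rng = np.random.default_rng([config.seed, 29])
    samples = _sample_sheet(config, rng, prefix="EXT-")
    betas = _draw_betas(config, ann, plan, samples, rng,
                        batch_shift=config.batch_shift)
    return betas, samples
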