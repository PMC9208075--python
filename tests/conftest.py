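import numpy as np
import pandas as pd
import pytest

from methpanel.datatypes import BetaMatrix
from methpanel.simulate import SimulationConfig, generate_cohort


def make_manifest(rows):
    """Manifest table from (probe_id, chrom, pos, feature, island, flags) tuples."""
    return pd.DataFrame(
        [
            {
                "probe_id": pid,
                "chromosome": chrom,
                "position": pos,
                "strand": "F",
                "gene": None,
                "feature_class": feat,
                "island_relation": isl,
                "flags": frozenset(flags),
            }
            for pid, chrom, pos, feat, isl, flags in rows
        ]
    )


def make_betas(probe_ids, sample_ids, values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return BetaMatrix(np.asarray(probe_ids, dtype=object),
                      np.asarray(sample_ids, dtype=object), values, mask)


def make_samples(rows):
    """Sample sheet from (sample_id, patient_id, tissue, type, stage) tuples."""
    return pd.DataFrame(
        [
            {
                "sample_id": sid,
                "patient_id": pid,
                "tissue": tissue,
                "cancer_type": ctype,
                "stage": stage,
                "age": 60.0,
                "sex": "F",
            }
            for sid, pid, tissue, ctype, stage in rows
        ]
    )


def tumor_labels(m, samples):
    srows = samples.set_index("sample_id").loc[list(m.sample_ids)]
    return (srows["tissue"] == "TP").to_numpy()


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-type cohort with planted pan/specific probes, shared across tests."""
    cfg = SimulationConfig(n_probes=1500, n_types=3, n_tumor=50, n_normal=50,
                           n_pan_dmps=6, n_type_dmps=4, n_regions=1, n_blocks=1,
                           noise_sd=0.08, seed=11)
    betas, samples, truth, ann = generate_cohort(cfg)
    return {"config": cfg, "betas": betas, "samples": samples,
            "truth": truth, "manifest": ann}
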