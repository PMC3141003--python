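import numpy as np
import pandas as pd
import pytest

from symbiokern import array_preprocess as ap
from symbiokern import synthetic_data as sd


@pytest.fixture(scope="session")
def annotation_small():
    return sd.generate_annotation(160, 30, 10, 2, seed=1)


@pytest.fixture(scope="session")
def noiseless_state():
    """Small noiseless state experiment: every estimator should be exact."""
    ann = sd.generate_annotation(160, 30, 10, 2, seed=1)
    cfg = sd.StateSimConfig(
        n_probes=200, n_planted_sy=10, n_planted_apo=10, effect_log2=1.5,
        activity_prob=1.0, noise_sd=0.0, dye_bias_amplitude=0.0,
        n_print_tips=4, bg_mean=0.0, seed=1,
    )
    scans, design, truth = sd.generate_state_experiment(cfg, ann)
    return cfg, ann, scans, design, truth


@pytest.fixture(scope="session")
def noiseless_state_ma(noiseless_state):
    _, _, scans, _, _ = noiseless_state
    corrected = ap.background_correct(scans, method="none")
    return ap.compute_ma(corrected)


def make_ma(m_by_array: dict, design_rows: list, a_value: float = 10.0) -> ap.MAMatrix:
    """Hand-construct an MAMatrix from per-array M vectors (already oriented)."""
    frames = []
    probes = None
    for array_id, m in m_by_array.items():
        m = np.asarray(m, dtype=float)
        if probes is None:
            probes = [f"g{i:04d}" for i in range(len(m))]
        frames.append(
            pd.DataFrame(
                {"array_id": array_id, "probe_id": probes, "M": m,
                 "A": a_value, "print_tip_group": 1}
            )
        )
    design = ap.orient_design(pd.DataFrame(design_rows))
    return ap.MAMatrix(values=pd.concat(frames, ignore_index=True), design=design)


def ref_design_row(array_id: str, sample: str, swap_of: str = "") -> dict:
    """Design row for a sample-vs-reference array (or its dye swap)."""
    if swap_of:
        return {"array_id": array_id, "cy3_sample": sample, "cy5_sample": "REF",
                "dye_swap_of": swap_of}
    return {"array_id": array_id, "cy3_sample": "REF", "cy5_sample": sample,
            "dye_swap_of": ""}
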