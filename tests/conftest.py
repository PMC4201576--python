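import pandas as pd
import pytest

import refstab as rs


def make_dataset(rows):
    """Build a small AbundanceDataset from (animal, exp, dose, candidate,
    intensity) tuples; remaining metadata filled with defaults."""
    frame = pd.DataFrame([
        {"animal_id": a, "experiment": e, "strain": "C57BL/6", "sex": "M",
         "genotype": "WT", "dose_ug_per_kg": d, "time_h": 96.0,
         "blot_id": f"blot{e:02d}", "candidate": c, "intensity": v,
         "excluded": False}
        for (a, e, d, c, v) in rows
    ])
    return rs.AbundanceDataset(frame)


@pytest.fixture(scope="session")
def default_sim():
    cfg = rs.default_config(seed=11)
    abundance, cq = rs.simulate_dataset(cfg)
    return cfg, abundance, cq


@pytest.fixture(scope="session")
def fitted(default_sim):
    _, abundance, cq = default_sim
    return rs.ReferenceStabilityModel(abundance, cq).fit()
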