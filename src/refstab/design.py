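"""The encoded experimental design of the TCDD reference-protein study.

192 mice across 47 experimental groups in 10 experiments: timecourse
studies (500 µg/kg TCDD vs corn-oil vehicle, harvest at 6-144 h; the 19 h
experiment also used 5 µg/kg) and dose-response studies (0-1000 µg/kg,
harvest at 96 h), varying mouse strain, sex and Ahr genotype.  One western
blot per experiment.
"""

from __future__ import annotations

import pandas as pd

from .data import AnimalRecord

# (experiment, strain, sex, genotype, time_h, {dose_ug_per_kg: n_animals})
_DESIGN_ROWS = [
    (1, "C57BL/6", "M", "WT", 6, {0: 4, 500: 5}),
    (1, "C57BL/6", "F", "WT", 6, {0: 4, 500: 5}),
    (2, "C57BL/6", "M", "rWT", 19, {0: 4, 5: 4, 500: 4}),
    (2, "DBA/2J", "M", "Ala375Val", 19, {0: 4, 5: 4, 500: 4}),
    (3, "C57BL/6", "M", "WT", 24, {0: 4, 500: 5}),
    (3, "C57BL/6", "F", "WT", 24, {0: 3, 500: 5}),
    (4, "C57BL/6", "M", "WT", 72, {0: 4, 500: 5}),
    (4, "C57BL/6", "F", "WT", 72, {0: 4, 500: 5}),
    (5, "C57BL/6", "M", "WT", 144, {0: 3, 500: 4}),
    (5, "C57BL/6", "F", "WT", 144, {0: 3, 500: 5}),
    (6, "C57BL/6", "M", "WT", 96, {0: 4, 125: 4, 250: 4, 500: 4, 1000: 4}),
    (7, "C57BL/6", "M", "DEL", 96, {0: 5, 125: 4, 250: 3, 500: 3, 1000: 4}),
    (8, "C57BL/6", "M", "INS", 96, {0: 5, 125: 4, 250: 4, 500: 4, 1000: 5}),
    (9, "C57BL/6", "M", "rWT", 96, {0: 5, 125: 3, 250: 1, 500: 4, 1000: 3}),
    (10, "C57BL/6", "F", "WT", 96, {0: 5, 125: 5, 250: 4, 500: 4, 1000: 5}),
]


def design_fixture() -> list[AnimalRecord]:
    """The full study design as a list of animals with stable synthetic ids.

    Returns 192 animals in 47 (experiment, strain, sex, genotype, dose, time)
    groups, group sizes exactly as designed.  Animal ids are deterministic
    (``A<experiment>_<index>``); one blot per experiment.
    """
    animals: list[AnimalRecord] = []
    counters: dict[int, int] = {}
    for exp, strain, sex, genotype, time_h, doses in _DESIGN_ROWS:
        for dose, n in doses.items():
            for _ in range(n):
                idx = counters.get(exp, 0) + 1
                counters[exp] = idx
                animals.append(AnimalRecord(
                    animal_id=f"A{exp:02d}_{idx:03d}",
                    experiment=exp,
                    strain=strain,
                    sex=sex,
                    genotype=genotype,
                    dose_ug_per_kg=float(dose),
                    time_h=float(time_h),
                    blot_id=f"blot{exp:02d}",
                ))
    return animals


def design_frame() -> pd.DataFrame:
    """The design fixture as a DataFrame (one row per animal)."""
    return pd.DataFrame([vars(a) for a in design_fixture()])
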