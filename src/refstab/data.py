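"""Core data model: candidates, animals, abundance and Cq datasets, I/O.

The central container is :class:`AbundanceDataset` — a long/tidy table with
one row per (animal, candidate) band: animal metadata, a background-normalized
intensity in arbitrary fluorescence units, and an ``excluded`` flag for wells
with unsatisfactory loading patterns.  Excluded rows are retained for
provenance but never enter any statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    DuplicateRecordError,
    SchemaError,
    ValidationError,
)

#: The seven candidate loading controls screened in the study configuration.
CANDIDATES: tuple[str, ...] = (
    "ACTB", "EEF1A1", "GAPDH", "HPRT", "PGK1", "PPIA", "SDHA",
)

#: Strongly dioxin-induced positive control; never a candidate reference.
POSITIVE_CONTROL = "CYP1A1"

TRAINING_EXPERIMENTS = frozenset({1, 4, 6, 8, 9})
VALIDATION_EXPERIMENTS = frozenset({2, 3, 5, 7, 10})

COHORTS = ("training", "validation", "overall")

#: Columns identifying one experimental group of biologically equivalent animals.
GROUP_COLUMNS = ["experiment", "strain", "sex", "genotype", "dose_ug_per_kg", "time_h"]

#: Required columns of a long-format abundance table.
ABUNDANCE_COLUMNS = [
    "animal_id", "experiment", "strain", "sex", "genotype",
    "dose_ug_per_kg", "time_h", "blot_id", "candidate", "intensity", "excluded",
]

CQ_COLUMNS = ["animal_id", "gene", "mean_cq"]


class ConditionKey(NamedTuple):
    """One treated experimental group, paired implicitly with the dose-0
    control group of the same experiment/strain/sex/genotype/time."""

    experiment: int
    strain: str
    sex: str
    genotype: str
    dose_ug_per_kg: float
    time_h: float


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    experiment: int
    strain: str
    sex: str
    genotype: str
    dose_ug_per_kg: float
    time_h: float
    blot_id: str

    @property
    def treated(self) -> bool:
        return self.dose_ug_per_kg > 0


def assign_cohort(experiment: int) -> str:
    """Map an experiment number (1-10) to its training/validation cohort.

    The split places experiments 1, 4, 6, 8 and 9 in the training cohort and
    2, 3, 5, 7 and 10 in the validation cohort, so each half holds a similar
    mix of timecourse and dose-response designs.
    """
    experiment = int(experiment)
    if experiment in TRAINING_EXPERIMENTS:
        return "training"
    if experiment in VALIDATION_EXPERIMENTS:
        return "validation"
    raise DomainError(f"experiment must be in 1..10, got {experiment!r}")


def background_subtract(band_mean, background_mean):
    """Background-normalize a band: band minus local background.

    Returns NaN (a missing-value marker) where the difference is <= 0; such
    records must be flagged excluded by the caller.  Accepts scalars or
    arrays.  Negative inputs are invalid.
    """
    band = np.asarray(band_mean, dtype=float)
    bg = np.asarray(background_mean, dtype=float)
    if np.any(~np.isfinite(band)) or np.any(~np.isfinite(bg)):
        raise ValidationError("band and background intensities must be finite")
    if np.any(band < 0) or np.any(bg < 0):
        raise ValidationError("band and background intensities must be >= 0")
    out = band - bg
    out = np.where(out <= 0, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


class AbundanceDataset:
    """Long-format table of background-normalized band intensities.

    Parameters
    ----------
    frame
        DataFrame with the columns in :data:`ABUNDANCE_COLUMNS`.  Rows with
        ``excluded=True`` may carry NaN intensities; all other intensities
        must be finite and strictly positive.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ABUNDANCE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"abundance table missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, ABUNDANCE_COLUMNS].copy()
        try:
            frame["experiment"] = frame["experiment"].astype(int)
            frame["dose_ug_per_kg"] = frame["dose_ug_per_kg"].astype(float)
            frame["time_h"] = frame["time_h"].astype(float)
            frame["intensity"] = frame["intensity"].astype(float)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"malformed numeric field: {exc}") from exc
        frame["excluded"] = frame["excluded"].astype(bool)
        for col in ("animal_id", "strain", "sex", "genotype", "blot_id", "candidate"):
            frame[col] = frame[col].astype(str)

        dup = frame.duplicated(subset=["animal_id", "candidate"])
        if dup.any():
            pairs = frame.loc[dup, ["animal_id", "candidate"]].head(3).to_records(index=False)
            raise DuplicateRecordError(
                f"duplicate (animal, candidate) record(s), e.g. {list(pairs)}"
            )
        ok = frame["excluded"] | (np.isfinite(frame["intensity"]) & (frame["intensity"] > 0))
        if not ok.all():
            bad = frame.loc[~ok].head(3)
            raise ValidationError(
                "non-positive or non-finite intensity on non-excluded row(s):\n"
                f"{bad.to_string()}"
            )
        self.frame = frame.reset_index(drop=True)

    # -- views -----------------------------------------------------------

    def included(self) -> pd.DataFrame:
        """Rows that participate in statistics (excluded flag False)."""
        return self.frame.loc[~self.frame["excluded"]].copy()

    @property
    def candidates(self) -> list[str]:
        """Candidate ids present, in canonical (sorted) order."""
        return sorted(self.frame["candidate"].unique())

    def animal_table(self) -> pd.DataFrame:
        """One row of metadata per animal, with derived cohort/treated columns."""
        cols = ["animal_id"] + GROUP_COLUMNS + ["blot_id"]
        tab = self.frame[cols].drop_duplicates("animal_id").reset_index(drop=True)
        tab["treated"] = tab["dose_ug_per_kg"] > 0
        tab["cohort"] = tab["experiment"].map(assign_cohort)
        return tab

    def subset_cohort(self, cohort: str) -> "AbundanceDataset":
        """Restrict to one cohort ('training' | 'validation' | 'overall')."""
        if cohort not in COHORTS:
            raise DomainError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
        if cohort == "overall":
            return self
        keep = self.frame["experiment"].map(assign_cohort) == cohort
        return AbundanceDataset(self.frame.loc[keep])

    def drop_excluded(self) -> "AbundanceDataset":
        """Physically delete excluded rows (statistics must be unchanged)."""
        return AbundanceDataset(self.included())

    def __len__(self) -> int:
        return len(self.frame)


class CqDataset:
    """qPCR mean quantification-cycle values, one row per (animal, gene).

    Cq is on an inverse scale: a lower cycle number means more abundant mRNA.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in CQ_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"cq table missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, CQ_COLUMNS].copy()
        try:
            frame["mean_cq"] = frame["mean_cq"].astype(float)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"malformed mean_cq field: {exc}") from exc
        if not np.isfinite(frame["mean_cq"]).all():
            raise ValidationError("mean_cq values must be finite")
        frame["animal_id"] = frame["animal_id"].astype(str)
        frame["gene"] = frame["gene"].astype(str)
        if frame.duplicated(subset=["animal_id", "gene"]).any():
            raise DuplicateRecordError("duplicate (animal, gene) Cq record(s)")
        self.frame = frame.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].unique())

    def __len__(self) -> int:
        return len(self.frame)


# -- condition construction ----------------------------------------------


def build_conditions(dataset: AbundanceDataset) -> list[ConditionKey]:
    """Enumerate treated-vs-control comparison keys present in a dataset.

    Every distinct treated group is paired with the dose-0 group of the same
    experiment/strain/sex/genotype/time.  A treated group with no matching
    control is dropped with a warning (comparisons cannot be formed for it).
    Ordering is deterministic: (experiment, dose, time, strain, sex, genotype).
    """
    if len(dataset.frame) == 0:
        raise ValidationError("dataset is empty")
    animals = dataset.animal_table()
    groups = animals[GROUP_COLUMNS].drop_duplicates()
    controls = {
        tuple(row)
        for row in groups.loc[groups["dose_ug_per_kg"] == 0]
        .drop(columns="dose_ug_per_kg")
        .itertuples(index=False)
    }
    conditions: list[ConditionKey] = []
    for row in groups.loc[groups["dose_ug_per_kg"] > 0].itertuples(index=False):
        key = ConditionKey(
            int(row.experiment), row.strain, row.sex, row.genotype,
            float(row.dose_ug_per_kg), float(row.time_h),
        )
        base = (key.experiment, key.strain, key.sex, key.genotype, key.time_h)
        if base not in controls:
            warnings.warn(
                f"treated group {key} has no dose-0 control; omitted from comparisons",
                stacklevel=2,
            )
            continue
        conditions.append(key)
    conditions.sort(key=lambda k: (k.experiment, k.dose_ug_per_kg, k.time_h,
                                   k.strain, k.sex, k.genotype))
    return conditions


def condition_groups(dataset: AbundanceDataset, condition: ConditionKey,
                     candidate: str) -> tuple[np.ndarray, np.ndarray]:
    """Included intensities of (treated, control) animals for one condition."""
    inc = dataset.included()
    inc = inc.loc[inc["candidate"] == candidate]
    base = (
        (inc["experiment"] == condition.experiment)
        & (inc["strain"] == condition.strain)
        & (inc["sex"] == condition.sex)
        & (inc["genotype"] == condition.genotype)
        & (inc["time_h"] == condition.time_h)
    )
    treated = inc.loc[base & (inc["dose_ug_per_kg"] == condition.dose_ug_per_kg),
                      "intensity"].to_numpy()
    control = inc.loc[base & (inc["dose_ug_per_kg"] == 0), "intensity"].to_numpy()
    return treated, control


# -- file I/O -------------------------------------------------------------


def read_abundance_table(path) -> AbundanceDataset:
    """Read a tab-delimited long-format abundance table (validated)."""
    frame = pd.read_csv(path, sep="\t")
    return AbundanceDataset(frame)


def read_cq_table(path) -> CqDataset:
    frame = pd.read_csv(path, sep="\t")
    return CqDataset(frame)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write result tables as TSV with 12-significant-digit floats.

    Keys are file stems (``table2_like`` -> ``table2_like.tsv``).  Fixed
    column order and deterministic row order are the caller's contract;
    re-reading reproduces integers bit-identically and floats to 12
    significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for stem, table in tables.items():
        dest = out_dir / f"{stem}.tsv"
        table.to_csv(dest, sep="\t", index=False, float_format="%.12g")
        written.append(dest)
    return written
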