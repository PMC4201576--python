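"""Pairwise comparative-normalization stability.

Each candidate takes a turn as the reference: every other candidate is
divided by it animal-by-animal (the intensity-scale analogue of a
quantification-cycle difference), rescaled back to intensity units by the
reference's median, and the residual spread of the normalized values among
biologically equivalent animals is measured.  A reference that removes
technical variation leaves little spread; the score is the mean SD across
the other candidates, lower = better.

Because the rescaling restores intensity units, the score inherits the
reference panel's absolute scale: multiplying all intensities by c
multiplies every score by c.  Candidates with unusually bright bands are
penalised by construction, which is why this screen must be read together
with the scale-free ones.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .data import GROUP_COLUMNS, POSITIVE_CONTROL, AbundanceDataset
from .exceptions import InsufficientDataError, ValidationError


def reference_normalize(dataset: AbundanceDataset, target: str,
                        reference: str) -> pd.Series:
    """Target intensities normalized by a reference candidate, per animal.

    v_j = (target_j / reference_j) * median_j(reference), indexed by animal.
    Animals missing either band are dropped.
    """
    if target == reference:
        raise ValidationError("target and reference must differ")
    inc = dataset.included()
    t = inc.loc[inc["candidate"] == target].set_index("animal_id")["intensity"]
    r = inc.loc[inc["candidate"] == reference].set_index("animal_id")["intensity"]
    shared = t.index.intersection(r.index)
    if len(shared) == 0:
        raise InsufficientDataError(
            f"no animals with both {target} and {reference}")
    v = (t.loc[shared] / r.loc[shared]) * float(r.loc[shared].median())
    v.name = f"{target}/{reference}"
    return v


def _group_sds(dataset: AbundanceDataset, v: pd.Series) -> pd.Series:
    """SD of normalized values within each experimental group (>= 2 animals)."""
    meta = dataset.animal_table().set_index("animal_id")
    frame = meta.loc[v.index, GROUP_COLUMNS].copy()
    frame["v"] = v
    sds = frame.groupby(GROUP_COLUMNS, sort=True)["v"].agg(["std", "count"])
    return sds.loc[sds["count"] >= 2, "std"]


def comparative_stability(dataset: AbundanceDataset,
                          candidates: Sequence[str] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-SD stability score for each candidate acting as the reference.

    For reference k and each target i != k the per-group SDs of the
    normalized values are averaged over groups, and the per-target values
    averaged into mean_sd(k).  Returns (scores, per-pair detail).
    """
    if candidates is None:
        candidates = [c for c in dataset.candidates if c != POSITIVE_CONTROL]
    candidates = list(candidates)
    if len(candidates) < 2:
        raise InsufficientDataError("need at least 2 candidates")
    pair_rows = []
    for ref in candidates:
        for target in candidates:
            if target == ref:
                continue
            v = reference_normalize(dataset, target, ref)
            sds = _group_sds(dataset, v)
            if len(sds) == 0:
                raise InsufficientDataError(
                    f"no experimental group with >= 2 animals for {target}/{ref}")
            pair_rows.append({"reference": ref, "target": target,
                              "sd": float(sds.mean())})
    pairs = pd.DataFrame(pair_rows)
    scores = (pairs.groupby("reference", sort=True)["sd"].mean()
              .rename("mean_sd").reset_index())
    return scores, pairs
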