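"""Univariate fold-difference screen.

For every treated experimental group the candidate's fold-difference M
(mean treated / mean control intensity) is computed against the matching
vehicle-control group, and differential abundance is assessed with an
unpaired two-tailed Welch t-test on the linear intensity scale.  A
candidate's significance profile (conditions with p < alpha out of
testable conditions) summarises how often treatment moves it.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceDataset, build_conditions, condition_groups
from .exceptions import InsufficientDataError, UnknownCandidateError, ValidationError


class FoldDifference(NamedTuple):
    M: float
    log2M: float
    sd_log2M: float


class WelchResult(NamedTuple):
    t_stat: float
    df: float
    p: float

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p)


#: Marker for comparisons with fewer than 2 animals in either group.
UNTESTABLE = WelchResult(np.nan, np.nan, np.nan)


def fold_difference(treated, control) -> FoldDifference:
    """Fold-difference M of a treated group over its control.

    M is the ratio of linear-scale group means; the SD is taken over the
    per-animal log2 ratios treated_j / mean(control), matching how error
    bars are usually drawn on log2 fold-change plots.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValidationError("fold_difference requires non-empty groups")
    if np.any(treated <= 0) or np.any(control <= 0):
        raise ValidationError("intensities must be > 0")
    M = float(treated.mean() / control.mean())
    per_animal = np.log2(treated / control.mean())
    sd = float(np.std(per_animal, ddof=1)) if treated.size > 1 else np.nan
    return FoldDifference(M, float(np.log2(M)), sd)


def welch_test(a, b) -> WelchResult:
    """Two-tailed unpaired t-test with Welch's heteroscedasticity adjustment.

    Returns the untestable marker (NaNs) when either group has fewer than 2
    values.  Zero variance in both groups degenerates to t=0, p=1 for equal
    means and |t|=inf, p=0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return UNTESTABLE
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        sign = np.sign(a.mean() - b.mean())
        return WelchResult(float(sign * np.inf), float(a.size + b.size - 2), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return WelchResult(float(t), float(df), float(p))


def condition_table(dataset: AbundanceDataset,
                    candidates: Sequence[str] | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per (condition, candidate) fold-differences and Welch tests.

    One row per treated-vs-control comparison; comparisons with fewer than
    2 animals in either group carry NaN test fields and testable=False.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if candidates is None:
        candidates = dataset.candidates
    conditions = build_conditions(dataset)
    rows = []
    for cond in conditions:
        for cand in candidates:
            treated, control = condition_groups(dataset, cond, cand)
            if treated.size == 0 or control.size == 0:
                continue  # candidate fully excluded for one side
            fd = fold_difference(treated, control)
            wt = welch_test(treated, control)
            rows.append({
                **cond._asdict(), "candidate": cand,
                "M": fd.M, "log2M": fd.log2M, "sd_log2M": fd.sd_log2M,
                "t_stat": wt.t_stat, "df": wt.df, "p": wt.p,
                "n_treated": int(treated.size), "n_control": int(control.size),
                "testable": bool(wt.testable),
                "significant": bool(wt.testable and wt.p < alpha),
            })
    return pd.DataFrame(rows)


def significance_profile(dataset: AbundanceDataset, candidate: str,
                         alpha: float = 0.05,
                         table: pd.DataFrame | None = None) -> tuple[int, int]:
    """(n significant, n testable) conditions for one candidate."""
    if candidate not in dataset.candidates:
        raise UnknownCandidateError(f"candidate {candidate!r} not in dataset")
    if table is None:
        table = condition_table(dataset, candidates=[candidate], alpha=alpha)
    sub = table.loc[(table["candidate"] == candidate) & table["testable"]]
    return int(sub["significant"].sum()), int(len(sub))


def fold_profile_correlation(dataset: AbundanceDataset, candidate_a: str,
                             candidate_b: str,
                             table: pd.DataFrame | None = None) -> float:
    """Pearson correlation of two candidates' log2 fold-difference profiles
    over the conditions evaluable for both (at least 3 required)."""
    for cand in (candidate_a, candidate_b):
        if cand not in dataset.candidates:
            raise UnknownCandidateError(f"candidate {cand!r} not in dataset")
    if table is None:
        table = condition_table(dataset, candidates=[candidate_a, candidate_b])
    key = ["experiment", "strain", "sex", "genotype", "dose_ug_per_kg", "time_h"]
    a = table.loc[table["candidate"] == candidate_a, key + ["log2M"]]
    b = table.loc[table["candidate"] == candidate_b, key + ["log2M"]]
    merged = a.merge(b, on=key, suffixes=("_a", "_b")).dropna(
        subset=["log2M_a", "log2M_b"])
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} shared conditions for "
            f"{candidate_a}/{candidate_b}; need >= 3")
    r = np.corrcoef(merged["log2M_a"], merged["log2M_b"])[0, 1]
    return float(r)
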