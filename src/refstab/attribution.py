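"""Linear-model attribution of combination stability to individual candidates.

The overall stability Y of every candidate combination is regressed on
Boolean inclusion indicators, one per candidate, with no intercept:

    Y = sum_p alpha_p x_p + eps

A negative coefficient means including that candidate lowers the stability
value of combinations it joins (i.e. stabilises them); significance is a
two-sided t-test per coefficient with Benjamini-Hochberg FDR across the
candidate family.
"""

from __future__ import annotations

from itertools import combinations as _combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .exceptions import IncompleteDesignError, ValidationError


def design_matrix(combinations: Sequence[str],
                  candidates: Sequence[str]) -> pd.DataFrame:
    """Boolean inclusion indicators, one column per candidate."""
    cols = {c: [] for c in candidates}
    for combo in combinations:
        members = set(combo.split("+"))
        unknown = members.difference(candidates)
        if unknown:
            raise ValidationError(f"unknown member(s) {sorted(unknown)} in {combo!r}")
        if not members:
            raise ValidationError("empty combination")
        for c in candidates:
            cols[c].append(1.0 if c in members else 0.0)
    return pd.DataFrame(cols, index=list(combinations))


def fit_linear_attribution(scores: pd.DataFrame,
                           candidates: Sequence[str] | None = None,
                           ) -> pd.DataFrame:
    """OLS of combination stability on inclusion indicators (no intercept).

    Parameters
    ----------
    scores
        Columns ``combination`` ('+'-joined sorted ids) and ``stability``;
        must cover every non-empty subset of the candidate set exactly once.

    Returns
    -------
    DataFrame with candidate, coef, se, p, q_bh.
    """
    if candidates is None:
        candidates = sorted({m for c in scores["combination"]
                             for m in c.split("+")})
    candidates = list(candidates)
    expected = {
        "+".join(s)
        for k in range(1, len(candidates) + 1)
        for s in _combinations(sorted(candidates), k)
    }
    seen = set(scores["combination"])
    if seen != expected or len(scores) != len(expected):
        missing = sorted(expected - seen)[:3]
        raise IncompleteDesignError(
            f"scores must cover all {len(expected)} subsets exactly once; "
            f"e.g. missing {missing}")
    X = design_matrix(scores["combination"], candidates)
    assert np.linalg.matrix_rank(X.to_numpy()) == len(candidates)
    fit = sm.OLS(scores["stability"].to_numpy(), X.to_numpy()).fit()
    q = multipletests(fit.pvalues, method="fdr_bh")[1]
    return pd.DataFrame({
        "candidate": candidates,
        "coef": fit.params,
        "se": fit.bse,
        "p": fit.pvalues,
        "q_bh": q,
    }).reset_index(drop=True)
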