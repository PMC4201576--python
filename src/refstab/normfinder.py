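"""Model-based stability values (NormFinder) for candidates and combinations.

The model decomposes log-scale abundance into a candidate-by-group mean, a
per-animal sample effect shared by all candidates, and candidate-specific
intra-group noise:

    y_igj = alpha_ig + b_gj + eps_igj,   eps_igj ~ N(0, sigma2_ig)

For candidate i in group g (n candidates, G groups, n_g animals in group g):

* ``MS_ig``  — mean square of the double-centered residuals
  (y_igj - ybar_ig. - ybar_.gj + ybar_.g.) over j, divided by (n_g - 1);
* ``sigma2_ig = max(0, n/(n-2) * (MS_ig - sum_i' MS_i'g / (n (n-1))))`` —
  an exactly unbiased intra-group variance estimate (before truncation);
* ``d_ig = (ybar_ig. - ybar_.g.) - (ybar_i.. - ybar_...)`` — the
  inter-group expression difference (sums to zero over candidates);
* ``gamma2`` — the variance of true inter-group differences, estimated by
  moment matching and shared across candidates;
* ``d_tilde_ig = d_ig * gamma2 / (gamma2 + sigma2_ig / n_g)`` — the
  empirical-Bayes shrunk difference;
* stability ``rho_i = mean_g(|d_tilde_ig| + sqrt(sigma2_ig/n_g *
  gamma2 / (gamma2 + sigma2_ig/n_g)))`` — lower is more stable.

Combinations are scored as geometric-mean pseudo-candidates: the subset's
per-animal mean log2 value is scored against the sample effects, mean-square
correction and gamma2 estimated once from the full candidate matrix, which
keeps singleton scores exactly equal to the per-candidate scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import POSITIVE_CONTROL, AbundanceDataset
from .exceptions import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)


def log_matrix(dataset: AbundanceDataset, base: float = 2.0) -> pd.DataFrame:
    """Candidate x animal matrix of log intensities (complete cases).

    Excluded records become missing; animals missing any candidate are then
    dropped listwise (NormFinder needs the shared per-animal sample effect),
    with the dropped count logged.
    """
    inc = dataset.included()
    if (inc["intensity"] <= 0).any():
        raise ValidationError("intensities must be > 0 for log transform")
    mat = inc.pivot(index="candidate", columns="animal_id", values="intensity")
    mat = np.log(mat) / np.log(base)
    complete = mat.notna().all(axis=0)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("log_matrix: dropped %d animal(s) with missing candidates", n_drop)
    return mat.loc[:, complete].sort_index(axis=0).sort_index(axis=1)


@dataclass(eq=False)
class NormFinderComponents:
    """Variance-decomposition components, indexed candidate x group."""

    MS: pd.DataFrame                #: residual mean squares (log2 units^2)
    sigma2_raw: pd.DataFrame        #: unbiased intra-group variance (untruncated)
    sigma2: pd.DataFrame            #: truncated at 0
    d: pd.DataFrame                 #: inter-group differences (log2 units)
    d_tilde: pd.DataFrame           #: shrunk inter-group differences
    gamma2: float                   #: variance of true inter-group differences
    rho: pd.Series                  #: stability value per candidate (lower=stabler)
    n_per_group: pd.Series          #: animals per group


def _group_sizes(groups: pd.Series) -> pd.Series:
    sizes = groups.value_counts().sort_index()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise InsufficientDataError(f"group(s) {small} have fewer than 2 animals")
    if len(sizes) < 2:
        raise InsufficientDataError("need at least 2 groups")
    return sizes


def decompose_variance(log_mat: pd.DataFrame, groups: Mapping[str, str] | pd.Series,
                       ) -> NormFinderComponents:
    """Estimate the full variance decomposition of a log-intensity matrix.

    Parameters
    ----------
    log_mat
        Candidates (rows) by animals (columns), no missing values.
    groups
        Group label per animal id (e.g. treated/control).
    """
    groups = pd.Series(groups).loc[log_mat.columns]
    n = log_mat.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need >= 3 candidates, got {n}")
    if log_mat.isna().any().any():
        raise ValidationError("log matrix must be complete (no missing values)")
    sizes = _group_sizes(groups)
    glabels = list(sizes.index)
    G = len(glabels)

    y = log_mat.to_numpy(dtype=float)
    ybar_i = y.mean(axis=1)                 # per candidate, over all animals
    ybar = y.mean()

    MS = np.empty((n, G))
    d = np.empty((n, G))
    sample_effect = {}                      # per group: ybar_.gj - ybar_.g.
    group_mean = {}
    for gi, g in enumerate(glabels):
        cols = (groups == g).to_numpy()
        yg = y[:, cols]
        n_g = yg.shape[1]
        ybar_ig = yg.mean(axis=1)
        ybar_gj = yg.mean(axis=0)
        ybar_g = yg.mean()
        resid = yg - ybar_ig[:, None] - ybar_gj[None, :] + ybar_g
        MS[:, gi] = (resid ** 2).sum(axis=1) / (n_g - 1)
        d[:, gi] = (ybar_ig - ybar_g) - (ybar_i - ybar)
        sample_effect[g] = pd.Series(ybar_gj - ybar_g, index=log_mat.columns[cols])
        group_mean[g] = ybar_g

    correction = MS.sum(axis=0) / (n * (n - 1))          # per group
    sigma2_raw = (n / (n - 2)) * (MS - correction[None, :])
    sigma2 = np.maximum(0.0, sigma2_raw)

    n_g_arr = sizes.to_numpy(dtype=float)
    var_terms = sigma2 / n_g_arr[None, :]
    gamma2 = max(0.0, (d ** 2).sum() / (n * (G - 1)) - var_terms.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(gamma2 + var_terms > 0,
                          gamma2 / (gamma2 + var_terms), 0.0)
    d_tilde = d * shrink
    rho = (np.abs(d_tilde) + np.sqrt(var_terms * shrink)).mean(axis=1)

    idx = log_mat.index
    comp = NormFinderComponents(
        MS=pd.DataFrame(MS, index=idx, columns=glabels),
        sigma2_raw=pd.DataFrame(sigma2_raw, index=idx, columns=glabels),
        sigma2=pd.DataFrame(sigma2, index=idx, columns=glabels),
        d=pd.DataFrame(d, index=idx, columns=glabels),
        d_tilde=pd.DataFrame(d_tilde, index=idx, columns=glabels),
        gamma2=float(gamma2),
        rho=pd.Series(rho, index=idx, name="rho"),
        n_per_group=sizes,
    )
    # stash centering context for pseudo-candidate scoring
    comp._sample_effect = sample_effect
    comp._group_mean = group_mean
    comp._grand_mean = float(ybar)
    comp._correction = pd.Series(correction, index=glabels)
    comp._n_candidates = n
    comp._groups = groups
    return comp


def _score_pseudo(values: pd.Series, comp: NormFinderComponents) -> float:
    """Stability of one pseudo-candidate against a fitted decomposition.

    Uses the sample effects, MS-sum correction and gamma2 of the full
    candidate matrix, so a singleton pseudo-candidate reproduces its
    per-candidate score exactly.
    """
    n = comp._n_candidates
    gamma2 = comp.gamma2
    vbar = float(values.mean())
    terms = []
    for g, n_g in comp.n_per_group.items():
        se = comp._sample_effect[g]
        vg = values.loc[se.index]
        vbar_g = float(vg.mean())
        resid = vg - vbar_g - se
        MS = float((resid ** 2).sum()) / (n_g - 1)
        sigma2 = max(0.0, (n / (n - 2)) * (MS - comp._correction[g]))
        d = (vbar_g - comp._group_mean[g]) - (vbar - comp._grand_mean)
        var_term = sigma2 / n_g
        shrink = gamma2 / (gamma2 + var_term) if gamma2 + var_term > 0 else 0.0
        terms.append(abs(d * shrink) + np.sqrt(var_term * shrink))
    return float(np.mean(terms))


def combination_pseudocandidate(log_mat: pd.DataFrame,
                                subset: Sequence[str]) -> pd.Series:
    """Per-animal log2 geometric-mean normalization factor of a subset.

    The arithmetic mean of the members' log2 values equals the log2 of the
    geometric mean of their intensities.  Animals missing any member are
    dropped (logged).
    """
    subset = list(subset)
    if not subset:
        raise ValidationError("subset must be non-empty")
    missing = [s for s in subset if s not in log_mat.index]
    if missing:
        raise ValidationError(f"subset member(s) not in matrix: {missing}")
    block = log_mat.loc[subset]
    complete = block.notna().all(axis=0)
    if (~complete).any():
        logger.info("combination %s: dropped %d animal(s) with missing values",
                    "+".join(subset), int((~complete).sum()))
    return block.loc[:, complete].mean(axis=0)


def default_groups(dataset: AbundanceDataset) -> pd.Series:
    """TCDD-treated vs control labels per animal."""
    tab = dataset.animal_table()
    return pd.Series(
        np.where(tab["treated"], "treated", "control"),
        index=tab["animal_id"], name="group",
    )


def stability_scores(dataset: AbundanceDataset,
                     groups: pd.Series | None = None,
                     cohort: str = "overall",
                     candidates: Sequence[str] | None = None,
                     base: float = 2.0) -> pd.Series:
    """Per-candidate stability values within one cohort.

    Restricts animals to the cohort, labels them TCDD-treated vs control
    (unless custom labels are given), and runs the variance decomposition.
    The positive control is not part of the candidate panel.
    """
    comp = _cohort_components(dataset, groups, cohort, candidates, base)
    return comp.rho


def _panel(dataset: AbundanceDataset,
           candidates: Sequence[str] | None) -> list[str]:
    if candidates is not None:
        return list(candidates)
    return [c for c in dataset.candidates if c != POSITIVE_CONTROL]


def _cohort_components(dataset, groups, cohort, candidates,
                       base: float = 2.0) -> NormFinderComponents:
    sub = dataset.subset_cohort(cohort)
    panel = _panel(dataset, candidates)
    mat = log_matrix(sub, base=base)
    missing = [c for c in panel if c not in mat.index]
    if missing:
        raise ValidationError(f"candidate(s) absent from dataset: {missing}")
    mat = mat.loc[panel].dropna(axis=1)
    if groups is None:
        g = default_groups(sub)
    else:
        g = pd.Series(groups)
    return decompose_variance(mat, g.loc[mat.columns])


def enumerate_combination_stability(dataset: AbundanceDataset,
                                    groups: pd.Series | None = None,
                                    cohort: str = "overall",
                                    candidates: Sequence[str] | None = None,
                                    base: float = 2.0) -> pd.DataFrame:
    """Stability of every non-empty candidate subset (127 rows for 7).

    Subsets are canonically ordered by (size, member tuple); the
    ``combination`` column joins sorted member ids with '+'.
    """
    sub = dataset.subset_cohort(cohort)
    panel = sorted(_panel(dataset, candidates))
    mat = log_matrix(sub, base=base)
    mat = mat.loc[panel].dropna(axis=1)
    if groups is None:
        g = default_groups(sub)
    else:
        g = pd.Series(groups)
    comp = decompose_variance(mat, g.loc[mat.columns])

    rows = []
    for size in range(1, len(panel) + 1):
        for subset in _combinations(panel, size):
            values = combination_pseudocandidate(mat, subset)
            rows.append({
                "combination": "+".join(subset),
                "n_members": size,
                "cohort": cohort,
                "stability": _score_pseudo(values, comp),
            })
    return pd.DataFrame(rows)
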