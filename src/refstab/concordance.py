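"""Protein-mRNA concordance via Spearman correlation with AS89 p-values.

Spearman's rho is computed on average ranks.  Significance follows the
AS 89 algorithm (Best & Roberts 1975) on the statistic
S = sum of squared rank differences: exact enumeration of the permutation
distribution for n <= 9 without ties, and an Edgeworth-series
approximation of the tail otherwise (also used, as an approximation, in
the presence of ties).  Two-sided p-values double the smaller tail.

Quantification cycles sit on an inverse scale — a lower Cq means more
abundant mRNA — so a *negative* protein-vs-Cq correlation indicates
concordant abundances.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import AbundanceDataset, CqDataset, POSITIVE_CONTROL
from .exceptions import InsufficientDataError, ValidationError
from .normfinder import enumerate_combination_stability

# Edgeworth-series coefficients of AS 89 (Best & Roberts 1975).
_C = (0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
      0.0879, 0.0151, 0.0072, 0.0831, 0.0131, 0.00046)


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


@lru_cache(maxsize=None)
def _exact_s_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Values and counts of S over all n! rank permutations (n <= 9)."""
    base = np.arange(n)
    perms = np.array(list(permutations(range(n))), dtype=np.int16)
    s = ((perms - base) ** 2).sum(axis=1)
    values, counts = np.unique(s, return_counts=True)
    return values, counts


def _exact_upper(n: int, s_obs: float) -> float:
    """P(S >= s_obs) under the null, by exact enumeration."""
    values, counts = _exact_s_distribution(n)
    total = counts.sum()
    return float(counts[values >= s_obs - 1e-9].sum() / total)


def _edgeworth_tail(n: int, s_obs: float, lower_tail: bool) -> float:
    """AS 89 Edgeworth-series tail of S.

    Upper tail evaluates P(S >= s_obs); the lower tail negates the
    standardized variable and applies the same series, which keeps the
    expansion accurate in both tails (S's null distribution is symmetric).
    """
    c1, c2, c3, c4, c5, c6, c7, c8, c9, c10, c11, c12 = _C
    b = 1.0 / n
    x = (6.0 * (s_obs - 1.0) * b / (n * n - 1.0) - 1.0) * np.sqrt(1.0 / b - 1.0)
    if lower_tail:
        x = -x
    y = x * x
    u = x * b * (c1 + b * (c2 + c3 * b)
                 + y * (-c4 + b * (c5 + c6 * b)
                        - y * b * (c7 + c8 * b
                                   - y * (c9 - c10 * b
                                          + y * b * (c11 - c12 * y)))))
    p = u / np.exp(y / 2.0) + stats.norm.sf(x)
    return float(min(max(p, 0.0), 1.0))


def _s_upper(n: int, s_obs: float, method: str) -> float:
    """P(S >= s_obs) — the tail toward negative rho."""
    if method == "exact":
        return _exact_upper(n, s_obs)
    return _edgeworth_tail(n, s_obs, lower_tail=False)


def _s_lower(n: int, s_obs: float, method: str) -> float:
    """P(S <= s_obs) — the tail toward positive rho.

    S only takes even values, so the Edgeworth evaluation uses the
    midpoint continuity point at s_obs + 2 with a negated variable.
    """
    if method == "exact":
        values, counts = _exact_s_distribution(n)
        return float(counts[values <= s_obs + 1e-9].sum() / counts.sum())
    return _edgeworth_tail(n, s_obs + 2.0, lower_tail=True)


def spearman_as89(x: Sequence[float], y: Sequence[float],
                  method: str = "auto") -> SpearmanResult:
    """Spearman's rho with an AS89 two-sided p-value.

    ``method`` is 'auto' (exact for n <= 9 without ties, else Edgeworth),
    'exact', or 'edgeworth'.  A constant input yields rho = NaN (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 paired values, got {n}")
    if method not in ("auto", "exact", "edgeworth"):
        raise ValidationError(f"unknown method {method!r}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(np.nan, np.nan, n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
    if method == "auto":
        method = "exact" if (n <= 9 and not ties) else "edgeworth"
    if method == "exact" and (n > 9):
        raise ValidationError("exact enumeration only supported for n <= 9")
    # With ties S is reconstructed from rho so the Edgeworth series still
    # applies approximately (exactness is impossible under ties).
    if ties:
        s_obs = (1.0 - rho) * (n ** 3 - n) / 6.0
    else:
        s_obs = float(((rx - ry) ** 2).sum())
    mu = (n ** 3 - n) / 6.0            # null mean of S
    if s_obs > mu:                     # rho < 0: upper tail of S
        p_one = _s_upper(n, s_obs, method)
    else:                              # rho >= 0: lower tail of S
        p_one = _s_lower(n, s_obs, method)
    p = min(1.0, 2.0 * p_one)
    return SpearmanResult(rho, p, n)


def protein_mrna_concordance(dataset: AbundanceDataset, cq: CqDataset,
                             genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene Spearman correlation of log2 protein intensity with mean Cq.

    Animals lacking either measurement are dropped per gene.  Remember the
    inverse Cq scale: concordant abundances show up as negative rho here.
    """
    if genes is None:
        genes = [g for g in cq.genes if g in dataset.candidates
                 and g != POSITIVE_CONTROL]
    inc = dataset.included()
    rows = []
    for gene in genes:
        prot = inc.loc[inc["candidate"] == gene].set_index("animal_id")["intensity"]
        mrna = cq.frame.loc[cq.frame["gene"] == gene].set_index("animal_id")["mean_cq"]
        shared = prot.index.intersection(mrna.index)
        if len(shared) < 4:
            raise InsufficientDataError(
                f"gene {gene}: only {len(shared)} paired animals; need >= 4")
        res = spearman_as89(np.log2(prot.loc[shared].to_numpy()),
                            mrna.loc[shared].to_numpy())
        rows.append({"gene": gene, "spearman_rho": res.rho,
                     "p_as89": res.p, "n": res.n})
    return pd.DataFrame(rows)


def stability_score_concordance(protein_scores: pd.DataFrame,
                                mrna_scores: pd.DataFrame) -> SpearmanResult:
    """Spearman concordance of combination-stability vectors across platforms.

    Both inputs need ``combination`` and ``stability`` columns with
    identical combination keys.
    """
    for name, tab in (("protein", protein_scores), ("mrna", mrna_scores)):
        if not {"combination", "stability"}.issubset(tab.columns):
            raise ValidationError(f"{name} scores need combination+stability columns")
    merged = protein_scores[["combination", "stability"]].merge(
        mrna_scores[["combination", "stability"]],
        on="combination", suffixes=("_protein", "_mrna"), how="outer",
        indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "combination"].head(3).tolist()
        raise ValidationError(f"combination keys do not match, e.g. {bad}")
    return spearman_as89(merged["stability_protein"].to_numpy(),
                         merged["stability_mrna"].to_numpy())


def mrna_combination_stability(cq: CqDataset, dataset: AbundanceDataset,
                               cohort: str = "overall",
                               genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Combination stability of the mRNA panel through the same code path.

    -Cq is a log2-scale abundance proxy (one qPCR cycle ~ a doubling), so
    Cq data are mapped onto intensities 2^(-Cq) and scored with the
    identical variance decomposition used for protein.
    """
    if genes is None:
        genes = [g for g in cq.genes if g != POSITIVE_CONTROL]
    meta = dataset.animal_table().set_index("animal_id")
    frame = cq.frame.loc[cq.frame["gene"].isin(genes)].copy()
    frame = frame.loc[frame["animal_id"].isin(meta.index)]
    frame["intensity"] = 2.0 ** (-frame["mean_cq"])
    frame["candidate"] = frame["gene"]
    frame["excluded"] = False
    for col in ("experiment", "strain", "sex", "genotype",
                "dose_ug_per_kg", "time_h", "blot_id"):
        frame[col] = meta.loc[frame["animal_id"], col].to_numpy()
    pseudo = AbundanceDataset(frame)
    return enumerate_combination_stability(pseudo, cohort=cohort,
                                           candidates=sorted(genes))
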