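"""Model/Results interface composing the full stability screen.

``ReferenceStabilityModel`` is built from an abundance table (and optional
paired qPCR Cq table); ``fit()`` runs every analysis stage — fold-difference
screen, per-candidate and per-combination stability in the training,
validation and overall cohorts, pairwise comparative normalization,
linear-model attribution, and protein-mRNA concordance — and returns a
``ReferenceStabilityResults`` carrying the estimates, their uncertainties
and a ``summary()`` table.  The analysis is fully deterministic.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .attribution import fit_linear_attribution
from .compnorm import comparative_stability
from .concordance import (
    mrna_combination_stability,
    protein_mrna_concordance,
    stability_score_concordance,
)
from .data import (
    COHORTS,
    POSITIVE_CONTROL,
    AbundanceDataset,
    CqDataset,
    read_abundance_table,
    read_cq_table,
    write_results,
)
from .exceptions import InsufficientDataError, ValidationError
from .foldscreen import condition_table
from .normfinder import enumerate_combination_stability, stability_scores


class ReferenceStabilityModel:
    """Candidate loading-control stability screen for one study.

    Parameters
    ----------
    abundance
        :class:`AbundanceDataset` or a long-format DataFrame of
        background-normalized band intensities.
    cq
        Optional :class:`CqDataset` (or DataFrame) of paired qPCR mean
        quantification cycles; enables the cross-platform concordance stage.
    alpha
        Significance level of the fold-difference Welch screen (uncorrected,
        per-condition).
    candidates
        Candidate panel; defaults to every candidate in the data except the
        positive control.
    log_base
        Log base of the stability analysis; scores scale linearly with it.
    """

    def __init__(self, abundance, cq=None, *, alpha: float = 0.05,
                 candidates: Sequence[str] | None = None,
                 positive_control: str | None = POSITIVE_CONTROL,
                 log_base: float = 2.0):
        if not isinstance(abundance, AbundanceDataset):
            abundance = AbundanceDataset(abundance)
        if cq is not None and not isinstance(cq, CqDataset):
            cq = CqDataset(cq)
        if not 0 < alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if log_base <= 1:
            raise ValidationError("log_base must be > 1")
        self.abundance = abundance
        self.cq = cq
        self.alpha = float(alpha)
        self.log_base = float(log_base)
        self.positive_control = positive_control
        if candidates is None:
            candidates = [c for c in abundance.candidates if c != positive_control]
        self.candidates = sorted(candidates)

    @classmethod
    def from_files(cls, abundances_path, cq_path=None, **kwargs):
        """Build the model from TSV files (see the data module's schemas)."""
        abundance = read_abundance_table(abundances_path)
        cq = read_cq_table(cq_path) if cq_path is not None else None
        return cls(abundance, cq, **kwargs)

    def fit(self) -> "ReferenceStabilityResults":
        """Run all stages; deterministic given the inputs."""
        log: list[dict] = [{
            "event": "start",
            "refstab_version": _pkg_version,
            "python": platform.python_version(),
            "alpha": self.alpha, "log_base": self.log_base,
            "n_records": len(self.abundance),
            "n_excluded": int(self.abundance.frame["excluded"].sum()),
            "candidates": self.candidates,
            "positive_control": self.positive_control,
        }]

        screened = list(self.candidates)
        if (self.positive_control is not None
                and self.positive_control in self.abundance.candidates):
            screened.append(self.positive_control)
        conditions = condition_table(self.abundance, candidates=screened,
                                     alpha=self.alpha)
        sig = (
            conditions.loc[conditions["testable"]]
            .groupby("candidate")["significant"]
            .agg(n_sig="sum", n_comparisons="count")
            .astype(int)
            .reindex(screened)
        )
        log.append({"event": "fold_screen",
                    "n_conditions": int(conditions[
                        ["experiment", "strain", "sex", "genotype",
                         "dose_ug_per_kg", "time_h"]].drop_duplicates().shape[0])})

        singles: dict[str, pd.Series] = {}
        combos: dict[str, pd.DataFrame] = {}
        for cohort in COHORTS:
            try:
                singles[cohort] = stability_scores(
                    self.abundance, cohort=cohort, candidates=self.candidates,
                    base=self.log_base)
                combos[cohort] = enumerate_combination_stability(
                    self.abundance, cohort=cohort, candidates=self.candidates,
                    base=self.log_base)
                log.append({"event": "normfinder", "cohort": cohort,
                            "n_combinations": len(combos[cohort])})
            except InsufficientDataError as exc:
                singles[cohort] = pd.Series(np.nan, index=self.candidates)
                combos[cohort] = None
                log.append({"event": "normfinder_skipped", "cohort": cohort,
                            "reason": str(exc)})

        comp_scores, comp_pairs = comparative_stability(
            self.abundance, candidates=self.candidates)

        attribution = None
        if combos["overall"] is not None:
            attribution = fit_linear_attribution(
                combos["overall"], candidates=self.candidates)

        concordance = None
        mrna_combos = None
        stability_conc = None
        if self.cq is not None:
            concordance = protein_mrna_concordance(self.abundance, self.cq,
                                                   genes=self.candidates)
            try:
                mrna_combos = mrna_combination_stability(
                    self.cq, self.abundance, cohort="overall",
                    genes=self.candidates)
                if combos["overall"] is not None:
                    stability_conc = stability_score_concordance(
                        combos["overall"], mrna_combos)
            except InsufficientDataError as exc:
                log.append({"event": "mrna_stability_skipped", "reason": str(exc)})
            log.append({"event": "concordance", "n_genes": len(concordance)})
        else:
            log.append({"event": "concordance_skipped", "reason": "no cq data"})

        return ReferenceStabilityResults(
            model=self,
            condition_comparisons=conditions,
            significance=sig.reset_index(),
            stability_single=pd.DataFrame(singles).rename_axis("candidate"),
            stability_combinations=combos,
            comparative_scores=comp_scores,
            comparative_pairs=comp_pairs,
            attribution=attribution,
            concordance=concordance,
            mrna_combinations=mrna_combos,
            stability_concordance=stability_conc,
            run_log=log,
        )


@dataclass(eq=False)
class ReferenceStabilityResults:
    """Estimates and diagnostics of a fitted stability screen."""

    model: ReferenceStabilityModel
    condition_comparisons: pd.DataFrame   #: per condition x candidate fold screen
    significance: pd.DataFrame            #: candidate, n_sig, n_comparisons
    stability_single: pd.DataFrame        #: candidate x cohort stability values
    stability_combinations: dict          #: cohort -> 127-row DataFrame (or None)
    comparative_scores: pd.DataFrame      #: reference, mean_sd
    comparative_pairs: pd.DataFrame       #: reference, target, sd
    attribution: pd.DataFrame | None      #: candidate, coef, se, p, q_bh
    concordance: pd.DataFrame | None      #: gene, spearman_rho, p_as89, n
    mrna_combinations: pd.DataFrame | None
    stability_concordance: object | None  #: SpearmanResult or None
    run_log: list = field(default_factory=list)

    # -- assembled tables -------------------------------------------------

    def table2_like(self) -> pd.DataFrame:
        """Per-candidate summary: Welch screen, cohort stability, comparative."""
        tab = self.significance.set_index("candidate").reindex(self.model.candidates)
        out = pd.DataFrame({
            "candidate": self.model.candidates,
            "n_sig": tab["n_sig"].to_numpy(),
            "n_comparisons": tab["n_comparisons"].to_numpy(),
            "nf_training": self.stability_single["training"]
                .reindex(self.model.candidates).to_numpy(),
            "nf_validation": self.stability_single["validation"]
                .reindex(self.model.candidates).to_numpy(),
            "nf_overall": self.stability_single["overall"]
                .reindex(self.model.candidates).to_numpy(),
            "compnorm_score": self.comparative_scores.set_index("reference")
                ["mean_sd"].reindex(self.model.candidates).to_numpy(),
        })
        return out

    def combinations_table(self) -> pd.DataFrame:
        frames = [t for t in self.stability_combinations.values() if t is not None]
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable per-candidate summary table."""
        lines = ["Reference-protein stability screen",
                 f"  candidates: {', '.join(self.model.candidates)}",
                 f"  alpha = {self.model.alpha}, log base = {self.model.log_base:g}",
                 ""]
        tab = self.table2_like()
        header = (f"{'candidate':<10} {'welch':>8} {'nf_train':>9} "
                  f"{'nf_valid':>9} {'nf_all':>8} {'compnorm':>10}")
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in tab.iterrows():
            welch = (f"{int(r.n_sig)}/{int(r.n_comparisons)}"
                     if np.isfinite(r.n_comparisons) else "-")
            lines.append(
                f"{r.candidate:<10} {welch:>8} {r.nf_training:>9.3f} "
                f"{r.nf_validation:>9.3f} {r.nf_overall:>8.3f} "
                f"{r.compnorm_score:>10.2f}")
        if self.attribution is not None:
            lines += ["", "Attribution of combination stability (no-intercept OLS):"]
            for _, r in self.attribution.iterrows():
                flag = "*" if r.q_bh < 0.05 else " "
                lines.append(f"  {r.candidate:<10} coef={r.coef:+.4f} "
                             f"se={r.se:.4f} q_bh={r.q_bh:.3g}{flag}")
        if self.stability_concordance is not None:
            sc = self.stability_concordance
            lines += ["", "Protein vs mRNA combination-stability concordance: "
                      f"Spearman rho = {sc.rho:.3f} (p = {sc.p:.3g}, n = {sc.n})"]
        return "\n".join(lines)

    def save(self, out_dir) -> list[Path]:
        """Write all result tables (TSV) plus a JSON-lines run log."""
        tables = {
            "conditions": self.condition_comparisons,
            "table2_like": self.table2_like(),
            "combinations": self.combinations_table(),
            "pairwise_sd": self.comparative_pairs,
        }
        if self.attribution is not None:
            tables["attribution"] = self.attribution
        if self.concordance is not None:
            tables["table3_like"] = self.concordance
        if self.stability_concordance is not None:
            sc = self.stability_concordance
            tables["stability_concordance"] = pd.DataFrame(
                [{"entity": "stability-vector", "spearman_rho": sc.rho,
                  "p_as89": sc.p, "n": sc.n}])
        written = write_results(tables, out_dir)
        log_path = Path(out_dir) / "run_log.jsonl"
        with open(log_path, "w") as fh:
            for entry in self.run_log:
                fh.write(json.dumps(entry) + "\n")
        written.append(log_path)
        return written
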