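"""Synthetic abundance and qPCR data with the study's statistical structure.

The generator plants a log-additive (multiplicative on the intensity scale)
noise model on top of the encoded experimental design:

    log2 intensity(i, j) = baseline_i + delta_i(dose_j, time_j) + blot_b(j) + eps_ij

with a shared per-blot shift ``blot_b ~ N(0, blot_effect_sd^2)`` (one blot
per experiment) and within-group noise ``eps_ij ~ N(0, sigma_intra_i^2)``.
qPCR quantification cycles are coupled to protein abundance through a
Gaussian copula with a tunable target Spearman correlation, sign-inverted
because a lower Cq means more abundant mRNA.

All draws come from counter-based streams keyed on stable animal/candidate
identifiers, so subsetting the design or the candidate panel never shifts
the draws of the remaining entries.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    POSITIVE_CONTROL,
    AbundanceDataset,
    AnimalRecord,
    CqDataset,
)
from .design import design_fixture
from .exceptions import ValidationError

__all__ = [
    "CandidateParams",
    "SyntheticConfig",
    "default_config",
    "cyp1a1_induction",
    "simulate_dataset",
    "true_total_variation",
    "true_stability_order",
    "design_fixture",
]

# Effect functions take (dose_ug_per_kg, time_h) and return a log2 shift.
EffectFn = Callable[[float, float], float]


def cyp1a1_induction(dose: float, time_h: float) -> float:
    """Default treatment effect of the dioxin-induced positive control.

    Strong induction (+6 log2 units, a 64-fold increase) at doses >= 125
    µg/kg and a smaller +3 log2 shift at lower non-zero doses.  The true
    induction magnitude is a free parameter of the simulation; these
    defaults make the positive control unambiguous at the design's group
    sizes without saturating the scale.
    """
    if dose <= 0:
        return 0.0
    return 6.0 if dose >= 125 else 3.0


@dataclass(frozen=True)
class CandidateParams:
    """Generative parameters of one protein.

    baseline_log2
        Mean log2 band intensity of untreated animals (arbitrary
        fluorescence units on the linear scale).
    sigma_intra
        SD of log2 intensity among biologically equivalent animals.
    treatment_effect
        Either a constant log2 shift applied to all treated animals or a
        function delta(dose, time_h); 0 for an ideal reference.
    """

    baseline_log2: float
    sigma_intra: float
    treatment_effect: float | EffectFn = 0.0

    def delta(self, dose: float, time_h: float) -> float:
        if callable(self.treatment_effect):
            return float(self.treatment_effect(dose, time_h))
        return float(self.treatment_effect) if dose > 0 else 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Design-independent parameters of the generator.

    ``mrna_coupling`` is the target Spearman correlation between log2
    protein intensity and -Cq (abundance scale) per gene; ``cq_baseline``
    and ``cq_sd`` are in cycles.
    """

    candidates: Mapping[str, CandidateParams]
    blot_effect_sd: float = 0.3
    mrna_coupling: float = 0.2
    cq_baseline: float = 22.0
    cq_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.blot_effect_sd < 0 or self.cq_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not -1.0 <= self.mrna_coupling <= 1.0:
            raise ValidationError("mrna_coupling must lie in [-1, 1]")
        for name, par in self.candidates.items():
            if par.sigma_intra < 0:
                raise ValidationError(f"sigma_intra of {name} must be >= 0")


#: Baseline log2 intensities of the study panel.  ACTB sits well above the
#: other candidates (its bands are far brighter), the rest span the
#: mid-intensity range typical of infrared-scanner densitometry.
_DEFAULT_BASELINES = {
    "ACTB": 13.0, "EEF1A1": 11.0, "GAPDH": 11.5, "HPRT": 10.0,
    "PGK1": 10.5, "PPIA": 11.2, "SDHA": 10.8,
}

#: Default high-dose treatment-effect amplitudes (log2 units).  Even usable
#: loading controls drift slightly under a strong transcriptional modulator
#: — the screen's whole point — so the emulated candidates carry small
#: dose-saturating shifts of mixed sign, an order of magnitude below the
#: positive control's induction.
_DEFAULT_EFFECT_AMPLITUDES = {
    "ACTB": -0.20, "EEF1A1": 0.35, "GAPDH": -0.10, "HPRT": 0.05,
    "PGK1": 0.30, "PPIA": -0.35, "SDHA": 0.25,
}


def dose_response_effect(amplitude: float) -> EffectFn:
    """Saturating dose effect: amplitude * min(1, dose/500), 0 for controls."""

    def delta(dose: float, time_h: float) -> float:
        if dose <= 0:
            return 0.0
        return amplitude * min(1.0, dose / 500.0)

    return delta


def default_config(seed: int = 0, sigma_intra: float = 0.25,
                   blot_effect_sd: float = 0.3,
                   mrna_coupling: float = 0.2,
                   include_positive_control: bool = True) -> SyntheticConfig:
    """Study-condition defaults: 7 weakly dose-responsive candidates plus
    the strongly dioxin-induced positive control."""
    candidates = {
        name: CandidateParams(
            baseline_log2=b, sigma_intra=sigma_intra,
            treatment_effect=dose_response_effect(_DEFAULT_EFFECT_AMPLITUDES[name]),
        )
        for name, b in _DEFAULT_BASELINES.items()
    }
    if include_positive_control:
        candidates[POSITIVE_CONTROL] = CandidateParams(
            baseline_log2=9.0, sigma_intra=sigma_intra,
            treatment_effect=cyp1a1_induction,
        )
    return SyntheticConfig(candidates=candidates, blot_effect_sd=blot_effect_sd,
                           mrna_coupling=mrna_coupling, seed=seed)


def _stream(seed: int, *keys) -> np.random.Generator:
    """Counter-based substream: stable under design/panel subsetting."""
    ints = [seed & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(ints)


def simulate_dataset(config: SyntheticConfig,
                     design: Sequence[AnimalRecord] | None = None,
                     ) -> tuple[AbundanceDataset, CqDataset]:
    """Draw one synthetic study: band intensities and paired mean-Cq values.

    Fully reproducible from ``config.seed``; the same seed yields
    bit-identical datasets.
    """
    if design is None:
        design = design_fixture()
    if len(design) == 0:
        raise ValidationError("design must contain at least one animal")
    names = list(config.candidates)

    blots = sorted({a.blot_id for a in design})
    blot_shift = {
        b: config.blot_effect_sd * _stream(config.seed, 1, b).standard_normal()
        for b in blots
    }

    rows = []
    log2_by_cand: dict[str, np.ndarray] = {}
    for name in names:
        par = config.candidates[name]
        vals = np.empty(len(design))
        for k, a in enumerate(design):
            eps = par.sigma_intra * _stream(config.seed, 2, a.animal_id,
                                            name).standard_normal()
            vals[k] = (par.baseline_log2
                       + par.delta(a.dose_ug_per_kg, a.time_h)
                       + blot_shift[a.blot_id] + eps)
        log2_by_cand[name] = vals
        for a, v in zip(design, vals):
            rows.append({
                "animal_id": a.animal_id, "experiment": a.experiment,
                "strain": a.strain, "sex": a.sex, "genotype": a.genotype,
                "dose_ug_per_kg": a.dose_ug_per_kg, "time_h": a.time_h,
                "blot_id": a.blot_id, "candidate": name,
                "intensity": 2.0 ** v, "excluded": False,
            })
    abundance = AbundanceDataset(pd.DataFrame(rows))

    # Gaussian copula: normal scores of the realized log2 intensities mixed
    # with fresh noise; Cq negated so positive coupling means high protein
    # intensity <-> low cycle number.
    rho_s = config.mrna_coupling
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    n = len(design)
    cq_rows = []
    for name in names:
        ranks = stats.rankdata(log2_by_cand[name])
        z_protein = stats.norm.ppf((ranks - 0.5) / n)
        for k, a in enumerate(design):
            noise = _stream(config.seed, 3, a.animal_id, name).standard_normal()
            z = rho_p * z_protein[k] + np.sqrt(max(0.0, 1 - rho_p ** 2)) * noise
            cq_rows.append({
                "animal_id": a.animal_id, "gene": name,
                "mean_cq": config.cq_baseline - config.cq_sd * z,
            })
    cq = CqDataset(pd.DataFrame(cq_rows))
    return abundance, cq


def true_total_variation(config: SyntheticConfig,
                         design: Sequence[AnimalRecord] | None = None,
                         ) -> pd.Series:
    """Planted total variation per candidate, in log2 units squared.

    Intra-group variance plus the between-group variance of the treatment
    effect over the design's animals (population variance, animal-weighted).
    The blot effect is shared by all candidates and does not separate them.
    """
    if design is None:
        design = design_fixture()
    out = {}
    for name, par in config.candidates.items():
        deltas = np.array([par.delta(a.dose_ug_per_kg, a.time_h) for a in design])
        out[name] = par.sigma_intra ** 2 + float(np.var(deltas))
    return pd.Series(out, name="total_variation").sort_index()


def true_stability_order(config: SyntheticConfig,
                         design: Sequence[AnimalRecord] | None = None,
                         ) -> list[str]:
    """Candidates ranked most-stable first by planted total variation.

    Ties (identical planted variation) are broken alphabetically, so equal
    parameters yield adjacent, interchangeable ranks.
    """
    tv = true_total_variation(config, design)
    return list(tv.sort_values(kind="mergesort").index)
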