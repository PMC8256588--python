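"""Synthetic longitudinal sputum cohort generator.

Emulates the statistical structure the prevalence pipeline assumes, so
every stage is testable without a clinical database: each patient carries
a latent eosinophilic state evolving as a two-state discrete-time Markov
chain over examinations, and each examination produces a quantitative
cytometry record conditionally on that state.

Key features of real sputum series that the generator reproduces:

* *masking* — a latent-eosinophilic visit may show a low intact eosinophil
  % anyway (observation noise drawn from the non-eosinophilic
  distribution); realized masks are coupled to elevated neutrophil counts
  and to corticosteroid exposure so that downstream etiology attribution
  has signal to find;
* *degenerated samples* — a fraction of cytospins admit no intact
  differential; free eosinophil granules are still enumerated, at higher
  clump rates than in viable samples (cytolysis and degeneration covary);
* *steroid weaning* — inhaled/oral doses step down over visits, creating
  dose-decrease etiologies.

Observed eosinophil % is drawn from per-state log-normal distributions
(capped at 97%, the maximum the field's reference tables report), FEG
clump counts from per-(state, viability) Poisson rates.  Everything is
driven by one :class:`numpy.random.Generator`, so a seed fully determines
the cohort, byte for byte.

:func:`closed_form_expectations` returns the analytic sample-category
fractions, call prevalences, per-pair emergence probability and
patient-level emergence fraction implied by a configuration — exact under
the generator's own assumptions — for use as oracles in tests and for
calibrating configurations to published cohort summaries.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import (
    ClinicalState,
    Cohort,
    PatientSeries,
    SputumSample,
    ThresholdSpec,
    ValidationError,
    DEFAULT_THRESHOLDS,
)

__all__ = [
    "GeneratorConfig",
    "paper_cohort_config",
    "noiseless_config",
    "generate_cohort",
    "closed_form_expectations",
]


def _check_prob(name: str, v: float) -> None:
    if not (0.0 <= v <= 1.0):
        raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Defaults are the calibrated values of :func:`paper_cohort_config`
    scaled to a small smoke-test cohort; use the factory functions for
    analysis-sized cohorts.
    """

    seed: int = 0
    n_patients: int = 500
    #: fraction of patients sampled on more than one occasion
    multi_sample_fraction: float = 0.31
    #: multi-sample series length = 1 + zero-truncated Geometric(p);
    #: mean multi length = 1 + 1/p
    series_length_geom_p: float = 0.3654
    #: latent chain: P(N->E) and P(E->N) per examination step
    p_ne: float = 0.0509
    p_en: float = 0.0737
    #: probability a latent-eosinophilic visit is masked (observed eos %
    #: drawn from the non-eosinophilic distribution)
    masking_prob: float = 0.0652
    #: log-normal observed eos % by effective state: median and log-sigma
    eos_median_neg: float = 0.359
    eos_sigma_neg: float = 0.900
    eos_median_pos: float = 3.94
    eos_sigma_pos: float = 0.680
    eos_cap: float = 97.0
    #: fraction of samples too degenerated for an intact differential
    p_nonviable: float = 0.158
    #: probability the FEG enumeration is missing entirely (indeterminate
    #: when the differential is also unavailable)
    feg_missing_prob: float = 0.0
    #: Poisson clump rates per 400x field by (latent state, viability)
    feg_rate_viable_neg: float = 0.0089
    feg_rate_viable_pos: float = 0.754
    feg_rate_nonviable_neg: float = 0.674
    feg_rate_nonviable_pos: float = 3.046
    #: marginal probability of an elevated neutrophil % (above cutoff)
    neutrophil_elevated_fraction: float = 0.45
    neutrophil_cutoff: float = 64.4
    #: probability a masked visit shows elevated neutrophils (the mask's
    #: attributable cause)
    mask_neutrophil_coupling: float = 0.6
    #: daily-dose ladders and initial-level weights (index 0 = untreated)
    ics_levels: tuple = (0.0, 250.0, 500.0, 1000.0, 2000.0)
    ics_initial_weights: tuple = (0.248, 0.150, 0.226, 0.263, 0.113)
    ocs_levels: tuple = (0.0, 5.0, 10.0, 15.0, 25.0)
    ocs_initial_weights: tuple = (0.677, 0.113, 0.113, 0.065, 0.032)
    #: per-visit probability of stepping one level down each ladder
    dose_step_down_prob: float = 0.20
    exacerbation_prob: float = 0.15

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for nm in (
            "multi_sample_fraction",
            "series_length_geom_p",
            "p_ne",
            "p_en",
            "masking_prob",
            "p_nonviable",
            "feg_missing_prob",
            "neutrophil_elevated_fraction",
            "mask_neutrophil_coupling",
            "dose_step_down_prob",
            "exacerbation_prob",
        ):
            _check_prob(nm, getattr(self, nm))
        if self.series_length_geom_p == 0:
            raise ValidationError("series_length_geom_p must be positive")
        for nm in (
            "eos_median_neg",
            "eos_sigma_neg",
            "eos_median_pos",
            "eos_sigma_pos",
            "feg_rate_viable_neg",
            "feg_rate_viable_pos",
            "feg_rate_nonviable_neg",
            "feg_rate_nonviable_pos",
        ):
            if getattr(self, nm) < 0:
                raise ValidationError(f"{nm} must be non-negative")
        for nm in ("ics_initial_weights", "ocs_initial_weights"):
            w = getattr(self, nm)
            if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
                raise ValidationError(f"{nm} must be a probability vector")

    @property
    def stationary_latent(self) -> float:
        """Long-run probability of the latent eosinophilic state."""
        denom = self.p_ne + self.p_en
        return self.p_ne / denom if denom > 0 else 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k in (
            "ics_levels",
            "ics_initial_weights",
            "ocs_levels",
            "ocs_initial_weights",
        ):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def paper_cohort_config(
    seed: int = 0, n_patients: int = 9570
) -> GeneratorConfig:
    """Configuration calibrated to the published cohort's structure.

    Category fractions (intact-positive at 1.2%/2.3%, FEG-positive with
    and without an intact differential, few vs moderate/many grades) and
    the patient-level emergence fractions were matched to the published
    values by least squares on the closed-form expectations; cohort
    dimensions mirror the source database (9570 patients, 31% sampled
    multiply, mean 3.7 samples per multi-sample patient, ~17,700 samples).
    """
    return GeneratorConfig(seed=seed, n_patients=n_patients)


def noiseless_config(
    seed: int = 0,
    n_patients: int = 2000,
    p_ne: float = 0.3,
    p_en: float = 0.2,
    multi_sample_fraction: float = 1.0,
) -> GeneratorConfig:
    """Configuration with a noise-free observation channel.

    Observed calls coincide with the latent state at both standard
    thresholds: no masking, no degenerated samples, well-separated eos %
    distributions, no FEGs.  Used for parameter-recovery checks where the
    estimand is the latent chain itself.
    """
    return GeneratorConfig(
        seed=seed,
        n_patients=n_patients,
        multi_sample_fraction=multi_sample_fraction,
        p_ne=p_ne,
        p_en=p_en,
        masking_prob=0.0,
        p_nonviable=0.0,
        eos_median_neg=0.10,
        eos_sigma_neg=0.05,
        eos_median_pos=20.0,
        eos_sigma_pos=0.10,
        feg_rate_viable_neg=0.0,
        feg_rate_viable_pos=0.0,
        feg_rate_nonviable_neg=0.0,
        feg_rate_nonviable_pos=0.0,
    )


# ---------------------------------------------------------------------------
# sampling


def _draw_series_length(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    if rng.random() >= cfg.multi_sample_fraction:
        return 1
    # zero-truncated geometric on {1, 2, ...} shifted to lengths >= 2
    return 1 + int(rng.geometric(cfg.series_length_geom_p))


def _draw_eos(
    cfg: GeneratorConfig, positive: bool, rng: np.random.Generator
) -> float:
    if positive:
        med, sig = cfg.eos_median_pos, cfg.eos_sigma_pos
    else:
        med, sig = cfg.eos_median_neg, cfg.eos_sigma_neg
    value = med * math.exp(sig * rng.standard_normal())
    return round(min(value, cfg.eos_cap), 2)


def _draw_differential(
    cfg: GeneratorConfig,
    eos: float,
    elevated_neut: bool,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Neutrophil, macrophage, lymphocyte, epithelial %, summing with eos
    to exactly 100 after 2-decimal rounding."""
    remaining = 100.0 - eos
    cutoff = cfg.neutrophil_cutoff
    if elevated_neut and remaining * 0.98 > cutoff:
        neut = rng.uniform(cutoff, remaining * 0.98)
    elif elevated_neut:
        neut = remaining * 0.9
    else:
        hi = min(cutoff, remaining * 0.95)
        neut = rng.uniform(min(0.2, hi), hi)
    rest = remaining - neut
    macro = rest * rng.uniform(0.85, 0.97)
    lymph = (rest - macro) * rng.uniform(0.3, 0.9)
    neut = round(neut, 2)
    macro = round(macro, 2)
    lymph = round(lymph, 2)
    epith = round(100.0 - eos - neut - macro - lymph, 2)
    if epith < 0:  # rounding spill
        macro = round(macro + epith, 2)
        epith = 0.0
    return neut, macro, lymph, epith


def _step_dose(
    level_idx: int, cfg: GeneratorConfig, rng: np.random.Generator
) -> int:
    if level_idx > 0 and rng.random() < cfg.dose_step_down_prob:
        return level_idx - 1
    return level_idx


def generate_cohort(
    cfg: GeneratorConfig,
    seed: Optional[int] = None,
) -> tuple[Cohort, dict]:
    """Generate a cohort and its ground-truth ledger.

    Returns ``(cohort, ledger)``.  The ledger records, per patient, the
    latent state and mask indicator at every visit, plus the true chain
    parameters and the full configuration, so tests can score recovery of
    any pipeline estimate.  ``seed`` overrides ``cfg.seed`` when given.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pi = cfg.stationary_latent
    base_date = _dt.date(2005, 1, 1)
    series_list: list[PatientSeries] = []
    truth_states: dict[str, list[int]] = {}
    truth_masked: dict[str, list[int]] = {}
    n_masked_visits = 0
    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        k = _draw_series_length(cfg, rng)
        start = base_date + _dt.timedelta(days=int(rng.integers(0, 3650)))
        ics_idx = int(rng.choice(len(cfg.ics_levels),
                                 p=np.asarray(cfg.ics_initial_weights)))
        ocs_idx = int(rng.choice(len(cfg.ocs_levels),
                                 p=np.asarray(cfg.ocs_initial_weights)))
        state = int(rng.random() < pi)
        date = start
        samples = []
        states: list[int] = []
        masks: list[int] = []
        for visit in range(k):
            if visit > 0:
                flip = cfg.p_ne if state == 0 else cfg.p_en
                if rng.random() < flip:
                    state = 1 - state
                date = date + _dt.timedelta(days=int(rng.integers(30, 400)))
                ics_idx = _step_dose(ics_idx, cfg, rng)
                ocs_idx = _step_dose(ocs_idx, cfg, rng)
            masked = state == 1 and rng.random() < cfg.masking_prob
            n_masked_visits += masked
            viable = rng.random() >= cfg.p_nonviable
            feg_seen = rng.random() >= cfg.feg_missing_prob
            if viable:
                rate = (
                    cfg.feg_rate_viable_pos
                    if state
                    else cfg.feg_rate_viable_neg
                )
            else:
                rate = (
                    cfg.feg_rate_nonviable_pos
                    if state
                    else cfg.feg_rate_nonviable_neg
                )
            clumps = int(rng.poisson(rate)) if feg_seen else None
            eos = _draw_eos(cfg, positive=bool(state) and not masked, rng=rng)
            elevated = (
                rng.random() < cfg.mask_neutrophil_coupling
                if masked
                else rng.random() < cfg.neutrophil_elevated_fraction
            )
            if viable:
                neut, macro, lymph, epith = _draw_differential(
                    cfg, eos, elevated, rng
                )
            else:
                eos = neut = macro = lymph = epith = None
            sample = SputumSample(
                patient_id=pid,
                exam_date=date,
                differential_viable=viable,
                total_cell_count=round(
                    6.0 * math.exp(1.1 * rng.standard_normal()), 1
                ),
                viability_pct=round(100.0 * rng.beta(3.0, 1.0), 1),
                squamous_pct=round(100.0 * rng.beta(1.0, 6.0), 1),
                neutrophil_pct=neut,
                eosinophil_pct=eos,
                macrophage_pct=macro,
                lymphocyte_pct=lymph,
                bronchial_epithelial_pct=epith,
                feg_clumps_per_fov=clumps,
                ics_dose=cfg.ics_levels[ics_idx],
                ocs_dose=cfg.ocs_levels[ocs_idx],
                clinical_state=(
                    ClinicalState.EXACERBATION
                    if rng.random() < cfg.exacerbation_prob
                    else ClinicalState.STABLE
                ),
            )
            samples.append(sample)
            states.append(state)
            masks.append(int(masked))
        series_list.append(PatientSeries(patient_id=pid,
                                         samples=tuple(samples)))
        truth_states[pid] = states
        truth_masked[pid] = masks
    cohort = Cohort(series_list)
    ledger = {
        "config": cfg.to_dict(),
        "true_p_ne": cfg.p_ne,
        "true_p_en": cfg.p_en,
        "stationary_latent": pi,
        "n_patients": cohort.n_patients,
        "n_samples": cohort.n_samples,
        "n_masked_visits": int(n_masked_visits),
        "latent_states": truth_states,
        "masked_visits": truth_masked,
    }
    return cohort, ledger


def write_ledger(ledger: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=1)


# ---------------------------------------------------------------------------
# analytic expectations


def _lognorm_sf(cut: float, median: float, sigma: float) -> float:
    if median <= 0:
        return 0.0
    if sigma == 0:
        return float(median >= cut)
    return float(stats.norm.sf(math.log(cut / median) / sigma))


def _emissions(cfg: GeneratorConfig, spec: ThresholdSpec) -> dict:
    """Per-latent-state probabilities of the observed call categories
    (eosinophilic / negative / indeterminate) and of the tally
    categories, exact under the generator's observation model."""
    cut = spec.intact_cutoff
    # qualifying clump counts: any grade <=> >=1 clump; moderate/many <=> >=3
    from .cohort import FegGrade

    qual_min = 1 if FegGrade.FEW in spec.qualifying_feg_grades else 3
    v = 1.0 - cfg.p_nonviable
    seen = 1.0 - cfg.feg_missing_prob
    out = {}
    for state in (0, 1):
        if state:
            p_eos = (1.0 - cfg.masking_prob) * _lognorm_sf(
                cut, cfg.eos_median_pos, cfg.eos_sigma_pos
            ) + cfg.masking_prob * _lognorm_sf(
                cut, cfg.eos_median_neg, cfg.eos_sigma_neg
            )
            r_v, r_nv = cfg.feg_rate_viable_pos, cfg.feg_rate_nonviable_pos
        else:
            p_eos = _lognorm_sf(cut, cfg.eos_median_neg, cfg.eos_sigma_neg)
            r_v, r_nv = cfg.feg_rate_viable_neg, cfg.feg_rate_nonviable_neg
        q_v = float(stats.poisson.sf(qual_min - 1, r_v)) if r_v > 0 else 0.0
        q_nv = float(stats.poisson.sf(qual_min - 1, r_nv)) if r_nv > 0 else 0.0
        few_nv = float(
            stats.poisson.pmf(1, r_nv) + stats.poisson.pmf(2, r_nv)
        )
        mm_nv = float(stats.poisson.sf(2, r_nv))
        p_pos = v * (p_eos + (1 - p_eos) * seen * q_v) + (
            1 - v
        ) * seen * q_nv
        p_ind = (1 - v) * cfg.feg_missing_prob
        out[state] = {
            "call_pos": p_pos,
            "call_ind": p_ind,
            "call_neg": 1.0 - p_pos - p_ind,
            "intact_pos": v * p_eos,
            "feg_with_diff": v * (1 - p_eos) * seen * q_v,
            "nonviable_few": (1 - v) * seen * few_nv,
            "nonviable_modmany": (1 - v) * seen * mm_nv,
        }
    return out


def _patient_emergence_prob(
    cfg: GeneratorConfig, em: dict, length: int
) -> float:
    """P(>=1 emergence event in a series of the given length), by forward
    recursion over (latent state, observed call category), forbidding the
    event pair (negative -> eosinophilic); pairs touching an
    indeterminate call are skipped, matching the default scan policy."""
    cats = ("call_pos", "call_neg", "call_ind")
    pi = cfg.stationary_latent
    start = {(l, c): (pi if l else 1 - pi) * em[l][c]
             for l in (0, 1) for c in cats}
    T = {
        (0, 0): 1 - cfg.p_ne,
        (0, 1): cfg.p_ne,
        (1, 0): cfg.p_en,
        (1, 1): 1 - cfg.p_en,
    }
    f = start
    for _ in range(length - 1):
        nxt = {(l2, c2): 0.0 for l2 in (0, 1) for c2 in cats}
        for (l1, c1), mass in f.items():
            if mass == 0.0:
                continue
            for l2 in (0, 1):
                step = mass * T[(l1, l2)]
                for c2 in cats:
                    if c1 == "call_neg" and c2 == "call_pos":
                        continue  # would be an emergence event
                    nxt[(l2, c2)] += step * em[l2][c2]
        f = nxt
    return 1.0 - sum(f.values())


def closed_form_expectations(
    cfg: GeneratorConfig,
    thresholds: Sequence[ThresholdSpec] = DEFAULT_THRESHOLDS,
    max_series_length: int = 400,
) -> dict:
    """Analytic expectations implied by a configuration.

    Exact under the generator's own assumptions (stationary latent
    initialization, per-visit conditionally independent observations).
    Per threshold: expected tally-category fractions, call prevalence,
    stationary per-pair emergence probability, and the patient-level
    probability of at least one emergence event averaged over the
    multi-sample series-length distribution.  Also reports the latent
    stationary prevalence and expected series-length moments.
    """
    pi = cfg.stationary_latent
    p = cfg.series_length_geom_p
    # multi length = 1 + G, G ~ Geometric(p) on {1, 2, ...}
    mean_multi = 1.0 + 1.0 / p
    out = {
        "stationary_latent": pi,
        "mean_multi_series_length": mean_multi,
        "expected_samples_per_patient": (
            (1 - cfg.multi_sample_fraction)
            + cfg.multi_sample_fraction * mean_multi
        ),
        "thresholds": {},
    }
    # geometric length weights, truncated when the tail is negligible
    weights = []
    for g in range(1, max_series_length):
        w = (1 - p) ** (g - 1) * p
        weights.append((1 + g, w))
        if (1 - p) ** g < 1e-12:
            break
    wsum = sum(w for _, w in weights)
    for spec in thresholds:
        em = _emissions(cfg, spec)
        marg = {
            key: pi * em[1][key] + (1 - pi) * em[0][key]
            for key in em[0]
        }
        # stationary consecutive-pair emergence probability
        T = [[1 - cfg.p_ne, cfg.p_ne], [cfg.p_en, 1 - cfg.p_en]]
        pair_q = sum(
            (pi if l1 else 1 - pi)
            * em[l1]["call_neg"]
            * T[l1][l2]
            * em[l2]["call_pos"]
            for l1 in (0, 1)
            for l2 in (0, 1)
        )
        emergence = (
            sum(
                w * _patient_emergence_prob(cfg, em, k) for k, w in weights
            )
            / wsum
        )
        out["thresholds"][spec.name] = {
            "frac_intact_pos": marg["intact_pos"],
            "frac_feg_with_diff": marg["feg_with_diff"],
            "frac_nonviable_few": marg["nonviable_few"],
            "frac_nonviable_modmany": marg["nonviable_modmany"],
            "frac_indeterminate": marg["call_ind"],
            "call_prevalence": marg["call_pos"],
            "pair_emergence_prob": pair_q,
            "patient_emergence_fraction": emergence,
        }
    return out
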