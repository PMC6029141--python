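"""Virtual neonatal ICU cohorts with the study's demographic, dosing and
sampling structure.

Marginal demographic distributions mirror the published cohort summary:
gestational age from a truncated normal, postnatal age lognormal, weight an
increasing function of postmenstrual age (a scaled median growth curve)
with lognormal noise, creatinine lognormal.  Dosing is 10–15 mg/kg q8h or
q12h as 2-h infusions; peak/trough samples are drawn after at least four
doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .dosing_design import interp_weight_for_pma
from .foce_engine import _add_residual_noise
from .pk_structural import (
    FINAL_THETA,
    FixedEffects,
    PopModel,
    ResidualSpec,
    StructuralParams,
    base_model,
    final_model,
    predict_concentration,
)
from .types import (
    ConcentrationObservation,
    CovariateState,
    DoseEvent,
    PopulationDataset,
    SubjectRecord,
    ValidationError,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Generating parameters; defaults mirror the study cohort."""

    n_subjects: int = 80
    seed: int = 1

    # demographics (weeks, days, kg, μmol/L)
    ga_mean: float = 34.7
    ga_sd: float = 4.31
    ga_range: tuple = (25.7, 41.1)
    pna_median: float = 24.0
    pna_sigma: float = 0.77  # sd of log(PNA)
    pna_range: tuple = (4.0, 126.0)
    pma_range: tuple = (29.0, 47.1)
    wt_range: tuple = (1.4, 5.6)
    wt_scale: float = 0.80  # ICU cohort runs below the reference growth curve
    wt_noise_sd: float = 0.10  # lognormal sd on weight
    scr_mean: float = 23.2
    scr_sd: float = 10.4
    scr_median: Optional[float] = None  # overrides mean/sd targeting when set
    scr_range: tuple = (5.85, 61.6)
    female_fraction: float = 26.0 / 80.0
    include_extras: bool = True  # labs (BUN/ALB/AST/ALT) and comedication flags
    time_varying_scr: bool = False
    scr_drift_sd: float = 0.2

    # dosing and sampling
    dose_per_kg_range: tuple = (10.0, 15.0)
    intervals: tuple = (8.0, 12.0)
    infusion_duration: float = 2.0
    n_doses: int = 7
    samples_per_subject: int = 2
    trough_fraction: float = 75.0 / 165.0

    # truth
    theta: FixedEffects = field(default_factory=lambda: FINAL_THETA)
    omega_cv: float = 37.9  # % CV of clearance IIV
    sigma_cv: float = 37.5  # % CV of proportional residual error
    residual_form: str = "proportional"
    truth_model: Optional[PopModel] = None  # defaults to the final structure

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_doses < 5:
            raise ConfigurationError("need at least 5 doses to sample after the 4th")
        for lo, hi in (self.ga_range, self.pna_range, self.wt_range, self.scr_range):
            if lo >= hi:
                raise ConfigurationError("empty truncation region")

    def resolved_truth_model(self) -> PopModel:
        return self.truth_model if self.truth_model is not None else final_model(self.theta)

    @property
    def omega2(self) -> float:
        return (self.omega_cv / 100.0) ** 2

    @property
    def sigma2(self) -> float:
        return (self.sigma_cv / 100.0) ** 2


@dataclass
class TruthRecord:
    """Generating values stored alongside a simulated dataset."""

    subject_ids: list
    eta: np.ndarray
    cl_true: np.ndarray
    v_true: np.ndarray
    noise_free: dict  # subject id -> noiseless predictions at sample times
    config: CohortConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ID": self.subject_ids,
                "eta": self.eta,
                "CL_true": self.cl_true,
                "V_true": self.v_true,
            }
        )


def _truncated(draw, lo, hi, rng, max_tries=1000):
    """Rejection-sample a scalar from ``draw(rng)`` into [lo, hi]."""
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return x
    raise ConfigurationError(f"truncation region [{lo}, {hi}] too improbable")


def _scr_log_params(config: CohortConfig):
    if config.scr_median is not None:
        mu = math.log(config.scr_median)
        sigma = 0.43
    else:
        cv2 = (config.scr_sd / config.scr_mean) ** 2
        sigma = math.sqrt(math.log1p(cv2))
        mu = math.log(config.scr_mean) - 0.5 * sigma**2
    return mu, sigma


def sample_demographics(config: CohortConfig, rng: np.random.Generator) -> list:
    """Baseline covariate states (time 0), one per subject."""
    mu_scr, sd_scr = _scr_log_params(config)
    mu_pna = math.log(config.pna_median)
    states = []
    for _ in range(config.n_subjects):
        # joint rejection so the PMA range is honored as well
        for _try in range(1000):
            ga = _truncated(
                lambda r: r.normal(config.ga_mean, config.ga_sd), *config.ga_range, rng
            )
            pna = _truncated(
                lambda r: math.exp(r.normal(mu_pna, config.pna_sigma)),
                *config.pna_range,
                rng,
            )
            pma = ga + pna / 7.0
            if config.pma_range[0] <= pma <= config.pma_range[1]:
                break
        else:
            raise ConfigurationError("could not draw a PMA inside the configured range")
        wt_det = config.wt_scale * interp_weight_for_pma(pma)
        wt = _truncated(
            lambda r: wt_det * math.exp(r.normal(0.0, config.wt_noise_sd)),
            *config.wt_range,
            rng,
            max_tries=200,
        ) if config.wt_range[0] <= wt_det <= config.wt_range[1] else float(
            np.clip(wt_det * math.exp(rng.normal(0.0, config.wt_noise_sd)), *config.wt_range)
        )
        scr = _truncated(
            lambda r: math.exp(r.normal(mu_scr, sd_scr)), *config.scr_range, rng
        )
        sex = "female" if rng.random() < config.female_fraction else "male"
        labs = {}
        comeds = frozenset()
        if config.include_extras:
            labs = {
                "BUN": float(np.clip(math.exp(rng.normal(math.log(4.1), 0.65)), 0.4, 28.5)),
                "ALB": float(np.clip(rng.normal(32.4, 5.49), 21.6, 46.8)),
                "AST": float(np.clip(math.exp(rng.normal(math.log(18.0), 0.9)), 3.0, 575.0)),
                "ALT": float(np.clip(math.exp(rng.normal(math.log(41.0), 0.9)), 9.0, 696.0)),
            }
            comeds = frozenset(
                c
                for c, p in (
                    ("ceftriaxone", 0.25),
                    ("meropenem", 0.20),
                    ("gentamicin", 0.15),
                    ("furosemide", 0.20),
                    ("ibuprofen", 0.10),
                    ("dexamethasone", 0.10),
                )
                if rng.random() < p
            )
        states.append(
            CovariateState(
                time=0.0, WT=wt, Scr=scr, GA=ga, PNA=pna, PMA=pma, sex=sex,
                comeds=comeds, labs=labs,
            )
        )
    return states


def build_regimen(state: CovariateState, config: CohortConfig, rng: np.random.Generator) -> list:
    """Maintenance regimen: one mg/kg level per subject, q8h or q12h."""
    mg_per_kg = rng.uniform(*config.dose_per_kg_range)
    interval = float(rng.choice(config.intervals))
    amount = mg_per_kg * state.WT
    return [
        DoseEvent(start_time=i * interval, amount=amount, duration=config.infusion_duration)
        for i in range(config.n_doses)
    ]


def schedule_samples(regimen: list, config: CohortConfig, rng=None) -> list:
    """(time, kind) sampling slots, only after the 4th dose.

    Peaks are 1 h after the end of infusion; troughs 0.5 h before the next
    dose.  Without an rng the kinds alternate peak/trough deterministically;
    with one they are drawn to match the configured trough fraction.
    """
    if len(regimen) < 5:
        raise ValidationError("regimen must have at least 5 doses")
    interval = regimen[1].start_time - regimen[0].start_time
    samples = []
    dose_idx = 4  # the 5th dose: sampling occurs after at least four doses
    prev_kind = None
    for k in range(config.samples_per_subject):
        if rng is None:
            kind = "peak" if k % 2 == 0 else "trough"
        else:
            kind = "trough" if rng.random() < config.trough_fraction else "peak"
        if kind == prev_kind:
            # a repeated kind moves to the next dosing occasion so sampling
            # times stay distinct
            dose_idx += 1
        dose = regimen[min(dose_idx, len(regimen) - 1)]
        if kind == "peak":
            t = dose.start_time + dose.duration + 1.0
        else:
            t = dose.start_time + interval - 0.5
        samples.append((t, kind))
        prev_kind = kind
    samples.sort()
    return samples


def _advance_state(state: CovariateState, time_h: float, scr: float) -> CovariateState:
    """Covariate state at a later time with ages advanced and Scr updated."""
    return replace(
        state,
        time=time_h,
        Scr=scr,
        PNA=state.PNA + time_h / 24.0,
        PMA=state.PMA + time_h / (24.0 * 7.0),
    )


def simulate_cohort(config: CohortConfig, rng: Optional[np.random.Generator] = None):
    """Generate a cohort; returns (PopulationDataset, TruthRecord)."""
    rng = rng or np.random.default_rng(config.seed)
    truth_model = config.resolved_truth_model()
    truth_theta = np.array([d.init for d in truth_model.param_defs()])
    omega = config.omega_cv / 100.0
    sigma2 = config.sigma2
    residual = (
        ResidualSpec(config.residual_form, sigma2_prop=sigma2)
        if config.residual_form in ("proportional", "exponential")
        else ResidualSpec(config.residual_form, sigma2_add=sigma2)
    ) if sigma2 > 0 else None

    states = sample_demographics(config, rng)
    subjects, etas, cls, vs, noise_free = [], [], [], [], {}
    for i, state in enumerate(states):
        sid = f"S{i + 1:03d}"
        regimen = build_regimen(state, config, rng)
        samples = schedule_samples(regimen, config, rng)
        eta = rng.normal(0.0, omega) if omega > 0 else 0.0

        covariates = [state]
        if config.time_varying_scr:
            t_mid = samples[0][0]
            scr_new = float(
                np.clip(state.Scr * math.exp(rng.normal(0.0, config.scr_drift_sd)),
                        *config.scr_range)
            )
            covariates.append(_advance_state(state, t_mid, scr_new))

        cov_dict = {
            name: np.array([state.value(name)])
            for name in truth_model.covariate_names() | {"WT", "Scr"}
        }
        tvcl, tvv = truth_model.typical_values(truth_theta, cov_dict)
        tvcl = np.atleast_1d(np.asarray(tvcl, dtype=float))
        tvv = np.atleast_1d(np.asarray(tvv, dtype=float))
        params = StructuralParams(cl=float(tvcl[0]) * math.exp(eta), v=float(tvv[0]))

        times = np.array([t for t, _ in samples])
        f = predict_concentration(params, regimen, times)
        if config.time_varying_scr and len(covariates) > 1:
            # recompute with the covariate state active at each sample time
            f = np.array(
                [
                    predict_concentration(
                        StructuralParams(
                            cl=float(
                                truth_model.typical_values(
                                    truth_theta,
                                    {
                                        name: np.array(
                                            [
                                                (covariates[1] if t >= covariates[1].time else state).value(name)
                                            ]
                                        )
                                        for name in truth_model.covariate_names() | {"WT", "Scr"}
                                    },
                                )[0][0]
                            )
                            * math.exp(eta),
                            v=params.v,
                        ),
                        regimen,
                        np.array([t]),
                    )[0]
                    for t in times
                ]
            )
        y = _add_residual_noise(f, residual, rng) if residual is not None else f.copy()

        observations = [
            ConcentrationObservation.from_value(t, float(val), kind)
            for (t, kind), val in zip(samples, y)
        ]
        subjects.append(
            SubjectRecord(id=sid, covariates=covariates, doses=regimen, observations=observations)
        )
        etas.append(eta)
        cls.append(params.cl)
        vs.append(params.v)
        noise_free[sid] = f

    dataset = PopulationDataset(
        subjects=subjects,
        provenance={
            "generator": "synthetic_cohort.simulate_cohort",
            "seed": config.seed,
            "n_subjects": config.n_subjects,
            "omega_cv": config.omega_cv,
            "sigma_cv": config.sigma_cv,
        },
    )
    truth = TruthRecord(
        subject_ids=[s.id for s in subjects],
        eta=np.asarray(etas),
        cl_true=np.asarray(cls),
        v_true=np.asarray(vs),
        noise_free=noise_free,
        config=config,
    )
    return dataset, truth


def null_cohort_config(**overrides) -> CohortConfig:
    """Config whose truth has no covariate effects (for calibration tests)."""
    cfg = CohortConfig(**overrides)
    cfg.truth_model = base_model(cfg.theta.cl_typical, cfg.theta.v_typical)
    return cfg
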