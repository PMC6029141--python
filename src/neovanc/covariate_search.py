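"""Four-step covariate screening.

Step 1 compares size/maturation structures on clearance (simple power,
fixed-0.75 power with a sigmoid maturation factor, weight- and
age-dependent exponents), rejecting unstable candidates (condition number
> 1000 or any RSE > 100%) and ranking the rest by AIC.  Step 2 screens
creatinine as a power versus a linear effect.  Step 3 runs forward
inclusion (ΔOFV > 3.83, χ² df=1, p<0.05) and backward elimination
(ΔOFV > 6.63, p<0.01).  Step 4 tries time-varying refinements of retained
continuous covariates and keeps one only on a conservative ΔOFV > 6.63.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .foce_engine import CompiledCohort, FitResult, compile_dataset, fit
from .pk_structural import CovariateModelSpec, PopModel
from .types import PopulationDataset, RunConfig

CONDITION_LIMIT = 1000.0
RSE_LIMIT = 100.0
FORWARD_DOFV = 3.83
BACKWARD_DOFV = 6.63

AGE_COVARIATES = ("GA", "PNA", "PMA")
# step-3 pool: covariates not already screened in steps 1 (size/age) and 2
# (creatinine)
DEFAULT_CONTINUOUS = ("BUN", "ALB", "AST", "ALT")
DEFAULT_CATEGORICAL = (
    "sex",
    "ceftriaxone",
    "meropenem",
    "gentamicin",
    "furosemide",
    "ibuprofen",
    "dexamethasone",
)


class SearchError(RuntimeError):
    pass


@dataclass
class CandidateResult:
    name: str
    model: PopModel
    fit: FitResult
    stable: bool
    instability_reasons: list = field(default_factory=list)

    def summary(self) -> dict:
        rse = [v for v in self.fit.rse_percent.values() if v is not None]
        return {
            "name": self.name,
            "ofv": self.fit.ofv,
            "aic": self.fit.aic,
            "bic": self.fit.bic,
            "condition_number": self.fit.condition_number,
            "max_rse_percent": max(rse) if rse else None,
            "converged": self.fit.converged,
            "stable": self.stable,
            "reasons": self.instability_reasons,
        }


@dataclass
class SearchStep:
    name: str
    candidates: list  # list[CandidateResult]
    decision: str
    selected: Optional[CandidateResult]
    extra: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "step": self.name,
            "candidates": [c.summary() for c in self.candidates],
            "decision": self.decision,
            "selected": self.selected.name if self.selected else None,
            **self.extra,
        }


@dataclass
class SearchReport:
    steps: list = field(default_factory=list)
    final: Optional[CandidateResult] = None

    @property
    def final_model(self) -> PopModel:
        return self.final.model

    @property
    def final_fit(self) -> FitResult:
        return self.final.fit

    def included_cl_covariates(self) -> list:
        return [t.covariate for t in self.final.model.cl_terms]

    def to_json_dict(self) -> dict:
        return {
            "steps": [s.to_json_dict() for s in self.steps],
            "final_model": self.final.name if self.final else None,
            "final_cl_covariates": self.included_cl_covariates() if self.final else [],
        }

    def decision_log(self) -> str:
        lines = []
        for s in self.steps:
            lines.append(f"== {s.name} ==")
            for c in s.candidates:
                info = c.summary()
                lines.append(
                    f"  {c.name}: OFV={info['ofv']:.2f} AIC={info['aic']:.2f} "
                    f"cond={info['condition_number']:.3g} stable={c.stable}"
                )
            lines.append(f"  decision: {s.decision}")
        return "\n".join(lines)


def _assess_stability(fr: FitResult) -> tuple:
    reasons = []
    if not math.isfinite(fr.condition_number):
        reasons.append("singular covariance (condition number infinite)")
    elif fr.condition_number > CONDITION_LIMIT:
        reasons.append(f"condition number {fr.condition_number:.0f} > {CONDITION_LIMIT:.0f}")
    rses = [v for v in fr.rse_percent.values() if v is not None]
    if len(rses) < len(fr.rse_percent):
        reasons.append("RSEs unavailable")
    if any(v > RSE_LIMIT for v in rses):
        reasons.append(f"max RSE {max(rses):.0f}% > {RSE_LIMIT:.0f}%")
    return (not reasons), reasons


def _fit_candidate(name, model, compiled_full, config, residual_form,
                   compute_se=True, x0=None) -> CandidateResult:
    fr = fit(
        compiled_full,
        model,
        residual_form=residual_form,
        config=config,
        compute_se=compute_se,
        x0_override=x0,
    )
    stable, reasons = _assess_stability(fr) if compute_se else (True, [])
    return CandidateResult(name=name, model=model, fit=fr, stable=stable,
                           instability_reasons=reasons)


def _x0_with_cl_term(current: CandidateResult, term: CovariateModelSpec):
    """Warm start for a fit that appends one CL term to the current model."""
    if current.fit.x_hat is None:
        return None
    from .pk_structural import _LOG_SCALE

    x = np.asarray(current.fit.x_hat, dtype=float)
    pos = 1 + sum(len(t.free_params) for t in current.model.cl_terms)
    inits = [
        math.log(term.params[h]) if h in _LOG_SCALE else term.params[h]
        for h in term.free_params
    ]
    return np.concatenate([x[:pos], inits, x[pos:]])


def _x0_without_cl_covariate(current: CandidateResult, covariate: str):
    """Warm start for a fit that removes one CL covariate."""
    if current.fit.x_hat is None:
        return None
    x = np.asarray(current.fit.x_hat, dtype=float)
    pos = 1
    keep = np.ones(len(x), dtype=bool)
    for t in current.model.cl_terms:
        width = len(t.free_params)
        if t.covariate == covariate:
            keep[pos:pos + width] = False
        pos += width
    return x[keep]


def _median(compiled: CompiledCohort, covariate: str) -> float:
    return float(np.median(compiled.cov[covariate]))


def _power_term(covariate, center, exp_init=0.5, target="CL"):
    return CovariateModelSpec(
        covariate=covariate, target=target, form="power", center=center,
        params={"exp": exp_init},
    )


# ---------------------------------------------------------------------------
# step 1: size / maturation structure
# ---------------------------------------------------------------------------


def step1_size_models(
    dataset,
    config: Optional[RunConfig] = None,
    residual_form: str = "proportional",
    age_covariates: Sequence[str] = ("PMA",),
    cl_init: float = 0.3,
    v_init: float = 2.6,
) -> SearchStep:
    """Fit the four weight/age structures on CL (weight power on V always)."""
    config = config or RunConfig()
    # the maturation / variable-exponent structures are expected to be hard
    # to estimate (that is the point of the stability screen); cap their
    # optimizer budget
    import dataclasses

    capped = dataclasses.replace(config, max_iter=min(config.max_iter, 250))
    needed = {"WT", "Scr"} | set(age_covariates)
    compiled = compile_dataset(dataset, needed) if isinstance(dataset, PopulationDataset) else dataset
    wt_med = _median(compiled, "WT")
    v_term = [_power_term("WT", wt_med, 1.0, target="V")]

    candidates = []

    model1 = PopModel(
        cl_base=cl_init, v_base=v_init,
        cl_terms=[_power_term("WT", wt_med, 0.75)], v_terms=list(v_term), name="I-power",
    )
    candidates.append(_fit_candidate("I-power", model1, compiled, config, residual_form))

    for age in age_covariates:
        age_med = _median(compiled, age)
        model2 = PopModel(
            cl_base=cl_init, v_base=v_init,
            cl_terms=[
                CovariateModelSpec(
                    covariate="WT", target="CL", form="power", center=wt_med,
                    params={"exp": 0.75}, fixed=frozenset({"exp"}),
                ),
                CovariateModelSpec(
                    covariate=age, target="CL", form="maturation",
                    params={"tm50": age_med, "hill": 3.0},
                ),
            ],
            v_terms=list(v_term),
            name=f"II-maturation-{age}",
        )
        candidates.append(
            _fit_candidate(model2.name, model2, compiled, capped, residual_form)
        )

    model3 = PopModel(
        cl_base=cl_init, v_base=v_init,
        cl_terms=[
            CovariateModelSpec(
                covariate="WT", target="CL", form="wt_exponent", center=wt_med,
                params={"exp0": 1.2, "kmax": 0.5, "k50": wt_med, "hill": 2.0},
            )
        ],
        v_terms=list(v_term),
        name="III-wt-exponent",
    )
    candidates.append(_fit_candidate("III-wt-exponent", model3, compiled, capped, residual_form))

    for age in age_covariates:
        age_med = _median(compiled, age)
        model4 = PopModel(
            cl_base=cl_init, v_base=v_init,
            cl_terms=[
                CovariateModelSpec(
                    covariate="WT", target="CL", form="age_exponent", center=wt_med,
                    params={"exp0": 1.2, "kmax": 0.5, "k50": age_med, "hill": 2.0},
                    modifier=age,
                )
            ],
            v_terms=list(v_term),
            name=f"IV-age-exponent-{age}",
        )
        candidates.append(
            _fit_candidate(model4.name, model4, compiled, capped, residual_form)
        )

    stable = [c for c in candidates if c.stable]
    if not stable:
        raise SearchError(
            "all size/maturation structures are unstable; simplify the model "
            "or the candidate set"
        )
    best = min(stable, key=lambda c: c.fit.aic)
    unstable = [c.name for c in candidates if not c.stable]
    decision = f"selected {best.name} by AIC among stable candidates"
    if unstable:
        decision += f"; rejected as unstable: {', '.join(unstable)}"
    return SearchStep(name="step1-size", candidates=candidates, decision=decision,
                      selected=best)


# ---------------------------------------------------------------------------
# step 2: renal function
# ---------------------------------------------------------------------------


def step2_renal_models(
    dataset,
    base: CandidateResult,
    config: Optional[RunConfig] = None,
    residual_form: str = "proportional",
    scr_center: Optional[float] = None,
) -> SearchStep:
    """Creatinine on CL: power versus linear; keep the better fit if it
    clears the forward threshold."""
    config = config or RunConfig()
    compiled = compile_dataset(dataset, base.model.covariate_names() | {"Scr"}) \
        if isinstance(dataset, PopulationDataset) else dataset
    center = scr_center if scr_center is not None else _median(compiled, "Scr")

    power_term = _power_term("Scr", center, -0.3)
    power = base.model.with_cl_term(power_term, name=f"{base.name}+Scr-power")
    linear_term = CovariateModelSpec(covariate="Scr", target="CL", form="linear",
                                     center=center, params={"slope": -0.001})
    linear = base.model.with_cl_term(linear_term, name=f"{base.name}+Scr-linear")
    cands = [
        _fit_candidate(power.name, power, compiled, config, residual_form,
                       x0=_x0_with_cl_term(base, power_term)),
        _fit_candidate(linear.name, linear, compiled, config, residual_form,
                       x0=_x0_with_cl_term(base, linear_term)),
    ]
    dofv = {c.name: base.fit.ofv - c.fit.ofv for c in cands}
    best = min(cands, key=lambda c: c.fit.ofv)
    if dofv[best.name] > FORWARD_DOFV:
        decision = (
            f"retained {best.name} (ΔOFV {dofv[best.name]:.2f} > {FORWARD_DOFV})"
        )
        selected = best
    else:
        decision = (
            f"no creatinine form significant (best ΔOFV {dofv[best.name]:.2f} "
            f"≤ {FORWARD_DOFV}); keeping {base.name}"
        )
        selected = base
    return SearchStep(name="step2-renal", candidates=cands, decision=decision,
                      selected=selected, extra={"delta_ofv": dofv})


# ---------------------------------------------------------------------------
# step 3: forward inclusion / backward elimination
# ---------------------------------------------------------------------------


def _candidate_term(compiled, covariate):
    if covariate in DEFAULT_CATEGORICAL:
        return CovariateModelSpec(
            covariate=covariate, target="CL", form="categorical", params={"ratio": 1.0}
        )
    return _power_term(covariate, max(_median(compiled, covariate), 1e-6), 0.1)


def step3_forward_backward(
    dataset,
    current: CandidateResult,
    candidates: Sequence[str],
    config: Optional[RunConfig] = None,
    residual_form: str = "proportional",
) -> SearchStep:
    """Stepwise search over the remaining covariates.

    Age descriptors (GA/PNA/PMA) are mutually collinear: including one
    drops the others from the pool.  A covariate removed during backward
    elimination may not re-enter.  Ties in ΔOFV break by candidate order.
    """
    config = config or RunConfig()
    pool = [c for c in candidates if c not in {t.covariate for t in current.model.cl_terms}]
    compiled = compile_dataset(
        dataset, current.model.covariate_names() | set(pool) | {"Scr"}
    ) if isinstance(dataset, PopulationDataset) else dataset

    fitted: list = []
    log: list = []
    banned: set = set()

    # forward
    while pool:
        results = []
        for cov in pool:
            term = _candidate_term(compiled, cov)
            model = current.model.with_cl_term(term)
            cand = _fit_candidate(model.name, model, compiled, config, residual_form,
                                  compute_se=False, x0=_x0_with_cl_term(current, term))
            results.append((cov, cand))
            fitted.append(cand)
        dofvs = [(cov, current.fit.ofv - cand.fit.ofv) for cov, cand in results]
        best_cov, best_dofv = max(dofvs, key=lambda t: (t[1],))
        # deterministic tie-break by candidate order
        for cov, d in dofvs:
            if d >= best_dofv - 1e-9:
                best_cov, best_dofv = cov, d
                break
        if best_dofv > FORWARD_DOFV:
            current = dict(results)[best_cov]
            log.append(f"forward: +{best_cov} (ΔOFV {best_dofv:.2f})")
            pool.remove(best_cov)
            if best_cov in AGE_COVARIATES:
                dropped = [c for c in pool if c in AGE_COVARIATES]
                pool = [c for c in pool if c not in AGE_COVARIATES]
                if dropped:
                    log.append(f"forward: dropped collinear age covariates {dropped}")
        else:
            log.append(
                f"forward: stop (best candidate {best_cov}, ΔOFV {best_dofv:.2f} "
                f"≤ {FORWARD_DOFV})"
            )
            break

    # backward: every CL covariate except the step-1 size structure (WT)
    removable = [t.covariate for t in current.model.cl_terms if t.covariate != "WT"]
    changed = True
    while changed and removable:
        changed = False
        for cov in list(removable):
            if cov in banned:
                continue
            reduced = current.model.without_cl_covariate(cov)
            cand = _fit_candidate(reduced.name, reduced, compiled, config, residual_form,
                                  compute_se=False,
                                  x0=_x0_without_cl_covariate(current, cov))
            fitted.append(cand)
            rise = cand.fit.ofv - current.fit.ofv
            if rise <= BACKWARD_DOFV:
                current = cand
                banned.add(cov)
                removable.remove(cov)
                log.append(f"backward: -{cov} (OFV rise {rise:.2f} ≤ {BACKWARD_DOFV})")
                changed = True
            else:
                log.append(f"backward: kept {cov} (OFV rise {rise:.2f} > {BACKWARD_DOFV})")
    decision = "; ".join(log) if log else "no candidates"
    return SearchStep(name="step3-stepwise", candidates=fitted, decision=decision,
                      selected=current, extra={"log": log})


# ---------------------------------------------------------------------------
# step 4: time-varying covariates
# ---------------------------------------------------------------------------


def _has_within_subject_variation(dataset: PopulationDataset, covariate: str) -> bool:
    for s in dataset.subjects:
        vals = {c.value(covariate) for c in s.covariates}
        if len(vals) > 1:
            return True
    return False


def step4_time_varying(
    dataset: PopulationDataset,
    current: CandidateResult,
    config: Optional[RunConfig] = None,
    residual_form: str = "proportional",
) -> SearchStep:
    """Baseline/delta and random-slope refinements of retained continuous
    covariates; a variant is kept only if ΔOFV > 6.63."""
    config = config or RunConfig()
    continuous = [
        t for t in current.model.cl_terms
        if t.form in ("power", "linear") and t.covariate not in DEFAULT_CATEGORICAL
    ]
    cands = []
    notes = []
    compiled = compile_dataset(dataset, current.model.covariate_names())
    for term in continuous:
        cov = term.covariate
        if not _has_within_subject_variation(dataset, cov):
            notes.append(f"{cov}: constant within all subjects; variants skipped")
            continue
        center = term.center
        for form, params, tag in (
            ("tv_baseline_delta", {"b_slope": 0.0, "d_slope": 0.0}, "baseline-delta"),
            ("tv_random", {"slope": 0.0, "omega2_cov": 0.01}, "random-slope"),
        ):
            variant_model = current.model.without_cl_covariate(cov).with_cl_term(
                CovariateModelSpec(covariate=cov, target="CL", form=form,
                                   center=center, params=params),
                name=f"{current.name}~{cov}-{tag}",
            )
            cands.append(
                _fit_candidate(variant_model.name, variant_model, compiled, config,
                               residual_form, compute_se=False)
            )
    selected = current
    decision_parts = list(notes)
    if cands:
        best = min(cands, key=lambda c: c.fit.ofv)
        dofv = current.fit.ofv - best.fit.ofv
        if dofv > BACKWARD_DOFV:
            selected = best
            decision_parts.append(f"retained {best.name} (ΔOFV {dofv:.2f} > {BACKWARD_DOFV})")
        else:
            decision_parts.append(
                f"time-varying variants did not improve the model "
                f"(best ΔOFV {dofv:.2f} ≤ {BACKWARD_DOFV}); static model kept"
            )
    elif not notes:
        decision_parts.append("no continuous covariates eligible")
    return SearchStep(name="step4-time-varying", candidates=cands,
                      decision="; ".join(decision_parts), selected=selected)


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------


def run_search(
    dataset: PopulationDataset,
    config: Optional[RunConfig] = None,
    residual_form: str = "proportional",
    candidates: Optional[Sequence[str]] = None,
    age_covariates: Sequence[str] = ("PMA",),
) -> SearchReport:
    """Full four-step procedure; returns the audit trail and final model."""
    config = config or RunConfig()
    report = SearchReport()

    step1 = step1_size_models(dataset, config, residual_form, age_covariates)
    report.steps.append(step1)

    step2 = step2_renal_models(dataset, step1.selected, config, residual_form)
    report.steps.append(step2)

    if candidates is None:
        available = _available_covariates(dataset)
        candidates = [
            c for c in (*DEFAULT_CONTINUOUS, *DEFAULT_CATEGORICAL) if c in available
        ]
    step3 = step3_forward_backward(dataset, step2.selected, candidates, config,
                                   residual_form)
    report.steps.append(step3)

    step4 = step4_time_varying(dataset, step3.selected, config, residual_form)
    report.steps.append(step4)

    final = step4.selected
    if final.fit.rse_percent and all(v is None for v in final.fit.rse_percent.values()):
        final = _fit_candidate(final.name, final.model,
                               compile_dataset(dataset, final.model.covariate_names()),
                               config, residual_form, compute_se=True)
    report.final = final
    return report


def _available_covariates(dataset: PopulationDataset) -> set:
    out = set()
    state = dataset.subjects[0].baseline
    for name in ("WT", "Scr", "GA", "PNA", "PMA", "sex"):
        out.add(name)
    out |= set(state.labs.keys())
    from .types import COMEDICATIONS

    if any(c.comeds for s in dataset.subjects for c in s.covariates):
        out |= set(COMEDICATIONS)
    return out
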