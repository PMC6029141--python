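"""One-compartment infusion kinetics and the covariate-model grammar.

Pure computation: typical-value covariate submodels (power, maturation,
weight/age-dependent exponents, linear, categorical, time-varying),
closed-form superposition predictions for multi-dose constant-rate
infusions, and steady-state AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FixedEffects",
    "RandomEffectSpec",
    "ResidualSpec",
    "StructuralParams",
    "CovariateModelSpec",
    "PopModel",
    "FINAL_THETA",
    "covariate_factor",
    "typical_clearance",
    "typical_volume",
    "individual_params",
    "predict_concentration",
    "steady_state_auc24",
    "final_model",
    "base_model",
]

WT_REF = 2.9  # kg
SCR_REF = 23.3  # μmol/L


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class FixedEffects:
    """Fixed effects of the clearance/volume covariate model.

    ``cl_scr_exponent`` uses the inverse-power convention: clearance scales
    as ``(scr_ref / Scr) ** cl_scr_exponent`` so a positive value means
    clearance falls as creatinine rises.
    """

    cl_typical: float  # L/h at reference covariates
    cl_wt_exponent: float
    cl_scr_exponent: float
    v_typical: float  # L at reference weight
    v_wt_exponent: float
    wt_ref: float = WT_REF
    scr_ref: float = SCR_REF

    def __post_init__(self) -> None:
        for name in ("cl_typical", "v_typical", "wt_ref", "scr_ref"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


#: published final-model point estimates
FINAL_THETA = FixedEffects(
    cl_typical=0.309,
    cl_wt_exponent=1.55,
    cl_scr_exponent=0.337,
    v_typical=2.63,
    v_wt_exponent=1.05,
)


@dataclass(frozen=True)
class RandomEffectSpec:
    """Lognormal inter-individual variability on clearance."""

    omega2_cl: float = 0.0

    def __post_init__(self) -> None:
        if self.omega2_cl < 0:
            raise DomainError("omega2_cl must be >= 0")

    @property
    def cv_percent(self) -> float:
        return 100.0 * math.sqrt(self.omega2_cl)

    @staticmethod
    def from_cv_percent(cv: float) -> "RandomEffectSpec":
        return RandomEffectSpec(omega2_cl=(cv / 100.0) ** 2)


@dataclass(frozen=True)
class ResidualSpec:
    """Residual error model.

    ``exponential`` is handled via its first-order proportional equivalent
    (standard deviation ``sigma * IPRED``); ``proportional`` is accepted as
    an alias.  ``combined`` adds an additive component.
    """

    form: str = "exponential"  # additive | exponential | proportional | combined
    sigma2_prop: float = 0.0
    sigma2_add: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("additive", "exponential", "proportional", "combined"):
            raise DomainError(f"unknown residual form {self.form!r}")
        if self.sigma2_prop < 0 or self.sigma2_add < 0:
            raise DomainError("residual variances must be >= 0")
        if self.sigma2_prop == 0 and self.sigma2_add == 0:
            raise DomainError("at least one residual variance must be positive")
        if self.form == "additive" and self.sigma2_add == 0:
            raise DomainError("additive form requires sigma2_add > 0")
        if self.form in ("exponential", "proportional") and self.sigma2_prop == 0:
            raise DomainError("proportional form requires sigma2_prop > 0")

    def variance(self, ipred):
        """Residual variance at a (conditional) prediction."""
        ipred = np.asarray(ipred, dtype=float)
        if self.form == "additive":
            return np.full_like(ipred, self.sigma2_add)
        if self.form in ("exponential", "proportional"):
            return self.sigma2_prop * ipred**2
        return self.sigma2_prop * ipred**2 + self.sigma2_add

    @property
    def prop_cv_percent(self) -> float:
        return 100.0 * math.sqrt(self.sigma2_prop)


@dataclass(frozen=True)
class StructuralParams:
    cl: float  # L/h
    v: float  # L

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.v <= 0:
            raise DomainError("CL and V must be > 0")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.cl / self.v


# ---------------------------------------------------------------------------
# covariate-model grammar
# ---------------------------------------------------------------------------

_FORM_PARAMS = {
    "power": ("exp",),
    "maturation": ("tm50", "hill"),
    "wt_exponent": ("exp0", "kmax", "k50", "hill"),
    "age_exponent": ("exp0", "kmax", "k50", "hill"),
    "linear": ("slope",),
    "categorical": ("ratio",),
    "tv_baseline_delta": ("b_slope", "d_slope"),
    "tv_random": ("slope", "omega2_cov"),
}

# hyperparameters kept strictly positive during estimation (log transform)
_LOG_SCALE = {"tm50", "hill", "kmax", "k50", "ratio", "omega2_cov"}


@dataclass(frozen=True)
class CovariateModelSpec:
    """One covariate–parameter relationship.

    forms
        power               (COV/center)**exp
        maturation          sigmoid factor rising 0→1 with the covariate,
                            0.5 at ``tm50`` (see ``as_printed`` for the
                            falling variant)
        wt_exponent         power of COV with exponent
                            exp0 − kmax·COV^hill/(k50^hill + COV^hill)
        age_exponent        as wt_exponent but the exponent is driven by a
                            second covariate (``modifier``)
        linear              additive term slope·(COV − center) on the target
        categorical         1 at the reference level (value 0), ``ratio``
                            otherwise
        tv_baseline_delta   1 + b_slope·(BCOV − center) + d_slope·(COV − BCOV)
        tv_random           1 + slope·exp(η_cov)·(COV − center); during
                            estimation η_cov is handled by a first-order
                            variance contribution with variance omega2_cov
    """

    covariate: str
    target: str  # "CL" | "V"
    form: str
    center: float = 1.0
    params: dict = field(default_factory=dict)
    fixed: frozenset = frozenset()
    modifier: Optional[str] = None  # second covariate for age_exponent
    as_printed: bool = False  # maturation: use the falling orientation

    def __post_init__(self) -> None:
        if self.form not in _FORM_PARAMS:
            raise DomainError(f"unknown covariate model form {self.form!r}")
        missing = [p for p in _FORM_PARAMS[self.form] if p not in self.params]
        if missing:
            raise DomainError(f"{self.form} form requires hyperparameters {missing}")
        if self.target not in ("CL", "V"):
            raise DomainError("target must be 'CL' or 'V'")
        if "hill" in self.params and self.params["hill"] <= 0:
            raise DomainError("hill must be > 0")
        if self.form == "age_exponent" and self.modifier is None:
            raise DomainError("age_exponent form requires a modifier covariate")

    @property
    def is_multiplicative(self) -> bool:
        return self.form != "linear"

    @property
    def free_params(self) -> tuple:
        return tuple(p for p in _FORM_PARAMS[self.form] if p not in self.fixed)

    def label(self, hyper: str) -> str:
        return f"{self.target}.{self.covariate}.{hyper}"


def _dexp(exp0, kmax, k50, hill, x):
    x = np.asarray(x, dtype=float)
    return exp0 - kmax * x**hill / (k50**hill + x**hill)


def covariate_factor(
    spec: CovariateModelSpec,
    value,
    baseline=None,
    eta_cov: float = 0.0,
    modifier=None,
    params: Optional[dict] = None,
):
    """Evaluate one covariate term.

    Returns a dimensionless multiplier for all multiplicative forms and the
    additive term (same units as the target parameter) for the linear form.
    ``params`` overrides the spec's hyperparameter values (used during
    estimation); vectorized over ``value``.
    """
    p = dict(spec.params)
    if params:
        p.update(params)
    v = np.asarray(value, dtype=float)
    form = spec.form

    if form in ("power", "maturation", "wt_exponent", "age_exponent") and np.any(v <= 0):
        raise DomainError(f"{spec.covariate}: power-form covariate must be > 0")

    if form == "power":
        return (v / spec.center) ** p["exp"]
    if form == "maturation":
        tm50, hill = p["tm50"], p["hill"]
        if spec.as_printed:
            # falling orientation, exactly as the source prints it
            return 1.0 / (1.0 + (v / tm50) ** hill)
        return 1.0 / (1.0 + (tm50 / v) ** hill)
    if form == "wt_exponent":
        exponent = _dexp(p["exp0"], p["kmax"], p["k50"], p["hill"], v)
        return (v / spec.center) ** exponent
    if form == "age_exponent":
        if modifier is None:
            raise DomainError("age_exponent requires the modifier covariate value")
        exponent = _dexp(p["exp0"], p["kmax"], p["k50"], p["hill"], modifier)
        return (v / spec.center) ** exponent
    if form == "linear":
        return p["slope"] * (v - spec.center)
    if form == "categorical":
        return np.where(v > 0.5, p["ratio"], 1.0)
    if form == "tv_baseline_delta":
        b = v if baseline is None else np.asarray(baseline, dtype=float)
        delta = v - b
        return 1.0 + p["b_slope"] * (b - spec.center) + p["d_slope"] * delta
    if form == "tv_random":
        return 1.0 + p["slope"] * math.exp(eta_cov) * (v - spec.center)
    raise AssertionError(form)


# ---------------------------------------------------------------------------
# final-model typical values (worked equations)
# ---------------------------------------------------------------------------


def typical_clearance(wt, scr, theta: FixedEffects = FINAL_THETA):
    """Typical clearance (L/h) at weight ``wt`` kg and creatinine ``scr`` μmol/L."""
    wt = np.asarray(wt, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(wt <= 0) or np.any(scr <= 0):
        raise DomainError("WT and Scr must be > 0")
    return (
        theta.cl_typical
        * (wt / theta.wt_ref) ** theta.cl_wt_exponent
        * (theta.scr_ref / scr) ** theta.cl_scr_exponent
    )


def typical_volume(wt, theta: FixedEffects = FINAL_THETA):
    """Typical volume of distribution (L) at weight ``wt`` kg."""
    wt = np.asarray(wt, dtype=float)
    if np.any(wt <= 0):
        raise DomainError("WT must be > 0")
    return theta.v_typical * (wt / theta.wt_ref) ** theta.v_wt_exponent


def individual_params(theta: FixedEffects, eta_cl: float, wt: float, scr: float) -> StructuralParams:
    """Individual CL/V: typical values with lognormal η on clearance only."""
    cl = float(typical_clearance(wt, scr, theta)) * math.exp(eta_cl)
    v = float(typical_volume(wt, theta))
    return StructuralParams(cl=cl, v=v)


# ---------------------------------------------------------------------------
# structural predictions
# ---------------------------------------------------------------------------


def predict_concentration(params: StructuralParams, doses: Sequence, times):
    """Concentration (mg/L) by superposition of constant-rate infusions.

    Each dose contributes ``(R/CL)(1 − e^{−ke·te}) e^{−ke·τ}`` where ``te``
    is the elapsed infusion time (capped at the duration) and ``τ`` the time
    since the infusion ended.  Times before the first dose predict 0.
    """
    t = np.asarray(times, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    conc = np.zeros_like(t)
    ke = params.ke
    for d in doses:
        dt = t - d.start_time
        te = np.clip(dt, 0.0, d.duration)
        tau = np.maximum(dt - d.duration, 0.0)
        conc += (d.rate / params.cl) * (-np.expm1(-ke * te)) * np.exp(-ke * tau)
    return conc[0] if scalar else conc


def steady_state_auc24(daily_dose: float, cl: float) -> float:
    """Steady-state 24-h area under the curve, mg·h/L."""
    if cl <= 0:
        raise DomainError("CL must be > 0")
    return daily_dose / cl


# ---------------------------------------------------------------------------
# assembled population model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamDef:
    name: str
    init: float
    log_scale: bool


@dataclass
class PopModel:
    """Typical-value model for CL and V assembled from covariate terms.

    The estimation engine sees a flat vector of free structural parameters
    (base typicals plus the free hyperparameters of every term, in order);
    variance parameters are appended by the engine itself.
    """

    cl_base: float
    v_base: float
    cl_terms: list = field(default_factory=list)
    v_terms: list = field(default_factory=list)
    name: str = "model"

    def param_defs(self) -> list:
        defs = [ParamDef("CL.typical", self.cl_base, True)]
        for term in self.cl_terms:
            for hyper in term.free_params:
                defs.append(
                    ParamDef(term.label(hyper), term.params[hyper], hyper in _LOG_SCALE)
                )
        defs.append(ParamDef("V.typical", self.v_base, True))
        for term in self.v_terms:
            for hyper in term.free_params:
                defs.append(
                    ParamDef(term.label(hyper), term.params[hyper], hyper in _LOG_SCALE)
                )
        return defs

    @property
    def n_theta(self) -> int:
        return len(self.param_defs())

    def covariate_names(self) -> set:
        names = set()
        for term in self.cl_terms + self.v_terms:
            names.add(term.covariate)
            if term.modifier:
                names.add(term.modifier)
        return names

    def _split_theta(self, theta: np.ndarray):
        """Map the flat free-parameter vector back onto terms."""
        it = iter(theta)
        cl_base = next(it)
        cl_hyper = []
        for term in self.cl_terms:
            d = dict(term.params)
            for hyper in term.free_params:
                d[hyper] = next(it)
            cl_hyper.append(d)
        v_base = next(it)
        v_hyper = []
        for term in self.v_terms:
            d = dict(term.params)
            for hyper in term.free_params:
                d[hyper] = next(it)
            v_hyper.append(d)
        return cl_base, cl_hyper, v_base, v_hyper

    def typical_values(self, theta, cov: dict, cov_baseline: Optional[dict] = None):
        """Per-observation typical CL and V.

        ``cov`` maps covariate name → per-observation array; ``cov_baseline``
        the per-observation baseline values (defaults to ``cov``).  Linear
        terms are additive and floored at 1% of the multiplicative part so
        the parameter stays positive for extreme covariates.
        """
        theta = np.asarray(theta, dtype=float)
        cov_baseline = cov_baseline or cov
        cl_base, cl_hyper, v_base, v_hyper = self._split_theta(theta)

        out = []
        for base, terms, hypers in (
            (cl_base, self.cl_terms, cl_hyper),
            (v_base, self.v_terms, v_hyper),
        ):
            mult = base
            add = 0.0
            for term, hyper in zip(terms, hypers):
                value = cov[term.covariate]
                modifier = cov[term.modifier] if term.modifier else None
                fac = covariate_factor(
                    term,
                    value,
                    baseline=cov_baseline.get(term.covariate),
                    modifier=modifier,
                    params=hyper,
                )
                if term.is_multiplicative:
                    mult = mult * fac
                else:
                    add = add + fac
            out.append(np.maximum(mult + add, 0.01 * mult))
        return out[0], out[1]

    def eta_cov_sensitivity(self, theta, cov: dict):
        """First-order η_cov sensitivity of CL for tv_random terms.

        Returns (relative dCL/dη_cov at η_cov = 0 per observation, ω²_cov)
        or (None, 0) when no tv_random term is present on CL.
        """
        tv_terms = [t for t in self.cl_terms if t.form == "tv_random"]
        if not tv_terms:
            return None, 0.0
        term = tv_terms[0]
        _, cl_hyper, _, _ = self._split_theta(np.asarray(theta, dtype=float))
        hyper = cl_hyper[self.cl_terms.index(term)]
        v = np.asarray(cov[term.covariate], dtype=float)
        fac = 1.0 + hyper["slope"] * (v - term.center)
        sens = hyper["slope"] * (v - term.center) / np.maximum(fac, 1e-6)
        return sens, hyper["omega2_cov"]

    def with_cl_term(self, term: CovariateModelSpec, name: Optional[str] = None) -> "PopModel":
        return PopModel(
            cl_base=self.cl_base,
            v_base=self.v_base,
            cl_terms=[*self.cl_terms, term],
            v_terms=list(self.v_terms),
            name=name or f"{self.name}+{term.covariate}",
        )

    def without_cl_covariate(self, covariate: str) -> "PopModel":
        return PopModel(
            cl_base=self.cl_base,
            v_base=self.v_base,
            cl_terms=[t for t in self.cl_terms if t.covariate != covariate],
            v_terms=list(self.v_terms),
            name=f"{self.name}-{covariate}",
        )


def base_model(cl_init: float = 0.3, v_init: float = 2.6) -> PopModel:
    """Covariate-free one-compartment model."""
    return PopModel(cl_base=cl_init, v_base=v_init, name="base")


def final_model(theta: FixedEffects = FINAL_THETA) -> PopModel:
    """Published covariate structure: weight and creatinine powers on CL,
    weight power on V.  Creatinine's grammar exponent is the negated
    inverse-power exponent."""
    return PopModel(
        cl_base=theta.cl_typical,
        v_base=theta.v_typical,
        cl_terms=[
            CovariateModelSpec(
                covariate="WT",
                target="CL",
                form="power",
                center=theta.wt_ref,
                params={"exp": theta.cl_wt_exponent},
            ),
            CovariateModelSpec(
                covariate="Scr",
                target="CL",
                form="power",
                center=theta.scr_ref,
                params={"exp": -theta.cl_scr_exponent},
            ),
        ],
        v_terms=[
            CovariateModelSpec(
                covariate="WT",
                target="V",
                form="power",
                center=theta.wt_ref,
                params={"exp": theta.v_wt_exponent},
            )
        ],
        name="final",
    )


def fixed_effects_from_model(model: PopModel, theta) -> FixedEffects:
    """Recover printed-convention fixed effects from a final-structure fit."""
    cl_base, cl_hyper, v_base, v_hyper = model._split_theta(np.asarray(theta, float))
    wt_exp = scr_exp = 0.0
    wt_ref, scr_ref = WT_REF, SCR_REF
    for term, hyper in zip(model.cl_terms, cl_hyper):
        if term.covariate == "WT" and term.form == "power":
            wt_exp, wt_ref = hyper["exp"], term.center
        if term.covariate == "Scr" and term.form == "power":
            scr_exp, scr_ref = -hyper["exp"], term.center
    v_exp = v_hyper[0]["exp"] if v_hyper else 0.0
    return FixedEffects(
        cl_typical=cl_base,
        cl_wt_exponent=wt_exp,
        cl_scr_exponent=scr_exp,
        v_typical=v_base,
        v_wt_exponent=v_exp,
        wt_ref=wt_ref,
        scr_ref=scr_ref,
    )
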