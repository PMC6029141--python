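"""Domain records shared by every pipeline stage.

All times are hours since the subject's first dose.  Weights are kg,
creatinine is μmol/L, ages are weeks (GA, PMA) or days (PNA),
concentrations are mg/L.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

#: assay limit of detection, mg/L
LOD = 1.0
#: lower end of the assay calibration range, mg/L
LOQ = 3.0

COMEDICATIONS = (
    "ceftriaxone",
    "meropenem",
    "gentamicin",
    "furosemide",
    "ibuprofen",
    "dexamethasone",
)

#: optional laboratory covariates (units: mmol/L, g/L, U/L, U/L)
OPTIONAL_LABS = ("BUN", "ALB", "AST", "ALT")


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class SchemaError(ValueError):
    """An input table is missing required columns."""


@dataclass(frozen=True)
class CovariateState:
    """Covariate snapshot at a point in time (carried forward until the next)."""

    time: float
    WT: float
    Scr: float
    GA: float
    PNA: float
    PMA: float
    sex: str = "male"
    comeds: frozenset = frozenset()
    labs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.WT <= 0:
            raise ValidationError(f"WT must be > 0, got {self.WT}")
        if self.Scr <= 0:
            raise ValidationError(f"Scr must be > 0, got {self.Scr}")
        if self.time < 0:
            raise ValidationError(f"covariate time must be >= 0, got {self.time}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if abs(self.PMA - (self.GA + self.PNA / 7.0)) > 0.2:
            raise ValidationError(
                f"PMA={self.PMA} inconsistent with GA + PNA/7 = "
                f"{self.GA + self.PNA / 7.0:.3f}"
            )

    def value(self, name: str) -> float:
        """Numeric value of a covariate by name (labs, comed flags, sex as 0/1)."""
        if name in ("WT", "Scr", "GA", "PNA", "PMA", "time"):
            return float(getattr(self, name))
        if name == "sex":
            return 1.0 if self.sex == "female" else 0.0
        if name in COMEDICATIONS:
            return 1.0 if name in self.comeds else 0.0
        if name in self.labs:
            return float(self.labs[name])
        raise KeyError(name)


@dataclass(frozen=True)
class DoseEvent:
    """Constant-rate intravenous infusion."""

    start_time: float
    amount: float
    duration: float = 2.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.duration <= 0:
            raise ValidationError(f"infusion duration must be > 0, got {self.duration}")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class ConcentrationObservation:
    time: float
    value: float
    kind: str = "trough"  # "trough" | "peak"
    below_detection: bool = False
    below_calibration: bool = False

    def __post_init__(self) -> None:
        if not self.below_detection and self.value <= 0:
            raise ValidationError(
                f"observed concentration must be > 0 (got {self.value})"
            )
        if self.kind not in ("trough", "peak"):
            raise ValidationError(f"kind must be 'trough' or 'peak', got {self.kind!r}")

    @staticmethod
    def from_value(time: float, value: float, kind: str = "trough") -> "ConcentrationObservation":
        """Build an observation, deriving the assay-limit flags from the value."""
        return ConcentrationObservation(
            time=time,
            value=value,
            kind=kind,
            below_detection=value < LOD,
            below_calibration=value < LOQ,
        )


@dataclass
class SubjectRecord:
    """One neonate: covariate history plus dose and observation events."""

    id: str
    covariates: list  # list[CovariateState], time-ordered
    doses: list  # list[DoseEvent], time-ordered
    observations: list  # list[ConcentrationObservation], time-ordered

    def __post_init__(self) -> None:
        for name, events in (
            ("covariates", [c.time for c in self.covariates]),
            ("doses", [d.start_time for d in self.doses]),
            ("observations", [o.time for o in self.observations]),
        ):
            if any(b < a for a, b in zip(events, events[1:])):
                raise ValidationError(f"subject {self.id}: {name} times not sorted")
        if self.observations:
            if not self.doses:
                raise ValidationError(f"subject {self.id}: observations without doses")
            first_dose = self.doses[0].start_time
            first_obs = self.observations[0].time
            if first_obs < first_dose:
                raise ValidationError(
                    f"subject {self.id}: observation at {first_obs} h precedes "
                    f"first dose at {first_dose} h"
                )

    def covariates_at(self, time: float) -> CovariateState:
        """Last covariate state at or before ``time`` (carried forward)."""
        state = self.covariates[0]
        for c in self.covariates:
            if c.time <= time:
                state = c
            else:
                break
        return state

    @property
    def baseline(self) -> CovariateState:
        return self.covariates[0]


@dataclass
class PopulationDataset:
    subjects: list  # list[SubjectRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValidationError("subject ids are not unique")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def subset(self, indices: Iterable[int], relabel: bool = True) -> "PopulationDataset":
        """New dataset from subject indices (with replacement allowed).

        When ``relabel`` is true, duplicated subjects get fresh unique ids —
        required by the bootstrap, which resamples with replacement.
        """
        subjects = []
        for k, i in enumerate(indices):
            src = self.subjects[i]
            if relabel:
                subjects.append(dataclasses.replace(src, id=f"bs{k}_{src.id}"))
            else:
                subjects.append(src)
        return PopulationDataset(subjects=subjects, provenance=dict(self.provenance))


@dataclass
class RunConfig:
    """Estimation / evaluation settings shared across CLI stages."""

    seed: int = 1
    ofv_tol: float = 1e-6
    max_iter: int = 500
    hessian_step: float = 1e-4
    n_bootstrap: int = 2000
    n_npde_sim: int = 1000
    n_dosing_sim: int = 1000
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("n_bootstrap", "n_npde_sim", "n_dosing_sim", "max_iter"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
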