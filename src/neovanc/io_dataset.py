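"""NONMEM-style event-table reader/writer.

One row per event.  ``EVID=1`` rows are infusion doses (AMT mg over DUR h),
``EVID=0``/``MDV=0`` rows are concentration observations, and ``EVID=2``
rows carry covariate updates that coincide with no dose or sample.
Covariates are carried forward in time within a subject.
"""

from __future__ import annotations

import io
import os
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    COMEDICATIONS,
    OPTIONAL_LABS,
    ConcentrationObservation,
    CovariateState,
    DoseEvent,
    PopulationDataset,
    SchemaError,
    SubjectRecord,
    ValidationError,
)

REQUIRED_COLUMNS = [
    "ID",
    "TIME",
    "EVID",
    "AMT",
    "DUR",
    "DV",
    "MDV",
    "WT",
    "SCR",
    "GA",
    "PNA",
    "PMA",
    "SEX",
]

_FLAG_COLUMNS = ["BELOW_LOD", "BELOW_LOQ"]
_COMED_COLUMNS = [c.upper() for c in COMEDICATIONS]
_FLOAT_FORMAT = "%.17g"  # exact round-trip; contract requires >= 12 digits


def _states_equal(a: CovariateState, b: CovariateState) -> bool:
    return (
        (a.WT, a.Scr, a.GA, a.PNA, a.PMA, a.sex) == (b.WT, b.Scr, b.GA, b.PNA, b.PMA, b.sex)
        and a.comeds == b.comeds
        and a.labs == b.labs
    )


def _row_covariates(row: pd.Series, labs_present, comeds_present) -> CovariateState:
    for col in ("WT", "SCR", "GA", "PNA", "PMA", "SEX"):
        if pd.isna(row[col]):
            raise ValidationError(
                f"subject {row['ID']}: missing required covariate {col} at TIME={row['TIME']}"
            )
    labs = {}
    for col in labs_present:
        if not pd.isna(row[col]):
            labs[col] = float(row[col])
    comeds = frozenset(c.lower() for c in comeds_present if float(row[c]) > 0.5)
    return CovariateState(
        time=float(row["TIME"]),
        WT=float(row["WT"]),
        Scr=float(row["SCR"]),
        GA=float(row["GA"]),
        PNA=float(row["PNA"]),
        PMA=float(row["PMA"]),
        sex="female" if float(row["SEX"]) > 0.5 else "male",
        comeds=comeds,
        labs=labs,
    )


def read_dataset(path) -> PopulationDataset:
    """Read an event-table CSV into a :class:`PopulationDataset`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    return frame_to_dataset(frame, provenance={"path": str(path)})


def frame_to_dataset(frame: pd.DataFrame, provenance: Optional[dict] = None) -> PopulationDataset:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"event table is missing required column(s): {', '.join(missing)}")

    labs_present = [c for c in OPTIONAL_LABS if c in frame.columns]
    comeds_present = [c for c in _COMED_COLUMNS if c in frame.columns]
    has_kind = "KIND" in frame.columns
    has_flags = all(c in frame.columns for c in _FLAG_COLUMNS)

    subjects = []
    for sid, rows in frame.groupby("ID", sort=False):
        times = rows["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValidationError(f"subject {sid}: TIME is not non-decreasing")

        covariates, doses, observations = [], [], []
        for _, row in rows.iterrows():
            state = _row_covariates(row, labs_present, comeds_present)
            if not covariates or not _states_equal(covariates[-1], state):
                covariates.append(state)
            evid = int(row["EVID"])
            if evid == 1:
                doses.append(
                    DoseEvent(
                        start_time=float(row["TIME"]),
                        amount=float(row["AMT"]),
                        duration=float(row["DUR"]) if not pd.isna(row["DUR"]) else 2.0,
                    )
                )
            elif evid == 0 and int(row["MDV"]) == 0:
                kind = str(row["KIND"]) if has_kind and not pd.isna(row["KIND"]) else "trough"
                if has_flags:
                    obs = ConcentrationObservation(
                        time=float(row["TIME"]),
                        value=float(row["DV"]),
                        kind=kind,
                        below_detection=float(row["BELOW_LOD"]) > 0.5,
                        below_calibration=float(row["BELOW_LOQ"]) > 0.5,
                    )
                else:
                    obs = ConcentrationObservation.from_value(
                        float(row["TIME"]), float(row["DV"]), kind
                    )
                observations.append(obs)
            elif evid == 2:
                pass  # covariate update only
        subjects.append(
            SubjectRecord(
                id=str(sid), covariates=covariates, doses=doses, observations=observations
            )
        )
    return PopulationDataset(subjects=subjects, provenance=provenance or {})


def dataset_to_frame(dataset: PopulationDataset) -> pd.DataFrame:
    any_labs = sorted(
        {lab for s in dataset.subjects for c in s.covariates for lab in c.labs}
    )
    any_comeds = any(c.comeds for s in dataset.subjects for c in s.covariates)
    comed_cols = _COMED_COLUMNS if any_comeds else []
    columns = (
        REQUIRED_COLUMNS[:7]
        + ["KIND"]
        + _FLAG_COLUMNS
        + REQUIRED_COLUMNS[7:]
        + any_labs
        + comed_cols
    )

    rows = []
    for subject in dataset.subjects:
        events = [("dose", d.start_time, d) for d in subject.doses]
        events += [("obs", o.time, o) for o in subject.observations]
        event_times = {t for _, t, _ in events}
        events += [
            ("cov", c.time, c) for c in subject.covariates if c.time not in event_times
        ]
        events.sort(key=lambda e: (e[1], e[0] != "dose"))
        for etype, time, ev in events:
            state = subject.covariates_at(time)
            row = {
                "ID": subject.id,
                "TIME": time,
                "WT": state.WT,
                "SCR": state.Scr,
                "GA": state.GA,
                "PNA": state.PNA,
                "PMA": state.PMA,
                "SEX": 1 if state.sex == "female" else 0,
            }
            for lab in any_labs:
                row[lab] = state.labs.get(lab, np.nan)
            for c in comed_cols:
                row[c] = 1 if c.lower() in state.comeds else 0
            if etype == "dose":
                row.update(EVID=1, AMT=ev.amount, DUR=ev.duration, DV=np.nan, MDV=1,
                           KIND="", BELOW_LOD=0, BELOW_LOQ=0)
            elif etype == "obs":
                row.update(EVID=0, AMT=0.0, DUR=np.nan, DV=ev.value, MDV=0,
                           KIND=ev.kind,
                           BELOW_LOD=int(ev.below_detection),
                           BELOW_LOQ=int(ev.below_calibration))
            else:
                row.update(EVID=2, AMT=0.0, DUR=np.nan, DV=np.nan, MDV=1,
                           KIND="", BELOW_LOD=0, BELOW_LOQ=0)
            rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def write_dataset(dataset: PopulationDataset, path) -> None:
    """Write an event-table CSV (bit-stable for a given dataset)."""
    frame = dataset_to_frame(dataset)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def dataset_to_csv_bytes(dataset: PopulationDataset) -> bytes:
    buf = io.StringIO()
    write_dataset(dataset, buf)
    return buf.getvalue().encode()
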