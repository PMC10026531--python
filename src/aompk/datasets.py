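"""Pharmacometric dataset I/O.

Longitudinal PK study data travel as NONMEM-convention CSV tables with one
row per dose or observation event:

    ID       subject identifier (int)
    TIME     h since first record
    AMT      dose amount (mg), 0 for observations
    RATE     zero-order input rate (mg/h) for oral doses, 0 otherwise
    CMT      compartment code: 1 oral depot, 2 IM depot, 3 central
    EVID     1 for dose records, 0 for observations
    MDV      1 if DV is missing (dose rows), 0 otherwise
    DV       observed concentration (ng/mL)
    SEX      1 male, 0 female
    BMI      kg/m^2
    PM       1 poor metabolizer, 0 extensive
    CYP2D6INH, CYP3A4INH   inhibitor-use flags
    PHASE    study phase (1 rich sampling, 3 sparse)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import ObservationSet
from .pk import DoseEvent, Regimen, SubjectCovariates

__all__ = [
    "COLUMNS",
    "CMT_ORAL_DEPOT",
    "CMT_IM_DEPOT",
    "CMT_CENTRAL",
    "SchemaError",
    "SubjectRecord",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "dataset_to_subjects",
]

COLUMNS = ["ID", "TIME", "AMT", "RATE", "CMT", "EVID", "MDV", "DV",
           "SEX", "BMI", "PM", "CYP2D6INH", "CYP3A4INH", "PHASE"]

CMT_ORAL_DEPOT, CMT_IM_DEPOT, CMT_CENTRAL = 1, 2, 3
_DOSE_CMTS = {CMT_ORAL_DEPOT: "oral", CMT_IM_DEPOT: "im"}


class SchemaError(ValueError):
    """A dataset violates the documented schema."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's covariates, dosing history and observations."""

    subject_id: int
    covariates: SubjectCovariates
    regimen: Regimen
    observations: ObservationSet


def validate_dataset(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming the offending columns/rows."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    bad_evid = df.index[~df["EVID"].isin([0, 1])].tolist()
    if bad_evid:
        raise SchemaError(f"unknown EVID codes at rows {bad_evid[:10]}")
    doses = df[df["EVID"] == 1]
    bad_cmt = doses.index[~doses["CMT"].isin(list(_DOSE_CMTS))].tolist()
    if bad_cmt:
        raise SchemaError(f"unknown dose compartment codes at rows {bad_cmt[:10]}")
    for sid, sub in df.groupby("ID"):
        t = sub["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise SchemaError(f"non-monotone TIME within subject {sid}")


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a validated dataset as CSV (numeric columns at full precision)."""
    validate_dataset(df)
    df.to_csv(path, index=False, columns=COLUMNS)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset CSV."""
    df = pd.read_csv(path)
    validate_dataset(df)
    return df


def dataset_to_subjects(df: pd.DataFrame) -> list[SubjectRecord]:
    """Partition dose and observation rows into per-subject records."""
    validate_dataset(df)
    records = []
    for sid, sub in df.groupby("ID", sort=True):
        first = sub.iloc[0]
        cov = SubjectCovariates(
            sex="male" if int(first["SEX"]) == 1 else "female",
            bmi=float(first["BMI"]),
            metabolizer="PM" if int(first["PM"]) == 1 else "EM",
            on_cyp2d6_inhibitor=bool(int(first["CYP2D6INH"])),
            on_cyp3a4_inhibitor=bool(int(first["CYP3A4INH"])),
        )
        doses = [
            DoseEvent(time=float(r.TIME), amount=float(r.AMT),
                      route=_DOSE_CMTS[int(r.CMT)])
            for r in sub[sub["EVID"] == 1].itertuples()
        ]
        obs_rows = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)]
        regimen = Regimen(doses)
        obs = ObservationSet(
            times=obs_rows["TIME"].to_numpy(dtype=float),
            dv=obs_rows["DV"].to_numpy(dtype=float),
            phase=obs_rows["PHASE"].to_numpy(dtype=int),
            regimen=regimen,
        )
        records.append(SubjectRecord(subject_id=int(sid), covariates=cov,
                                     regimen=regimen, observations=obs))
    return records
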