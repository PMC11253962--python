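"""Covariate-parameterized three-compartment pharmacokinetics.

Maps patient demographics (age, weight, height, sex) to the volumes,
clearances and micro rate constants of a mammillary three-compartment PK
model.  The covariate equations are the classic adult set in which the
central volume and the slow-compartment parameters are fixed, the rapid
compartment shrinks linearly with age, and the metabolic clearance is
corrected linearly for weight, lean body mass and height:

    V1  = 4.27 L
    V2  = 18.9 - 0.391 (age - 53) L
    V3  = 238 L
    Cl1 = 1.89 + 0.0456 (weight - 77) - 0.0681 (lbm - 59) + 0.0264 (height - 177) L/min
    Cl2 = 1.29 - 0.024 (age - 53) L/min
    Cl3 = 0.836 L/min

with micro rate constants k10 = Cl1/V1, k12 = Cl2/V1, k13 = Cl3/V1,
k21 = Cl2/V2, k31 = Cl3/V3 (all 1/min).

Units convention (used throughout the package): volumes in liters,
clearances in L/min, time in minutes, concentrations in ug/mL, doses in mg.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import OutOfModelRangeError, ValidationError

__all__ = [
    "Patient",
    "PKParams",
    "lean_body_mass",
    "pk_params_from_covariates",
    "read_cohort_csv",
    "write_cohort_csv",
]

_SEXES = ("male", "female")


@dataclass(frozen=True)
class Patient:
    """Demographic covariates that drive the PK parameters.

    Parameters
    ----------
    id : str
        Free-form patient identifier.
    age : float
        Age in years, > 0.
    weight : float
        Total body weight in kg, > 0.
    height : float
        Height in cm, > 0.
    sex : {"male", "female"}
    """

    id: str
    age: float
    weight: float
    height: float
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValidationError(
                f"unknown sex label {self.sex!r}; expected one of {_SEXES}"
            )
        for name in ("age", "weight", "height"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(f"{name} must be > 0, got {value}")

    @property
    def lbm(self) -> float:
        """Lean body mass (kg) derived from weight, height and sex."""
        return lean_body_mass(self.weight, self.height, self.sex)


@dataclass(frozen=True)
class PKParams:
    """Three-compartment model parameters.

    Volumes ``v1..v3`` in liters, clearances ``cl1..cl3`` in L/min, and the
    micro rate constants ``k10, k12, k13, k21, k31`` (1/min) they imply.
    Volumes must be strictly positive; clearances may be zero (a closed
    system) but not negative.
    """

    v1: float
    v2: float
    v3: float
    cl1: float
    cl2: float
    cl3: float

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "v3"):
            if not getattr(self, name) > 0:
                raise OutOfModelRangeError(
                    f"volume {name} must be > 0, got {getattr(self, name)}"
                )
        for name in ("cl1", "cl2", "cl3"):
            if getattr(self, name) < 0:
                raise OutOfModelRangeError(
                    f"clearance {name} must be >= 0, got {getattr(self, name)}"
                )

    # Micro rate constants (1/min), defined exactly as clearance/volume ratios.
    @property
    def k10(self) -> float:
        return self.cl1 / self.v1

    @property
    def k12(self) -> float:
        return self.cl2 / self.v1

    @property
    def k13(self) -> float:
        return self.cl3 / self.v1

    @property
    def k21(self) -> float:
        return self.cl2 / self.v2

    @property
    def k31(self) -> float:
        return self.cl3 / self.v3

    def to_dict(self) -> dict[str, float]:
        """Serialize as a flat JSON-ready mapping including rate constants."""
        return {
            "V1": self.v1,
            "V2": self.v2,
            "V3": self.v3,
            "Cl1": self.cl1,
            "Cl2": self.cl2,
            "Cl3": self.cl3,
            "k10": self.k10,
            "k12": self.k12,
            "k13": self.k13,
            "k21": self.k21,
            "k31": self.k31,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "PKParams":
        return cls(
            v1=d["V1"], v2=d["V2"], v3=d["V3"],
            cl1=d["Cl1"], cl2=d["Cl2"], cl3=d["Cl3"],
        )


def lean_body_mass(weight: float, height: float, sex: str) -> float:
    """James lean body mass (kg) from weight (kg), height (cm) and sex.

    female: 1.07 w - 148 w^2 / h^2
    male:   1.10 w - 128 w^2 / h^2

    Raises
    ------
    ValidationError
        For non-positive weight/height or an unknown sex label.
    OutOfModelRangeError
        If the formula returns a non-positive mass (degenerate covariates,
        e.g. extreme obesity relative to height).
    """
    if not weight > 0 or not height > 0:
        raise ValidationError(
            f"weight and height must be > 0, got weight={weight}, height={height}"
        )
    if sex == "female":
        lbm = 1.07 * weight - 148.0 * weight**2 / height**2
    elif sex == "male":
        lbm = 1.1 * weight - 128.0 * weight**2 / height**2
    else:
        raise ValidationError(f"unknown sex label {sex!r}; expected one of {_SEXES}")
    if not lbm > 0:
        raise OutOfModelRangeError(
            f"lean body mass evaluates to {lbm:.4g} kg (<= 0) for "
            f"weight={weight}, height={height}, sex={sex}"
        )
    return lbm


def pk_params_from_covariates(patient: Patient, lbm: float | None = None) -> PKParams:
    """PK volumes and clearances from patient covariates.

    At the reference covariates (age 53, weight 77 kg, lbm 59 kg, height
    177 cm) every correction term vanishes and the intercepts are returned
    exactly: V2 = 18.9, Cl1 = 1.89, Cl2 = 1.29.

    Parameters
    ----------
    lbm : optional lean body mass (kg) overriding the sex-specific formula
        (useful when lbm is known from body-composition measurement).

    Raises
    ------
    OutOfModelRangeError
        If any computed volume or clearance is non-positive (the message
        names the offending parameter).
    """
    if lbm is None:
        lbm = lean_body_mass(patient.weight, patient.height, patient.sex)
    elif not lbm > 0:
        raise ValidationError(f"lbm override must be > 0, got {lbm}")
    v1 = 4.27
    v2 = 18.9 - 0.391 * (patient.age - 53.0)
    v3 = 238.0
    cl1 = (
        1.89
        + 0.0456 * (patient.weight - 77.0)
        - 0.0681 * (lbm - 59.0)
        + 0.0264 * (patient.height - 177.0)
    )
    cl2 = 1.29 - 0.024 * (patient.age - 53.0)
    cl3 = 0.836
    for name, value in (("V2", v2), ("Cl1", cl1), ("Cl2", cl2)):
        if not value > 0:
            raise OutOfModelRangeError(
                f"covariates of patient {patient.id!r} give {name} = {value:.4g} <= 0"
            )
    return PKParams(v1=v1, v2=v2, v3=v3, cl1=cl1, cl2=cl2, cl3=cl3)


# --- cohort CSV I/O ---------------------------------------------------------
# Columns: id,age,weight,height,sex  (age in years, weight kg, height cm).

_COHORT_COLUMNS = ("id", "age", "weight", "height", "sex")


def read_cohort_csv(path: str | Path) -> list[Patient]:
    """Read a cohort table with header ``id,age,weight,height,sex``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_COHORT_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(
                f"cohort CSV must have columns {','.join(_COHORT_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        return [
            Patient(
                id=row["id"],
                age=float(row["age"]),
                weight=float(row["weight"]),
                height=float(row["height"]),
                sex=row["sex"].strip().lower(),
            )
            for row in reader
        ]


def write_cohort_csv(patients: Iterable[Patient], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_COLUMNS)
        for p in patients:
            writer.writerow([p.id, repr(p.age), repr(p.weight), repr(p.height), p.sex])
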