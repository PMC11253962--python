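"""Virtual patients, dosing protocols, noisy BIS traces and EEG-like features.

The generator emulates the study conditions the rest of the package is
exercised on: an elderly surgical cohort (ages 65-85), induction with a
1.0-1.5 mg/kg bolus followed by a constant maintenance infusion, BIS traces
produced by the covariate PKPD model plus additive Gaussian observation
noise (default sd 3 BIS units, clipped to the 0-100 monitor range), and
feature streams that are smooth monotone transforms of the effect-site
concentration so a BIS regressor has learnable signal.

Every draw is controlled by a single seed through ``numpy`` seed sequences,
so cohorts, noise and features are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariate_pk import Patient, pk_params_from_covariates
from .exceptions import ValidationError
from .gbdt import FeatureMatrix
from .pkpd import (
    BISTrace,
    EffectLinkConfig,
    InfusionProtocol,
    PDParams,
    default_grid,
    simulate_bis,
    simulate_concentrations,
)

__all__ = ["CohortSpec", "TruePatientModel", "generate_cohort", "observe_bis",
           "generate_eeg_features"]

#: Sub-box of the PD search bounds the true parameters are drawn from:
#: awake baseline 85-95, depression depth 50-85 (always <= E0), EC50
#: 1.5-4 ug/mL, Hill slope 1.5-3.  Keeps every virtual patient strictly
#: inside the default identification box.
PD_TRUE_RANGES = {
    "e0": (85.0, 95.0),
    "emax": (50.0, 85.0),
    "ec50": (1.5, 4.0),
    "gamma": (1.5, 3.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges for a virtual cohort.

    Defaults portray the elderly surgical population of interest and dosing
    in the clinical range: induction bolus 1.0-1.5 mg/kg, maintenance
    infusion 4-8 mg/kg/h over ``maintenance_minutes``.
    """

    n: int = 10
    age_range: tuple[float, float] = (65.0, 85.0)
    weight_range: tuple[float, float] = (55.0, 85.0)
    height_range: tuple[float, float] = (150.0, 180.0)
    female_fraction: float = 0.5
    bolus_mg_per_kg: tuple[float, float] = (1.0, 1.5)
    infusion_mg_per_kg_h: tuple[float, float] = (4.0, 8.0)
    maintenance_minutes: float = 40.0
    noise_sd: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        for name in ("age_range", "weight_range", "height_range",
                     "bolus_mg_per_kg", "infusion_mg_per_kg_h"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValidationError(f"{name} must satisfy 0 < low <= high")
        if not 0 <= self.female_fraction <= 1:
            raise ValidationError("female_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.maintenance_minutes <= 0:
            raise ValidationError("maintenance_minutes must be > 0")


@dataclass(frozen=True)
class TruePatientModel:
    """A virtual patient: covariates, ground-truth PD curve, dosing protocol
    and the observation-noise level of their BIS monitor."""

    patient: Patient
    pd_true: PDParams
    protocol: InfusionProtocol
    noise_sd: float = 3.0


def generate_cohort(
    spec: CohortSpec,
    link: EffectLinkConfig | None = None,
    check_depth: bool = True,
) -> list[TruePatientModel]:
    """Draw ``spec.n`` virtual patients with protocols and true PD curves.

    With ``check_depth`` each patient's noiseless BIS trace over the
    maintenance window is simulated and required to dip below 60 — the
    surgical-depth band — so the sigmoid's midregion is exercised and EC50
    and gamma are identifiable.  A violation raises rather than silently
    resampling; the default dosing ranges satisfy the check by construction.
    """
    rng = np.random.default_rng(spec.seed)
    models: list[TruePatientModel] = []
    for i in range(spec.n):
        patient = Patient(
            id=f"P{i + 1:02d}",
            age=float(rng.uniform(*spec.age_range)),
            weight=float(rng.uniform(*spec.weight_range)),
            height=float(rng.uniform(*spec.height_range)),
            sex="female" if rng.random() < spec.female_fraction else "male",
        )
        pk_params_from_covariates(patient)  # fail fast if outside the envelope
        bolus = float(rng.uniform(*spec.bolus_mg_per_kg)) * patient.weight
        rate = float(rng.uniform(*spec.infusion_mg_per_kg_h)) * patient.weight / 60.0
        protocol = InfusionProtocol(
            boluses=((0.0, bolus),),
            segments=((0.0, spec.maintenance_minutes, rate),),
        )
        e0 = float(rng.uniform(*PD_TRUE_RANGES["e0"]))
        pd_true = PDParams(
            e0=e0,
            emax=float(rng.uniform(*PD_TRUE_RANGES["emax"])),
            ec50=float(rng.uniform(*PD_TRUE_RANGES["ec50"])),
            gamma=float(rng.uniform(*PD_TRUE_RANGES["gamma"])),
        )
        model = TruePatientModel(
            patient=patient, pd_true=pd_true, protocol=protocol, noise_sd=spec.noise_sd
        )
        if check_depth:
            grid = default_grid(spec.maintenance_minutes, dt=0.1)
            trace = simulate_bis(patient, protocol, pd_true, link=link, grid=grid)
            if trace.bis.min() >= 60.0:
                raise ValidationError(
                    f"protocol for {patient.id} never reaches surgical depth "
                    f"(min BIS {trace.bis.min():.1f} >= 60)"
                )
        models.append(model)
    return models


def observe_bis(
    model: TruePatientModel,
    grid: np.ndarray,
    seed: int | None = None,
    link: EffectLinkConfig | None = None,
) -> BISTrace:
    """Noiseless PKPD BIS plus i.i.d. Gaussian monitor noise, clipped to [0, 100]."""
    clean = simulate_bis(model.patient, model.protocol, model.pd_true, link=link, grid=grid)
    if model.noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    noisy = clean.bis + rng.normal(0.0, model.noise_sd, size=clean.bis.size)
    return BISTrace(t=clean.t, bis=np.clip(noisy, 0.0, 100.0))


def generate_eeg_features(
    model: TruePatientModel,
    grid: np.ndarray,
    seed: int | None = None,
    link: EffectLinkConfig | None = None,
    n_distractors: int = 3,
    feature_noise_sd: float = 0.05,
    informative: bool = True,
) -> FeatureMatrix:
    """EEG-feature surrogate matrix aligned with an observed BIS target.

    Informative columns are smooth monotone transforms of the effect-site
    concentration Ce(t) — the physiological driver of BIS — each perturbed
    with Gaussian noise of sd ``feature_noise_sd`` times the column's spread:

        ce_linear     = Ce
        ce_saturating = Ce / (1 + Ce)
        ce_exp_decay  = exp(-Ce / 2)

    Distractor columns are pure standard-normal noise.  The target is the
    noisy observed BIS on the same grid.  With ``informative=False`` only
    distractors are emitted (a no-signal control).  Seeds for the BIS noise,
    the feature noise and the distractors are spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    bis_seed, feat_seed = ss.spawn(2)
    params = pk_params_from_covariates(model.patient)
    conc = simulate_concentrations(params, model.protocol, link=link, grid=grid)
    observed = observe_bis(
        model, grid, seed=int(bis_seed.generate_state(1)[0] % (2**31)), link=link
    )
    rng = np.random.default_rng(feat_seed)
    ce = conc.ce
    cols: dict[str, np.ndarray] = {}
    if informative:
        for name, values in (
            ("ce_linear", ce),
            ("ce_saturating", ce / (1.0 + ce)),
            ("ce_exp_decay", np.exp(-ce / 2.0)),
        ):
            scale = float(np.std(values)) or 1.0
            cols[name] = values + rng.normal(0.0, feature_noise_sd * scale, size=ce.size)
    for k in range(n_distractors):
        cols[f"distractor_{k + 1}"] = rng.normal(0.0, 1.0, size=ce.size)
    if not cols:
        raise ValidationError("no feature columns requested")
    return FeatureMatrix(features=pd.DataFrame(cols), target=observed.bis)
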