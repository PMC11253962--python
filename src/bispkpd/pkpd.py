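"""Three-compartment PK simulation and sigmoid-Emax BIS pharmacodynamics.

The plasma model is the linear mammillary system

    dC1/dt = -(k10 + k12 + k13) C1 + (k21 V2 / V1) C2 + (k31 V3 / V1) C3 + u(t)/V1
    dC2/dt = (k12 V1 / V2) C1 - k21 C2
    dC3/dt = (k13 V1 / V3) C1 - k31 C3

with u(t) the drug infusion rate (mg/min).  A hypothetical effect site is
linked to plasma with first-order dynamics dCe/dt = ke0 (C1 - Ce), and the
bispectral index follows the sigmoid Emax (Hill) curve

    BIS(t) = E0 - Emax * Ce^gamma / (EC50^gamma + Ce^gamma).

Because the system is linear and the input is piecewise constant (constant
rate segments plus instantaneous boluses) the trajectory is propagated
exactly with matrix exponentials of the augmented system, so accuracy is
independent of the output grid spacing and of the stiffness of the rate
constants.  Boluses are applied as instantaneous jumps of dose/V1 on C1;
the recorded trace is right-continuous at bolus instants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .covariate_pk import Patient, PKParams, pk_params_from_covariates
from .exceptions import ValidationError

__all__ = [
    "InfusionProtocol",
    "EffectLinkConfig",
    "ConcentrationTrace",
    "PDParams",
    "BISTrace",
    "default_grid",
    "simulate_concentrations",
    "bis_from_ce",
    "simulate_bis",
]

#: Default effect-site equilibration constant (1/min), the standard
#: literature value for this adult covariate set.
DEFAULT_KE0 = 0.456

#: Default output grid spacing: 1 second, the cadence of a BIS monitor.
DEFAULT_DT = 1.0 / 60.0


@dataclass(frozen=True)
class InfusionProtocol:
    """Dosing input u(t): instantaneous boluses plus constant-rate segments.

    boluses : list of (time min, dose mg)
    segments : list of (t_start min, t_end min, rate mg/min); non-overlapping
    """

    boluses: tuple[tuple[float, float], ...] = ()
    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        boluses = tuple((float(t), float(d)) for t, d in self.boluses)
        segments = tuple(
            (float(a), float(b), float(r)) for a, b, r in self.segments
        )
        object.__setattr__(self, "boluses", boluses)
        object.__setattr__(self, "segments", segments)
        for t, d in boluses:
            if t < 0:
                raise ValidationError(f"bolus time {t} < 0")
            if d < 0:
                raise ValidationError(f"bolus dose {d} < 0")
        prev_end = None
        for a, b, r in sorted(segments):
            if a < 0 or not a < b:
                raise ValidationError(f"invalid segment ({a}, {b}): need 0 <= start < end")
            if r < 0:
                raise ValidationError(f"segment rate {r} < 0")
            if prev_end is not None and a < prev_end - 1e-12:
                raise ValidationError("infusion segments overlap")
            prev_end = b

    def rate_at(self, t: float) -> float:
        """Infusion rate (mg/min) at time t; segments are [start, end)."""
        for a, b, r in self.segments:
            if a <= t < b:
                return r
        return 0.0

    def event_times(self) -> np.ndarray:
        """All instants where the input changes discontinuously."""
        times = [t for t, _ in self.boluses]
        for a, b, _ in self.segments:
            times.extend((a, b))
        return np.unique(np.asarray(times, dtype=float))


@dataclass(frozen=True)
class EffectLinkConfig:
    """First-order plasma-to-effect-site link; ke0 in 1/min (>= 0)."""

    ke0: float = DEFAULT_KE0

    def __post_init__(self) -> None:
        if self.ke0 < 0:
            raise ValidationError(f"ke0 must be >= 0, got {self.ke0}")


@dataclass(frozen=True)
class ConcentrationTrace:
    """Compartment and effect-site concentrations (ug/mL) on a time grid (min)."""

    t: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    ce: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "c1", "c2", "c3", "ce"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if any(getattr(self, name).size != n for name in ("c1", "c2", "c3", "ce")):
            raise ValidationError("trace arrays must share one length")


@dataclass(frozen=True)
class PDParams:
    """Hill-curve parameters mapping effect-site concentration to BIS.

    e0 : baseline (awake) BIS, in (0, 100]
    emax : maximal BIS depression, 0 < emax <= e0
    ec50 : effect-site concentration (ug/mL) at half-maximal depression
    gamma : Hill slope, > 0
    """

    e0: float
    emax: float
    ec50: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0 < self.e0 <= 100:
            raise ValidationError(f"e0 must be in (0, 100], got {self.e0}")
        if not 0 < self.emax <= self.e0:
            raise ValidationError(
                f"emax must be in (0, e0={self.e0}], got {self.emax}"
            )
        if not self.ec50 > 0:
            raise ValidationError(f"ec50 must be > 0, got {self.ec50}")
        if not self.gamma > 0:
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")

    def to_dict(self) -> dict[str, float]:
        return {"e0": self.e0, "emax": self.emax, "ec50": self.ec50, "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "PDParams":
        return cls(e0=d["e0"], emax=d["emax"], ec50=d["ec50"], gamma=d["gamma"])


@dataclass(frozen=True)
class BISTrace:
    """BIS values on a time grid (min)."""

    t: np.ndarray
    bis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "bis", np.asarray(self.bis, dtype=float))
        if self.t.size != self.bis.size:
            raise ValidationError("t and bis must share one length")


def default_grid(t_end: float, dt: float = DEFAULT_DT) -> np.ndarray:
    """Uniform grid 0..t_end (minutes) at spacing dt (default 1 s)."""
    n = int(round(t_end / dt))
    return np.linspace(0.0, n * dt, n + 1)


def _system_matrix(p: PKParams, ke0: float) -> np.ndarray:
    return np.array(
        [
            [-(p.k10 + p.k12 + p.k13), p.k21 * p.v2 / p.v1, p.k31 * p.v3 / p.v1, 0.0],
            [p.k12 * p.v1 / p.v2, -p.k21, 0.0, 0.0],
            [p.k13 * p.v1 / p.v3, 0.0, -p.k31, 0.0],
            [ke0, 0.0, 0.0, -ke0],
        ]
    )


def simulate_concentrations(
    params: PKParams,
    protocol: InfusionProtocol,
    link: EffectLinkConfig | None = None,
    grid: np.ndarray | Sequence[float] | None = None,
    initial_state: Sequence[float] | None = None,
) -> ConcentrationTrace:
    """Propagate the three compartments and the effect site along ``grid``.

    The state x = (C1, C2, C3, Ce) obeys dx/dt = A x + e1 u(t)/V1.  Between
    input discontinuities u is constant, so each step is advanced with the
    exact matrix exponential of the augmented 5x5 system (cached per
    distinct step size and rate).  Boluses add dose/V1 to C1 at their event
    time; events that fall between grid points are honored as internal
    breakpoints.

    Parameters
    ----------
    grid : strictly increasing times (min); defaults to 0..last event + 10 min
        at 1 s spacing.
    initial_state : optional (C1, C2, C3, Ce) at grid[0]; defaults to zeros.
    """
    if link is None:
        link = EffectLinkConfig()
    if grid is None:
        events = protocol.event_times()
        horizon = float(events[-1]) + 10.0 if events.size else 10.0
        grid = default_grid(horizon)
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValidationError("grid must be a 1-D array with at least one point")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError("grid must be strictly increasing")

    x = np.zeros(4) if initial_state is None else np.asarray(initial_state, dtype=float).copy()
    if x.shape != (4,):
        raise ValidationError("initial_state must have four components (C1, C2, C3, Ce)")

    A = _system_matrix(params, link.ke0)
    v1 = params.v1

    events = protocol.event_times()
    events = events[(events > t[0]) & (events < t[-1])]
    knots = np.union1d(t, events)
    grid_set = {round(ti, 12) for ti in t}
    bolus_at: dict[float, float] = {}
    for bt, dose in protocol.boluses:
        if t[0] <= bt <= t[-1]:
            key = round(bt, 12)
            bolus_at[key] = bolus_at.get(key, 0.0) + dose

    cache: dict[tuple[float, float], np.ndarray] = {}

    def step(x: np.ndarray, u: float, dt: float) -> np.ndarray:
        key = (round(dt, 12), u)
        M = cache.get(key)
        if M is None:
            aug = np.zeros((5, 5))
            aug[:4, :4] = A
            aug[0, 4] = u / v1
            M = expm(aug * dt)
            cache[key] = M
        return M[:4, :4] @ x + M[:4, 4]

    out = np.empty((t.size, 4))
    idx = 0  # next grid index to record

    # bolus exactly at the grid start
    key0 = round(knots[0], 12)
    if key0 in bolus_at:
        x[0] += bolus_at[key0] / v1
    out[idx] = x
    idx += 1

    for a, b in zip(knots[:-1], knots[1:]):
        u = protocol.rate_at(0.5 * (a + b))
        x = step(x, u, b - a)
        keyb = round(b, 12)
        if keyb in bolus_at:
            x[0] += bolus_at[keyb] / v1
        if keyb in grid_set:
            out[idx] = x
            idx += 1

    return ConcentrationTrace(t=t, c1=out[:, 0], c2=out[:, 1], c3=out[:, 2], ce=out[:, 3])


def bis_from_ce(ce, pd: PDParams):
    """Sigmoid Emax map: BIS = E0 - Emax ce^g / (EC50^g + ce^g).

    Accepts a scalar or array of non-negative effect-site concentrations;
    strictly decreasing in ce and bounded in [E0 - Emax, E0].
    """
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValidationError("effect-site concentration must be >= 0")
    num = np.power(ce_arr, pd.gamma)
    bis = pd.e0 - pd.emax * num / (pd.ec50**pd.gamma + num)
    return bis if ce_arr.ndim else float(bis)


def simulate_bis(
    patient: Patient,
    protocol: InfusionProtocol,
    pd: PDParams,
    link: EffectLinkConfig | None = None,
    grid: np.ndarray | Sequence[float] | None = None,
) -> BISTrace:
    """Full PKPD composition: covariates -> concentrations -> Hill -> BIS."""
    params = pk_params_from_covariates(patient)
    conc = simulate_concentrations(params, protocol, link=link, grid=grid)
    return BISTrace(t=conc.t, bis=bis_from_ce(conc.ce, pd))
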