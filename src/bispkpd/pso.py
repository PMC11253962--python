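"""Particle swarm optimization and PD-parameter identification.

The swarm follows the canonical velocity/position recursion

    v_ik <- w v_ik + C1 rand1 (l_ik - x_ik) + C2 rand2 (l_gk - x_ik)
    x_ik <- x_ik + v_ik

where l_i is particle i's personal best and l_g the global best.  Positions
are clipped to the search box after each move and the violating velocity
component is zeroed.  Termination is a fixed iteration budget.

``identify_pd`` fits the Hill parameters (E0, Emax, EC50, gamma) of the
BIS pharmacodynamic curve to an observed BIS trace, given the effect-site
concentration trace, by minimizing the RMSE between observed and modelled
BIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import metrics
from .exceptions import ValidationError
from .pkpd import BISTrace, ConcentrationTrace, PDParams, bis_from_ce

__all__ = [
    "PSOConfig",
    "PSOResult",
    "FitResult",
    "pso_minimize",
    "identify_pd",
    "DEFAULT_PD_BOUNDS",
]

#: Default search box for (E0, Emax, EC50 [ug/mL], gamma).
DEFAULT_PD_BOUNDS: tuple[tuple[float, float], ...] = (
    (80.0, 100.0),
    (40.0, 100.0),
    (0.5, 10.0),
    (0.5, 6.0),
)


@dataclass(frozen=True)
class PSOConfig:
    """Hyperparameters of the swarm.

    bounds : per-dimension (low, high) search box; low < high.
    swarm_size : particles m (default 30).
    max_iters : fixed iteration budget (default 200).
    inertia : w (default 0.729, constriction-equivalent).
    cognitive, social : learning factors C1 and C2 (default 1.494 each).
    velocity_clamp : |v| limit as a fraction of each bound span.
    seed : RNG seed; identical seeds give bitwise-identical runs.
    """

    bounds: tuple[tuple[float, float], ...]
    swarm_size: int = 30
    max_iters: int = 200
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    velocity_clamp: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        if len(bounds) < 1:
            raise ValidationError("need at least one search dimension")
        for lo, hi in bounds:
            if not lo < hi:
                raise ValidationError(f"bound ({lo}, {hi}) must satisfy low < high")
        if self.swarm_size < 1:
            raise ValidationError("swarm_size must be >= 1")
        if self.max_iters < 1:
            raise ValidationError("max_iters must be >= 1")
        if not 0 < self.velocity_clamp:
            raise ValidationError("velocity_clamp must be > 0")

    @property
    def dims(self) -> int:
        return len(self.bounds)


@dataclass(frozen=True)
class PSOResult:
    """Best position/value and the global-best value after each iteration
    (history[0] is the value after initialization; non-increasing)."""

    position: np.ndarray
    value: float
    history: np.ndarray


@dataclass(frozen=True)
class FitResult:
    """Outcome of a PD identification: fitted parameters, the RMSE objective
    at the optimum, the full metric report on the fitted trace, the
    convergence history, and the fitted BIS trace itself."""

    pd: PDParams
    objective_value: float
    metrics: metrics.EvalReport
    history: np.ndarray
    fitted: BISTrace


def _evaluate(objective: Callable[[np.ndarray], float], X: np.ndarray) -> np.ndarray:
    vals = np.empty(X.shape[0])
    for i, x in enumerate(X):
        v = float(objective(x))
        if np.isnan(v):
            raise ValidationError(f"objective returned NaN at position {x.tolist()}")
        vals[i] = v
    return vals


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    config: PSOConfig,
    init_positions: np.ndarray | None = None,
) -> PSOResult:
    """Minimize ``objective`` over the configured box.

    Parameters
    ----------
    objective : callable mapping a K-vector to a finite float.
    init_positions : optional (k, K) array seeding the first k particles
        (useful for warm starts and for tests); the rest are drawn uniformly
        in the box.  Initial velocities are zero.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    span = hi - lo
    m, k = config.swarm_size, config.dims

    X = rng.uniform(lo, hi, size=(m, k))
    if init_positions is not None:
        seeds = np.atleast_2d(np.asarray(init_positions, dtype=float))
        if seeds.shape[1] != k or seeds.shape[0] > m:
            raise ValidationError("init_positions must be (<=m, K)")
        if np.any(seeds < lo) or np.any(seeds > hi):
            raise ValidationError("init_positions must lie inside the bounds")
        X[: seeds.shape[0]] = seeds
    V = np.zeros((m, k))
    vmax = config.velocity_clamp * span

    f = _evaluate(objective, X)
    pbest, pbest_f = X.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    history = [gbest_f]

    for _ in range(config.max_iters):
        r1 = rng.random((m, k))
        r2 = rng.random((m, k))
        V = (
            config.inertia * V
            + config.cognitive * r1 * (pbest - X)
            + config.social * r2 * (gbest - X)
        )
        np.clip(V, -vmax, vmax, out=V)
        X = X + V
        low_hit = X < lo
        high_hit = X > hi
        np.clip(X, lo, hi, out=X)
        V[low_hit | high_hit] = 0.0

        f = _evaluate(objective, X)
        improved = f < pbest_f
        pbest[improved] = X[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        history.append(gbest_f)

    return PSOResult(position=gbest, value=gbest_f, history=np.asarray(history))


def identify_pd(
    observed: BISTrace,
    ce: ConcentrationTrace,
    bounds: Sequence[tuple[float, float]] | None = None,
    config: PSOConfig | None = None,
    interpolate: bool = False,
    n_restarts: int = 1,
    initial_guess: PDParams | None = None,
) -> FitResult:
    """Identify (E0, Emax, EC50, gamma) from an observed BIS trace.

    Minimizes RMSE(observed BIS, Hill(Ce; theta)) over the search box with
    PSO.  ``observed`` must share the concentration trace's grid unless
    ``interpolate`` is set, in which case it is linearly interpolated onto
    it.  ``n_restarts`` independent swarms (seeds spawned deterministically
    from ``config.seed``) are run and the best solution returned; the
    histories are concatenated restart by restart.  ``initial_guess`` seeds
    one particle of every swarm at the given parameters (a warm start, e.g.
    when refining a previous fit).

    Notes
    -----
    When the trace never leaves baseline (Ce = 0) only E0 is identifiable;
    the remaining parameters are returned as the swarm left them.  If the
    swarm's Emax exceeds its E0 — possible only in such unidentifiable
    regimes, where the objective is flat in Emax — Emax is clipped to E0 so
    the returned parameters are a valid Hill curve.
    """
    if observed.t.size == 0 or ce.t.size == 0:
        raise ValidationError("empty trace")
    if observed.t.size == ce.t.size and np.allclose(observed.t, ce.t):
        obs = observed.bis
    elif interpolate:
        obs = np.interp(ce.t, observed.t, observed.bis)
    else:
        raise ValidationError(
            "observed and concentration traces are on different grids; "
            "pass interpolate=True to resample"
        )

    if config is None:
        config = PSOConfig(bounds=tuple(bounds) if bounds is not None else DEFAULT_PD_BOUNDS)
    elif bounds is not None:
        config = replace(config, bounds=tuple(bounds))
    if config.dims != 4:
        raise ValidationError("PD identification searches exactly 4 dimensions")

    ce_vals = ce.ce

    def objective(theta: np.ndarray) -> float:
        e0, emax, ec50, gamma = theta
        num = np.power(ce_vals, gamma)
        pred = e0 - emax * num / (ec50**gamma + num)
        return float(np.sqrt(np.mean((obs - pred) ** 2)))

    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_restarts) % (2**31)
    warm = None
    if initial_guess is not None:
        warm = np.array([[initial_guess.e0, initial_guess.emax,
                          initial_guess.ec50, initial_guess.gamma]])
        lo = np.array([b[0] for b in config.bounds])
        hi = np.array([b[1] for b in config.bounds])
        warm = np.clip(warm, lo, hi)
    best: PSOResult | None = None
    histories = []
    for s in seeds:
        res = pso_minimize(objective, replace(config, seed=int(s)), init_positions=warm)
        histories.append(res.history)
        if best is None or res.value < best.value:
            best = res

    e0, emax, ec50, gamma = best.position
    pd = PDParams(e0=float(e0), emax=float(min(emax, e0)), ec50=float(ec50), gamma=float(gamma))
    fitted = bis_from_ce(ce_vals, pd)
    return FitResult(
        pd=pd,
        objective_value=best.value,
        metrics=_lenient_report(obs, fitted),
        history=np.concatenate(histories),
        fitted=BISTrace(t=ce.t, bis=fitted),
    )


def _lenient_report(obs: np.ndarray, pred: np.ndarray) -> metrics.EvalReport:
    """EvalReport that degrades to NaN where a metric is undefined
    (constant observations for R^2, zeros for MAPE) instead of raising."""
    try:
        r2 = metrics.r_squared(obs, pred)
    except metrics.UndefinedMetricError:
        r2 = float("nan")
    try:
        mape_val = metrics.mape(obs, pred)
    except metrics.UndefinedMetricError:
        mape_val = float("nan")
    return metrics.EvalReport(r2=r2, rmse=metrics.rmse(obs, pred), mape=mape_val, n=int(obs.size))
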