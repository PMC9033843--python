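"""Controllers: adaptive exposure and receding-horizon MPC.

The MPC explores every binary light profile over the horizon (2^H
candidates: a 1000 ms pulse is applied or not at each 6-min measurement
interval) and applies the first input of the cost-minimizing profile. With a
maturation delay tau, an input chosen now first affects the output tau
minutes later; candidate profiles are therefore scored on the H steps they
actually influence, after propagating the model through the buffered
(already-committed) delay steps. Costs: sum of squared deviations from the
target (deterministic / population control) or sum of expected absolute
deviations under the FSP predictive distributions (single-cell control).
Ties break toward less total light, then lexicographically off-first.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .cells import GeneExpressionParams, LightProfile
from .estimation import (FspState, KalmanState, _predict_mean,
                         transition_matrix)

__all__ = [
    "ExposureControllerParams",
    "ControlTask",
    "exposure_step",
    "mpc_select_deterministic",
    "mpc_select_single_cell",
    "precompute_open_loop",
    "time_averaged_deviation",
]


@dataclass(frozen=True)
class ExposureControllerParams:
    """Deadband / constant-step exposure regulation."""

    target: float = 3000.0  # fluorescence setpoint, arb. units
    deadband: float = 150.0
    step: float = 10.0  # ms
    e_min: float = 1.0
    e_max: float = 1000.0

    def __post_init__(self) -> None:
        if not self.e_min < self.e_max:
            raise ValueError("require e_min < e_max")
        if self.step <= 0 or self.deadband < 0:
            raise ValueError("require step > 0 and deadband >= 0")


def exposure_step(measured_mean: float, current_exposure: float,
                  params: ExposureControllerParams) -> float:
    """One constant-step exposure adjustment, clamped to [e_min, e_max]."""
    e = current_exposure
    if measured_mean < params.target - params.deadband:
        e += params.step
    elif measured_mean > params.target + params.deadband:
        e -= params.step
    return min(max(e, params.e_min), params.e_max)


@dataclass(frozen=True)
class ControlTask:
    """Receding-horizon tracking task.

    ``target`` maps absolute time (min) to the desired fluorescence; pass a
    scalar for a constant setpoint. Candidate inputs are all 2^H binary
    profiles of length ``horizon_steps``.
    """

    target: object  # callable(min) -> float, or scalar
    horizon_steps: int = 4
    step_min: float = 6.0
    pulse_ms: float = 1000.0
    cost: str = "mse"  # "mse" | "ead"

    def __post_init__(self) -> None:
        if self.horizon_steps < 1:
            raise ValueError("horizon_steps must be >= 1")
        if self.cost not in ("mse", "ead"):
            raise ValueError("cost must be 'mse' or 'ead'")

    def target_at(self, t_min: float) -> float:
        if callable(self.target):
            return float(self.target(t_min))
        return float(self.target)


def candidate_profiles(h: int):
    """All binary profiles of length h, lexicographic with off first."""
    return list(itertools.product((False, True), repeat=h))


def _select(costs, profiles):
    """Argmin with ties toward less light, then off-first lexicographic."""
    best = min(range(len(profiles)),
               key=lambda i: (costs[i], sum(profiles[i]),
                              tuple(int(b) for b in profiles[i])))
    return profiles[best]


def mpc_select_deterministic(
    est: KalmanState,
    task: ControlTask,
    params: GeneExpressionParams,
    t_now_min: float = 0.0,
) -> tuple[bool, tuple]:
    """Choose the next light input for the population (deterministic model).

    Propagates the Kalman mean through the committed delay-buffer steps,
    then through each candidate profile, and scores the squared deviation
    from the target at the H steps the candidates influence.
    """
    dt = task.step_min
    D = len(est.input_buffer)
    m = est.mean
    t = t_now_min
    for u in est.input_buffer:  # committed inputs: identical across candidates
        m = _predict_mean(m, float(u), dt, params)
        t += dt
    profiles = candidate_profiles(task.horizon_steps)
    costs = []
    for prof in profiles:
        mj, tj, cost = m, t, 0.0
        for on in prof:
            mj = _predict_mean(mj, 1.0 if on else 0.0, dt, params)
            tj += dt
            dev = params.alpha * mj - task.target_at(tj)
            cost += dev * dev
        costs.append(cost)
    chosen = _select(costs, profiles)
    return chosen[0], chosen


def mpc_select_single_cell(
    est: FspState,
    task: ControlTask,
    params: GeneExpressionParams,
    t_now_min: float = 0.0,
    log=None,
) -> tuple[bool, tuple]:
    """Choose the next light input for one cell (stochastic model).

    Propagates the FSP distribution through the committed delay steps, then
    through each candidate profile; the cost is the sum over the horizon of
    E|alpha*n - r(t)| under the predictive distributions.
    """
    dt = task.step_min
    N = est.N
    g = params.gamma
    T_off = transition_matrix(N, params.b0, g, dt)
    T_on = transition_matrix(N, params.b0 + params.k, g, dt)
    p = est.p.copy()
    t = t_now_min
    for u in est.input_buffer:  # committed inputs; may be fractional history
        T = T_on if u == 1.0 else T_off if u == 0.0 else transition_matrix(
            N, params.b0 + params.k * float(u), g, dt)
        p = T @ p
        t += dt
    n = np.arange(N + 1)
    fl = params.alpha * n
    profiles = candidate_profiles(task.horizon_steps)
    costs = []
    for prof in profiles:
        pj, tj, cost = p, t, 0.0
        for on in prof:
            pj = (T_on if on else T_off) @ pj
            tj += dt
            total = pj.sum()
            if total <= 0 or not np.isfinite(total):
                cost = math.inf
                break
            cost += float(np.dot(pj / total, np.abs(fl - task.target_at(tj))))
        costs.append(cost)
    if not any(math.isfinite(c) for c in costs):
        if log is not None:
            log.warning("control", "all candidate costs non-finite; "
                        "falling back to all-off")
        off = tuple([False] * task.horizon_steps)
        return False, off
    chosen = _select(costs, profiles)
    return chosen[0], chosen


def precompute_open_loop(
    model: GeneExpressionParams,
    task: ControlTask,
    total_steps: int,
    p0: float = 0.0,
    input_history: tuple | None = None,
) -> LightProfile:
    """Plan a full light profile on the model alone (no measurements).

    Runs the receding-horizon controller against the deterministic model
    itself, concatenating first-step decisions; the result is applied
    identically to all cells in an open-loop experiment.
    """
    if total_steps < task.horizon_steps:
        raise ValueError("total_steps must be >= the horizon")
    from .estimation import buffer_length

    D = buffer_length(model.tau, task.step_min)
    if input_history is None:
        input_history = (0.0,) * D
    state = KalmanState(mean=p0, variance=0.0, input_buffer=tuple(input_history))
    pulses = []
    t = 0.0
    for _ in range(total_steps):
        on, _prof = mpc_select_deterministic(state, task, model, t_now_min=t)
        pulses.append(on)
        # advance the model plant with the applied input; no measurement
        u = float(state.input_buffer[0]) if state.input_buffer else (1.0 if on else 0.0)
        m = _predict_mean(state.mean, u, task.step_min, model)
        buf = state.input_buffer[1:] + (1.0 if on else 0.0,) if state.input_buffer else ()
        state = KalmanState(m, 0.0, buf)
        t += task.step_min
    return LightProfile(pulses=tuple(pulses), step_min=task.step_min,
                        pulse_ms=task.pulse_ms)


def time_averaged_deviation(values: np.ndarray, targets: np.ndarray,
                            squared: bool = False) -> float:
    """Control performance: mean |y - r| (or squared) over measurement times."""
    values = np.asarray(values, dtype=float)
    targets = np.asarray(targets, dtype=float)
    dev = values - targets
    return float(np.mean(dev * dev)) if squared else float(np.mean(np.abs(dev)))
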