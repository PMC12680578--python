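"""Batch-reactor simulation of the hydrogenation cascade.

The experimental reactor is isothermal and operates at constant H2 pressure
(continuous insufflation at a regulated set-point), so the only state is
the vector of relative molar fractions X = (X_A, X_B, X_C, X_D) and the
mass balances reduce to dX_i/dt = r_i(X) with the mechanism-specific
Hougen-Watson rates.  Time is measured in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    Composition,
    MechanismSpec,
    OperatingConditions,
    ParameterVector,
    T_MEAN_DEFAULT,
    evaluate_constants,
    get_mechanism,
)

__all__ = [
    "TestSpec",
    "Trajectory",
    "IntegrationError",
    "SolverOptions",
    "simulate",
    "predict_at_samples",
]

_SUM_TOL = 1e-6


class _RhsBudgetExceeded(Exception):
    pass


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the solver's diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SolverOptions:
    """Integrator settings (stiff-capable; LSODA switches automatically).

    ``max_rhs_calls`` bounds the work per integration: extreme parameter
    draws during multistart regression can make the ODEs pathologically
    stiff, and hitting the budget raises :class:`IntegrationError` (which
    the optimizer treats as an infeasible point) instead of stalling.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_rhs_calls: int = 500_000


@dataclass(frozen=True)
class TestSpec:
    """Conditions and sampling schedule of one batch test.

    Temperatures are given in degC and pressures in MPa, mirroring how
    operating conditions are reported for this kind of experiment; they are
    converted to K and bar internally.
    """

    test_id: str
    temperature_c: float
    p_h2_mpa: float
    t_fin: float  # minutes
    sample_times: tuple[float, ...]  # minutes, strictly ascending in [0, t_fin]
    initial_composition: Composition

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times)
        object.__setattr__(self, "sample_times", times)
        if len(times) == 0:
            raise ValueError("at least one sample time is required")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("sample times must be strictly ascending")
        if times[0] < 0 or times[-1] > self.t_fin:
            raise ValueError("sample times must lie within [0, t_fin]")

    def conditions(self, t_mean: float = T_MEAN_DEFAULT) -> OperatingConditions:
        # degC -> K; MPa -> bar
        return OperatingConditions(
            temperature=self.temperature_c + 273.15,
            p_h2=self.p_h2_mpa * 10.0,
            t_mean=t_mean,
        )


@dataclass(frozen=True)
class Trajectory:
    """Simulated composition-vs-time solution for one test."""

    test: TestSpec
    times: np.ndarray  # minutes
    states: np.ndarray  # shape (n_times, 4)
    diagnostics: dict = field(default_factory=dict, compare=False)

    def state_at(self, index: int) -> Composition:
        return Composition.from_array(self.states[index])


def _validate_states(times: np.ndarray, states: np.ndarray) -> np.ndarray:
    states = np.where(states < 0.0, 0.0, states)
    drift = np.abs(states.sum(axis=1) - 1.0)
    if np.any(drift > _SUM_TOL):
        i = int(np.argmax(drift))
        raise IntegrationError(
            f"mole-fraction conservation drift {drift[i]:.3e} at "
            f"t={times[i]:g} min exceeds {_SUM_TOL:g}",
            {"max_drift": float(drift.max())},
        )
    return states


def simulate(
    mech: str | MechanismSpec,
    params: ParameterVector,
    test: TestSpec,
    solver_opts: SolverOptions | None = None,
    *,
    t_mean: float = T_MEAN_DEFAULT,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the batch mass balances for one test.

    Returns the states at ``times`` (default: the test's sampling schedule).
    Raises :class:`IntegrationError` if the solver does not converge or the
    mole-fraction total drifts by more than 1e-6.
    """
    mech = get_mechanism(mech)
    opts = solver_opts or SolverOptions()
    cond = test.conditions(t_mean)
    constants = evaluate_constants(params, cond)
    rates = mech.rate_factory(constants, cond.p_h2)

    t_eval = np.asarray(
        test.sample_times if times is None else list(times), dtype=float
    )
    x0 = test.initial_composition.as_array()
    t_end = float(t_eval[-1]) if len(t_eval) else 0.0

    if t_end == 0.0:
        states = np.tile(x0, (len(t_eval), 1))
        return Trajectory(test, t_eval, states, {"nfev": 0, "solver": opts.method})

    ncalls = 0

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        nonlocal ncalls
        ncalls += 1
        if ncalls > opts.max_rhs_calls:
            raise _RhsBudgetExceeded
        # solver trial states may dip slightly negative; evaluate on the
        # clamped state so denominators stay >= 1
        return rates(np.where(x < 0.0, 0.0, x))

    try:
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            x0,
            method=opts.method,
            t_eval=t_eval,
            rtol=opts.rtol,
            atol=opts.atol,
        )
    except _RhsBudgetExceeded:
        raise IntegrationError(
            f"integration of test {test.test_id!r} exceeded the budget of "
            f"{opts.max_rhs_calls} rhs evaluations",
            {"nfev": ncalls, "solver": opts.method},
        ) from None
    if not sol.success:
        raise IntegrationError(
            f"integration of test {test.test_id!r} failed: {sol.message}",
            {"nfev": sol.nfev, "status": sol.status, "solver": opts.method},
        )
    states = sol.y.T.copy()
    # the solver's dense interpolation at t = 0 can wobble in the last bit;
    # the initial state is known exactly
    states[t_eval == 0.0] = x0
    states = _validate_states(sol.t, states)
    diagnostics = {
        "nfev": int(sol.nfev),
        "solver": opts.method,
        "rtol": opts.rtol,
        "atol": opts.atol,
        "max_drift": float(np.abs(states.sum(axis=1) - 1.0).max()),
    }
    return Trajectory(test, t_eval, states, diagnostics)


def predict_at_samples(
    mech: str | MechanismSpec,
    params: ParameterVector,
    test: TestSpec,
    solver_opts: SolverOptions | None = None,
    *,
    t_mean: float = T_MEAN_DEFAULT,
) -> np.ndarray:
    """Model compositions at the test's sample times, shape (n_samples, 4).

    These are the predicted counterparts of the measured molar fractions
    entering the global least-squares objective.
    """
    traj = simulate(mech, params, test, solver_opts, t_mean=t_mean)
    return traj.states
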