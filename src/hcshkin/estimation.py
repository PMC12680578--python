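"""Global nonlinear least-squares estimation of kinetic parameters.

All tests of a campaign are regressed simultaneously: the objective is the
global sum of squared residuals over every test, sample time and component,

    SSR_global = sum_h sum_j sum_i (X_ijh - Xhat_ijh)^2

where each model prediction Xhat requires integrating the batch mass
balances for the candidate mechanism.  Goodness of fit is summarized by the
overall coefficient of determination R^2 = 1 - SSR_global/SST, with SST the
total sum of squares about the grand mean of all observations, and by a
per-(component, test) decomposition of the residual sum.  Candidate
mechanisms are compared on R^2 first; statistically comparable fits
(R^2 within 0.005) are discriminated by parameter count (Occam's razor).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    COMPONENTS,
    ConstantKind,
    MechanismSpec,
    ParameterVector,
    T_MEAN_DEFAULT,
    get_mechanism,
    parameter_dimension,
)
from .reactor import IntegrationError, SolverOptions, TestSpec, predict_at_samples

__all__ = [
    "KineticDataset",
    "FitOptions",
    "FitResult",
    "ModelComparison",
    "ssr_global",
    "sst",
    "r_squared",
    "ssr_component",
    "fit",
    "parameter_uncertainty",
    "linearized_covariance",
    "compare_models",
]

logger = logging.getLogger(__name__)

_RAW_SUM_TOL = 0.02
_IDENTITY_TOL = 1e-10


@dataclass(frozen=True)
class KineticDataset:
    """Observed compositions at the sample times of one or more tests."""

    tests: list[TestSpec]
    observations: dict[str, np.ndarray]  # test_id -> (n_samples, 4)

    def __post_init__(self) -> None:
        if not self.tests:
            raise ValueError("dataset must contain at least one test")
        for test in self.tests:
            if test.test_id not in self.observations:
                raise ValueError(f"no observations for test {test.test_id!r}")
            obs = np.asarray(self.observations[test.test_id], dtype=float)
            self.observations[test.test_id] = obs
            if obs.shape != (len(test.sample_times), 4):
                raise ValueError(
                    f"test {test.test_id!r}: observations shape {obs.shape} "
                    f"does not match {len(test.sample_times)} sample times"
                )
            if obs.shape[0] < 2:
                raise ValueError(
                    f"test {test.test_id!r}: at least 2 sample times required"
                )
            sums = obs.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _RAW_SUM_TOL) or np.any(obs < 0):
                raise ValueError(
                    f"test {test.test_id!r}: observations violate the "
                    f"composition constraints (sum within {_RAW_SUM_TOL})"
                )

    def n_observations(self) -> int:
        """Total number of scalar observations (samples x 4 components)."""
        return sum(obs.size for obs in self.observations.values())

    def stacked(self) -> np.ndarray:
        return np.concatenate(
            [self.observations[t.test_id].ravel() for t in self.tests]
        )

    def fingerprint(self) -> str:
        """Stable digest identifying the dataset (used to guard comparisons)."""
        h = hashlib.sha256()
        for test in self.tests:
            h.update(test.test_id.encode())
            h.update(np.asarray(test.sample_times).tobytes())
            h.update(self.observations[test.test_id].tobytes())
        return h.hexdigest()


def _check_alignment(
    data: KineticDataset, predictions: Mapping[str, np.ndarray]
) -> None:
    for test in data.tests:
        if test.test_id not in predictions:
            raise ValueError(f"missing predictions for test {test.test_id!r}")
        pred = np.asarray(predictions[test.test_id])
        if pred.shape != data.observations[test.test_id].shape:
            raise ValueError(
                f"test {test.test_id!r}: prediction shape {pred.shape} does "
                f"not match observations "
                f"{data.observations[test.test_id].shape}"
            )


def ssr_global(
    data: KineticDataset, predictions: Mapping[str, np.ndarray]
) -> float:
    """Global sum of squared residuals over tests, samples and components.

    Unweighted; all four components and every sample (including t = 0)
    contribute.
    """
    _check_alignment(data, predictions)
    total = 0.0
    for test in data.tests:
        resid = data.observations[test.test_id] - np.asarray(
            predictions[test.test_id], dtype=float
        )
        total += float(np.sum(resid**2))
    return total


def sst(data: KineticDataset) -> float:
    """Total sum of squares about the grand mean of all observations."""
    stacked = data.stacked()
    return float(np.sum((stacked - stacked.mean()) ** 2))


def r_squared(ssr: float, sst_value: float) -> float:
    """Overall explained variance, R^2 = 1 - SSR/SST."""
    if not sst_value > 0:
        raise ValueError("SST must be > 0 to compute R^2")
    return 1.0 - ssr / sst_value


def ssr_component(
    data: KineticDataset,
    predictions: Mapping[str, np.ndarray],
    component: str,
    test_id: str,
) -> float:
    """Residual sum for one component in one test.

    Summed over all 4 components and all tests this recovers the global SSR.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected A/B/C/D")
    if test_id not in data.observations:
        raise ValueError(f"unknown test {test_id!r}")
    _check_alignment(data, predictions)
    i = COMPONENTS.index(component)
    resid = data.observations[test_id][:, i] - np.asarray(
        predictions[test_id], dtype=float
    )[:, i]
    return float(np.sum(resid**2))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    """Options for the global regression.

    Pre-exponentials are optimized in log10 space (positivity for free);
    energies stay linear.  Multistart draws pre-exponentials log-uniformly
    and energies uniformly within the bounds.  ``max_nfev`` caps the
    residual evaluations per start; the fit-time integrator carries a
    small rhs-call budget so that pathological parameter draws register as
    infeasible instead of stalling the regression.
    """

    n_multistart: int = 20
    seed: int = 42
    log10_preexp_bounds: tuple[float, float] = (-6.0, 6.0)
    ea_bounds: tuple[float, float] = (0.0, 300.0)  # kJ/mol, rate constants
    dh_bounds: tuple[float, float] = (-300.0, 300.0)  # kJ/mol, equilibria
    ftol: float = 1e-10
    xtol: float = 1e-10
    #: relative finite-difference step for the residual Jacobian; must stay
    #: well above the integrator's relative tolerance or the differences
    #: measure solver noise instead of sensitivity
    diff_step: float = 1e-4
    #: trust-region scaling; "jac" (scale from the Jacobian columns) copes
    #: with the very different sensitivities of log-pre-exponentials and
    #: energies and is decisive for traversing the sloppy valleys of these
    #: rate laws
    x_scale: str | float = "jac"
    max_nfev: int | None = 400
    #: stop launching further starts once one attains an essentially exact
    #: fit (SSR at or below this); remaining starts cannot improve on it
    stop_at_cost: float = 1e-12
    #: multistart exploration runs at a slightly loosened integrator
    #: tolerance for speed; the winning start is then polished (and all
    #: reported statistics computed) at the reference tolerance below
    solver_opts: SolverOptions = field(
        default_factory=lambda: SolverOptions(
            rtol=1e-7, atol=1e-9, max_rhs_calls=20_000
        )
    )
    polish: bool = True
    polish_diff_step: float = 1e-5
    polish_solver_opts: SolverOptions = field(
        default_factory=lambda: SolverOptions(max_rhs_calls=100_000)
    )
    initial_guesses: tuple[ParameterVector, ...] = ()
    t_mean: float = T_MEAN_DEFAULT


@dataclass(frozen=True)
class FitResult:
    """Outcome of one global regression (best multistart)."""

    mechanism_id: str
    params: ParameterVector
    ssr_global: float
    sst: float
    r_squared: float
    ssr_table: dict[tuple[str, str], float]  # (component, test_id) -> SSR
    param_std: np.ndarray | None
    param_std_pct: np.ndarray | None
    diagnostics: dict
    dataset_fingerprint: str

    def __post_init__(self) -> None:
        if abs(self.r_squared - (1.0 - self.ssr_global / self.sst)) > _IDENTITY_TOL:
            raise ValueError("R^2 inconsistent with SSR/SST")
        table_sum = sum(self.ssr_table.values())
        if abs(table_sum - self.ssr_global) > max(
            _IDENTITY_TOL, _IDENTITY_TOL * self.ssr_global
        ):
            raise ValueError("component SSR table does not sum to SSR_global")

    @property
    def n_parameters(self) -> int:
        return parameter_dimension(self.mechanism_id)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


def _transform_bounds(
    mech: MechanismSpec, options: FitOptions
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for lab in mech.constant_labels:
        lo.append(options.log10_preexp_bounds[0])
        hi.append(options.log10_preexp_bounds[1])
        if lab.startswith("k"):
            lo.append(options.ea_bounds[0])
            hi.append(options.ea_bounds[1])
        else:
            lo.append(options.dh_bounds[0])
            hi.append(options.dh_bounds[1])
    return np.array(lo), np.array(hi)


def _to_z(params: ParameterVector) -> np.ndarray:
    z = params.values.copy()
    z[0::2] = np.log10(z[0::2])
    return z


def _from_z(mechanism_id: str, z: np.ndarray) -> ParameterVector:
    vals = np.asarray(z, dtype=float).copy()
    vals[0::2] = 10.0 ** vals[0::2]
    return ParameterVector(mechanism_id, vals)


def _predictions(
    mech: MechanismSpec,
    params: ParameterVector,
    data: KineticDataset,
    solver_opts: SolverOptions,
    t_mean: float,
) -> dict[str, np.ndarray]:
    return {
        test.test_id: predict_at_samples(
            mech, params, test, solver_opts, t_mean=t_mean
        )
        for test in data.tests
    }


def _make_residual(
    mech: MechanismSpec,
    data: KineticDataset,
    options: FitOptions,
    solver_opts: SolverOptions,
):
    observed = data.stacked()
    n = observed.size

    def residual(z: np.ndarray) -> np.ndarray:
        try:
            with warnings.catch_warnings():
                # extreme trial points trigger solver chatter; the budget
                # in SolverOptions already guards against stalls
                warnings.simplefilter("ignore")
                params = _from_z(mech.mechanism_id, z)
                preds = _predictions(
                    mech, params, data, solver_opts, options.t_mean
                )
        except (IntegrationError, ValueError, OverflowError):
            # infeasible point: push the optimizer away with a large,
            # finite penalty
            return np.full(n, 1e3)
        stacked = np.concatenate(
            [preds[t.test_id].ravel() for t in data.tests]
        )
        return stacked - observed

    return residual


def fit(
    mech: str | MechanismSpec,
    data: KineticDataset,
    options: FitOptions | None = None,
) -> FitResult:
    """Minimize the global SSR over the kinetic parameter vector.

    Bounded trust-region-reflective least squares with multistart; every
    residual evaluation integrates the batch ODEs for every test.  The best
    start (lowest SSR) is returned, with full fit statistics and linearized
    parameter uncertainties.  Reproducible for a given ``options.seed``.
    """
    mech = get_mechanism(mech)
    options = options or FitOptions()
    lo, hi = _transform_bounds(mech, options)
    residual = _make_residual(mech, data, options, options.solver_opts)
    rng = np.random.default_rng(options.seed)

    starts: list[np.ndarray] = []
    for guess in options.initial_guesses:
        if guess.mechanism_id != mech.mechanism_id:
            raise ValueError(
                f"initial guess is for mechanism {guess.mechanism_id!r}"
            )
        starts.append(np.clip(_to_z(guess), lo, hi))
    for _ in range(options.n_multistart):
        starts.append(rng.uniform(lo, hi))
    if not starts:
        raise ValueError("no starts: set n_multistart > 0 or pass initial_guesses")

    best = None
    start_costs: list[float] = []
    n_failed = 0
    for idx, z0 in enumerate(starts):
        try:
            res = least_squares(
                residual,
                z0,
                bounds=(lo, hi),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                diff_step=options.diff_step,
                x_scale=options.x_scale,
                max_nfev=options.max_nfev,
            )
        except Exception as exc:  # noqa: BLE001 - any start may blow up
            logger.debug("start %d failed: %s", idx, exc)
            n_failed += 1
            continue
        cost = 2.0 * res.cost  # least_squares cost = 0.5 * SSR
        start_costs.append(cost)
        logger.debug(
            "mechanism %s start %d: SSR=%.6g nfev=%d status=%d",
            mech.mechanism_id, idx, cost, res.nfev, res.status,
        )
        if best is None or cost < best[1]:
            best = (idx, cost, res)
        if best[1] <= options.stop_at_cost:
            logger.debug("start %d reached SSR %.3e; stopping early", idx, cost)
            break
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} starts failed for mechanism "
            f"{mech.mechanism_id!r} ({n_failed} exceptions)"
        )

    idx, _cost, res = best
    polished = False
    if options.polish:
        polish_residual = _make_residual(
            mech, data, options, options.polish_solver_opts
        )
        try:
            res_p = least_squares(
                polish_residual,
                res.x,
                bounds=(lo, hi),
                method="trf",
                ftol=options.ftol,
                xtol=options.xtol,
                diff_step=options.polish_diff_step,
                x_scale=options.x_scale,
                max_nfev=options.max_nfev,
            )
            if res_p.cost <= res.cost:
                res = res_p
                polished = True
        except Exception as exc:  # noqa: BLE001
            logger.debug("polish failed: %s", exc)
    params = _from_z(mech.mechanism_id, res.x)
    preds = _predictions(
        mech, params, data, options.polish_solver_opts, options.t_mean
    )
    ssr = ssr_global(data, preds)
    sst_value = sst(data)
    table = {
        (comp, test.test_id): ssr_component(data, preds, comp, test.test_id)
        for test in data.tests
        for comp in COMPONENTS
    }
    # make the additivity identity exact against accumulation-order round-off
    ssr = float(sum(table.values()))
    diagnostics = {
        "multistart_index": idx,
        "n_starts": len(starts),
        "n_starts_run": len(start_costs) + n_failed,
        "n_failed_starts": n_failed,
        "start_costs": start_costs,
        "nfev": int(res.nfev),
        "status": int(res.status),
        "polished": polished,
        "converged": bool(res.success) and n_failed == 0,
        "seed": options.seed,
    }
    result = FitResult(
        mechanism_id=mech.mechanism_id,
        params=params,
        ssr_global=ssr,
        sst=sst_value,
        r_squared=r_squared(ssr, sst_value),
        ssr_table=table,
        param_std=None,
        param_std_pct=None,
        diagnostics=diagnostics,
        dataset_fingerprint=data.fingerprint(),
    )
    std, pct = parameter_uncertainty(result, data, options)
    return FitResult(
        **{
            **result.__dict__,
            "param_std": std,
            "param_std_pct": pct,
        }
    )


# ---------------------------------------------------------------------------
# Uncertainty
# ---------------------------------------------------------------------------


def linearized_covariance(
    jacobian: np.ndarray, ssr: float, n_obs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Newton covariance s^2 (J^T J)^-1 from a residual Jacobian.

    Returns ``(variances, singular_flags)``.  Directions of J^T J with
    eigenvalues below ``max_eig * 1e-12`` are treated as unidentifiable:
    parameters with weight in those directions get infinite variance (a
    warning is emitted), matching the behaviour wanted for rank-deficient
    designs rather than raising.
    """
    jacobian = np.asarray(jacobian, dtype=float)
    n, p = jacobian.shape
    if n_obs <= p:
        raise ValueError("need more observations than parameters")
    s2 = ssr / (n_obs - p)
    jtj = jacobian.T @ jacobian
    eigvals, eigvecs = np.linalg.eigh(jtj)
    tol = max(eigvals.max(), 0.0) * 1e-12
    singular = eigvals <= tol
    if np.any(singular):
        warnings.warn(
            f"{int(singular.sum())} unidentifiable parameter direction(s); "
            "reporting infinite standard deviation",
            RuntimeWarning,
            stacklevel=2,
        )
    variances = np.zeros(p)
    for j in range(p):
        w2 = eigvecs[j, :] ** 2
        # a parameter is unidentifiable if it has non-trivial weight in a
        # flat direction (the 1e-6 floor ignores eigenvector round-off)
        if np.any(singular & (w2 > 1e-6)):
            variances[j] = np.inf
        else:
            good = ~singular
            variances[j] = s2 * float(np.sum(w2[good] / eigvals[good]))
    if s2 == 0.0:
        # a perfect fit pins every identifiable direction; report zeros
        variances = np.where(np.isinf(variances), np.inf, 0.0)
    return variances, singular


def parameter_uncertainty(
    fit_result: FitResult,
    data: KineticDataset,
    options: FitOptions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearized (Gauss-Newton) standard deviations of the fitted parameters.

    The residual Jacobian is built by forward differences in the natural
    parameter space at the optimum; covariance is s^2 (J^T J)^-1 with
    s^2 = SSR/(N - p).  Returns ``(std, percent_std)`` where percent is
    100 * std / |estimate|.  An exactly zero-residual fit yields zero
    standard deviations; unidentifiable directions yield infinite ones.
    """
    options = options or FitOptions()
    mech = get_mechanism(fit_result.mechanism_id)
    p0 = fit_result.params.values
    base = np.concatenate(
        [
            _predictions(
                mech, fit_result.params, data,
                options.polish_solver_opts, options.t_mean,
            )[t.test_id].ravel()
            for t in data.tests
        ]
    )
    n_obs = base.size
    jac = np.empty((n_obs, p0.size))
    for j in range(p0.size):
        h = 1e-6 * max(abs(p0[j]), 1e-3)
        pj = p0.copy()
        pj[j] += h
        try:
            pred_j = np.concatenate(
                [
                    _predictions(
                        mech,
                        ParameterVector(mech.mechanism_id, pj),
                        data,
                        options.polish_solver_opts,
                        options.t_mean,
                    )[t.test_id].ravel()
                    for t in data.tests
                ]
            )
        except (IntegrationError, ValueError):
            jac[:, j] = 0.0
            continue
        jac[:, j] = (pred_j - base) / h

    if fit_result.ssr_global == 0.0:
        return np.zeros(p0.size), np.zeros(p0.size)
    variances, _flags = linearized_covariance(
        jac, fit_result.ssr_global, n_obs
    )
    std = np.sqrt(variances)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * std / np.abs(p0)
    return std, pct


# ---------------------------------------------------------------------------
# Model discrimination
# ---------------------------------------------------------------------------

#: fits whose R^2 differ by no more than this are statistically comparable
#: and are discriminated by parameter count instead
R2_COMPARABLE_BAND = 0.005


@dataclass(frozen=True)
class ModelComparison:
    """Ranked mechanism fits with tabular summaries."""

    ranking: tuple[FitResult, ...]

    def summary_rows(self) -> list[dict]:
        """One row per mechanism: id, parameter count, SSR, R^2, rank."""
        return [
            {
                "rank": i + 1,
                "mechanism": f.mechanism_id,
                "n_parameters": f.n_parameters,
                "ssr_global": f.ssr_global,
                "r_squared": f.r_squared,
            }
            for i, f in enumerate(self.ranking)
        ]

    def ssr_grid_rows(self) -> list[dict]:
        """Per-(mechanism, test) rows of component residual sums."""
        rows = []
        for f in self.ranking:
            test_ids = sorted({t for (_c, t) in f.ssr_table})
            for test_id in test_ids:
                rows.append(
                    {
                        "mechanism": f.mechanism_id,
                        "test_id": test_id,
                        **{
                            f"ssr_{c}": f.ssr_table[(c, test_id)]
                            for c in COMPONENTS
                        },
                    }
                )
        return rows

    @property
    def best(self) -> FitResult:
        return self.ranking[0]


def compare_models(fits: Sequence[FitResult]) -> ModelComparison:
    """Rank fitted mechanisms: higher R^2 wins; fits within 0.005 of one
    another are discriminated by the lower parameter count (parsimony).

    All fits must come from the same dataset.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    fingerprints = {f.dataset_fingerprint for f in fits}
    if len(fingerprints) > 1:
        raise ValueError("fits were obtained on different datasets")

    import functools

    def beats(a: FitResult, b: FitResult) -> int:
        if abs(a.r_squared - b.r_squared) <= R2_COMPARABLE_BAND:
            if a.n_parameters != b.n_parameters:
                return -1 if a.n_parameters < b.n_parameters else 1
            return -1 if a.r_squared > b.r_squared else 1
        return -1 if a.r_squared > b.r_squared else 1

    ranking = tuple(sorted(fits, key=functools.cmp_to_key(beats)))
    return ModelComparison(ranking)
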