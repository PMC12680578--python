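"""File formats: dataset CSV dialect, trajectory CSV, fit reports.

Dataset dialect (one row per sample, conditions repeated for
self-containedness)::

    test_id,time_min,temperature_C,pH2_MPa,XA,XB,XC,XD

Rows whose four fractions sum within [0.98, 1.02] are renormalized to 1 on
load; anything further off is rejected as a measurement-entry error.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .estimation import FitResult, KineticDataset, ModelComparison
from .kinetics import COMPONENTS, Composition
from .reactor import TestSpec, Trajectory

__all__ = [
    "DATASET_COLUMNS",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "write_trajectories_csv",
    "fit_report_dict",
    "write_fit_report_json",
    "write_parameter_table_csv",
    "write_comparison_tables",
]

DATASET_COLUMNS = (
    "test_id",
    "time_min",
    "temperature_C",
    "pH2_MPa",
    "XA",
    "XB",
    "XC",
    "XD",
)

_FRACTION_COLS = ("XA", "XB", "XC", "XD")
_ROW_SUM_BAND = (0.98, 1.02)


class SchemaError(ValueError):
    """The file does not conform to the dataset CSV dialect."""


def write_dataset(data: KineticDataset, path: str | Path) -> None:
    rows = []
    for test in data.tests:
        obs = data.observations[test.test_id]
        for t, x in zip(test.sample_times, obs):
            rows.append(
                {
                    "test_id": test.test_id,
                    "time_min": t,
                    "temperature_C": test.temperature_c,
                    "pH2_MPa": test.p_h2_mpa,
                    **dict(zip(_FRACTION_COLS, x)),
                }
            )
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, index=False)


def read_dataset(path: str | Path) -> KineticDataset:
    """Parse and validate a dataset CSV; returns the in-memory dataset.

    The t = 0 row of each test (required) provides the initial composition.
    """
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    sums = df[list(_FRACTION_COLS)].sum(axis=1)
    bad = (sums < _ROW_SUM_BAND[0]) | (sums > _ROW_SUM_BAND[1])
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise SchemaError(
            f"row {i}: fractions sum to {sums.iloc[i]:.4f}, outside "
            f"[{_ROW_SUM_BAND[0]}, {_ROW_SUM_BAND[1]}]"
        )
    frac = df[list(_FRACTION_COLS)].to_numpy(dtype=float)
    frac = frac / frac.sum(axis=1, keepdims=True)
    df = df.assign(**dict(zip(_FRACTION_COLS, frac.T)))

    tests: list[TestSpec] = []
    observations: dict[str, np.ndarray] = {}
    for test_id, grp in df.groupby("test_id", sort=False):
        grp = grp.sort_values("time_min")
        temps = grp["temperature_C"].unique()
        pressures = grp["pH2_MPa"].unique()
        if len(temps) > 1 or len(pressures) > 1:
            raise SchemaError(
                f"test {test_id!r}: temperature/pressure must be constant"
            )
        times = grp["time_min"].to_numpy(dtype=float)
        obs = grp[list(_FRACTION_COLS)].to_numpy(dtype=float)
        if times[0] != 0.0:
            raise SchemaError(
                f"test {test_id!r}: a t = 0 row is required (initial "
                "composition)"
            )
        tests.append(
            TestSpec(
                test_id=str(test_id),
                temperature_c=float(temps[0]),
                p_h2_mpa=float(pressures[0]),
                t_fin=float(times[-1]),
                sample_times=tuple(times),
                initial_composition=Composition.from_array(obs[0]),
            )
        )
        observations[str(test_id)] = obs
    return KineticDataset(tests, observations)


def write_trajectories_csv(
    trajectories: Iterable[Trajectory], path: str | Path
) -> None:
    """Tidy CSV: test_id, time_min, XA, XB, XC, XD."""
    rows = []
    for traj in trajectories:
        for t, x in zip(traj.times, traj.states):
            rows.append(
                {
                    "test_id": traj.test.test_id,
                    "time_min": float(t),
                    **dict(zip(_FRACTION_COLS, x)),
                }
            )
    pd.DataFrame(
        rows, columns=["test_id", "time_min", *_FRACTION_COLS]
    ).to_csv(path, index=False)


def _jsonify(value):
    if isinstance(value, np.ndarray):
        return [None if not np.isfinite(v) else float(v) for v in value]
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, float) and not np.isfinite(value):
        return None
    if isinstance(value, dict):
        return {str(k): _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    return value


def fit_report_dict(result: FitResult) -> dict:
    """JSON-serializable view of a fit, with full provenance."""
    labels = [c.label for c in result.params.constants()]
    return _jsonify(
        {
            "mechanism": result.mechanism_id,
            "n_parameters": result.n_parameters,
            "ssr_global": result.ssr_global,
            "sst": result.sst,
            "r_squared": result.r_squared,
            "parameters": {
                lab: {
                    "preexponential": result.params.values[2 * i],
                    "energy_kJ_mol": result.params.values[2 * i + 1],
                    "preexponential_std": (
                        None
                        if result.param_std is None
                        else result.param_std[2 * i]
                    ),
                    "energy_std": (
                        None
                        if result.param_std is None
                        else result.param_std[2 * i + 1]
                    ),
                }
                for i, lab in enumerate(labels)
            },
            "ssr_components": {
                f"{comp}|{test_id}": v
                for (comp, test_id), v in sorted(result.ssr_table.items())
            },
            "diagnostics": result.diagnostics,
            "dataset_fingerprint": result.dataset_fingerprint,
        }
    )


def write_fit_report_json(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(fit_report_dict(result), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def write_parameter_table_csv(result: FitResult, path: str | Path) -> None:
    """Flat parameter table: label, kind, value, std, percent std."""
    rows = []
    for i, const in enumerate(result.params.constants()):
        for offset, which in ((0, "preexponential"), (1, "energy")):
            j = 2 * i + offset
            rows.append(
                {
                    "constant": const.label,
                    "kind": const.kind.value,
                    "quantity": which,
                    "value": result.params.values[j],
                    "std": (
                        np.nan
                        if result.param_std is None
                        else result.param_std[j]
                    ),
                    "pct_std": (
                        np.nan
                        if result.param_std_pct is None
                        else result.param_std_pct[j]
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_comparison_tables(
    comparison: ModelComparison, summary_path: str | Path, grid_path: str | Path
) -> None:
    """Model-summary table (id, parameter count, SSR, R^2) and the
    per-(mechanism, test) component-SSR grid."""
    pd.DataFrame(comparison.summary_rows()).to_csv(summary_path, index=False)
    pd.DataFrame(comparison.ssr_grid_rows()).to_csv(grid_path, index=False)
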