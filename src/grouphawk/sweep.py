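"""Parameter sweeps over the analytic solver and tabular writers.

These routines regenerate the model's two standard data products: the
equilibrium profile of (P_L*, P_F*, P*) against the sharing weight omega
for one society, and the regime map over the (omega, epsilon) plane with
the payoff split recomputed at each epsilon.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .equilibrium import Regime, solve_equilibrium
from .errors import GroupHawkError
from .payoffs import ModelConfig

__all__ = [
    "SweepSpec",
    "sweep",
    "equilibrium_profile",
    "regime_map",
    "write_records",
    "DEFAULT_OMEGA_GRID",
    "DEFAULT_EPSILON_GRID",
]

#: Default grids resolve the omega thresholds of typical parameterisations
#: to two decimals at trivial cost.
DEFAULT_OMEGA_GRID = np.round(np.linspace(0.0, 1.0, 101), 10)
#: epsilon = 0 and 1 are invalid societies, so the epsilon grid stays in
#: the open interval.
DEFAULT_EPSILON_GRID = np.round(np.arange(0.01, 0.995, 0.01), 10)

_CONFIG_FIELDS = [f.name for f in dc_fields(ModelConfig)]
_RESULT_FIELDS = [
    "p_leader_star",
    "p_follower_star",
    "p_group_star",
    "regime",
    "omega_lower",
    "omega_upper",
    "vtilde_leader",
    "vtilde_follower",
]
COLUMN_ORDER = _CONFIG_FIELDS + _RESULT_FIELDS + ["error"]


@dataclass(frozen=True)
class SweepSpec:
    """A base society plus one or two parameter axes to scan.

    ``axes`` maps ModelConfig field names to strictly increasing value
    grids; the sweep evaluates the closed-form equilibrium on the cartesian
    product, varying the named fields and holding the rest at ``base``.
    """

    base: ModelConfig
    axes: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("SweepSpec needs one or two axes")
        for name, grid in self.axes.items():
            if name not in _CONFIG_FIELDS:
                raise ValueError(f"unknown sweep axis {name!r}")
            arr = np.asarray(grid, dtype=float)
            if arr.ndim != 1 or len(arr) == 0:
                raise ValueError(f"axis {name!r} must be a non-empty 1-D grid")
            if len(arr) > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"axis {name!r} must be strictly increasing")


def _solve_row(config_kwargs: dict) -> dict:
    row = dict(config_kwargs)
    row.update({k: math.nan for k in _RESULT_FIELDS})
    row["regime"] = ""
    row["error"] = ""
    try:
        config = ModelConfig(**config_kwargs)
        eq = solve_equilibrium(config)
    except GroupHawkError as exc:  # recorded per row, never fatal
        row["error"] = f"{type(exc).__name__}: {exc}"
        return row
    row.update(
        p_leader_star=eq.p_leader_star,
        p_follower_star=eq.p_follower_star,
        p_group_star=eq.p_group_star,
        regime=eq.regime.value,
        omega_lower=eq.omega_lower,
        omega_upper=eq.omega_upper,
        vtilde_leader=eq.vtilde_leader,
        vtilde_follower=eq.vtilde_follower,
    )
    return row


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the closed-form equilibrium on the spec's grid.

    Returns one row per grid point in grid order (the first axis varies
    slowest), with all ModelConfig fields, all equilibrium fields, and an
    ``error`` column that records per-point failures (e.g. a degenerate
    sharing rule) instead of aborting the scan.
    """
    names = list(spec.axes)
    grids = [np.asarray(spec.axes[n], dtype=float) for n in names]
    base_kwargs = {f: getattr(spec.base, f) for f in _CONFIG_FIELDS}
    rows = []
    if len(names) == 1:
        points: Iterable[Tuple[float, ...]] = ((v,) for v in grids[0])
    else:
        points = ((a, b) for a in grids[0] for b in grids[1])
    for values in points:
        kwargs = dict(base_kwargs)
        kwargs.update(zip(names, (float(v) for v in values)))
        rows.append(_solve_row(kwargs))
    return pd.DataFrame(rows, columns=COLUMN_ORDER)


def equilibrium_profile(
    base: ModelConfig, omega_grid: Sequence[float] = DEFAULT_OMEGA_GRID
) -> pd.DataFrame:
    """Equilibrium strategies and regime along an omega scan."""
    return sweep(SweepSpec(base=base, axes={"omega": omega_grid}))


def regime_map(
    base: ModelConfig,
    omega_grid: Sequence[float] = DEFAULT_OMEGA_GRID,
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """2-D sweep over (omega, epsilon) plus per-regime cell counts.

    The payoff split (and hence both class preferences) is recomputed at
    each epsilon; the division biases, C/V and N are held at ``base``.
    """
    eps_arr = np.asarray(epsilon_grid, dtype=float)
    if np.any(eps_arr <= 0.0) or np.any(eps_arr >= 1.0):
        raise ValueError("epsilon grid must stay inside the open interval (0, 1)")
    records = sweep(SweepSpec(base=base, axes={"omega": omega_grid, "epsilon": epsilon_grid}))
    counts = {r.value: 0 for r in Regime}
    observed = records.loc[records["error"] == "", "regime"].value_counts()
    counts.update({k: int(v) for k, v in observed.items()})
    return records, counts


def write_records(records: pd.DataFrame, path, fmt: str = "csv") -> Path:
    """Write sweep records as CSV or JSON (floats at 12 significant digits)."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty record set")
    path = Path(path)
    try:
        if fmt == "csv":
            records.to_csv(path, index=False, float_format="%.12g")
        elif fmt == "json":
            def _coerce(v):
                if isinstance(v, float):
                    return float(f"{v:.12g}") if math.isfinite(v) else None
                return v

            payload = [
                {k: _coerce(v) for k, v in row.items()}
                for row in records.to_dict(orient="records")
            ]
            path.write_text(json.dumps(payload, indent=1) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    except OSError as exc:
        raise OSError(f"could not write records to {path}: {exc}") from exc
    return path
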