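"""Report generation: delimited tables, JSON twins and run manifests.

All numeric rounding happens here, at the presentation layer; the only
documented rounding is ICERs to one decimal.  Every output file carries
a reference to the manifest that produced it (a ``#`` comment line in
CSV files, a ``manifest`` key in JSON files); the manifest records the
settings snapshot, input checksums, seeds and software version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cea import IncrementalResult, round_icer
from .engine import CohortTrace, StrategyOutcome, discount_factor
from .parameters import STATES, STRUCTURAL_DEFAULTS, ModelSettings
from .sensitivity import CostGridResult, OneWayResult

__all__ = [
    "MANIFEST_NAME",
    "build_manifest",
    "write_manifest",
    "trace_frame",
    "outcomes_frame",
    "incremental_frame",
    "one_way_frame",
    "cost_grid_frame",
    "write_csv",
    "write_json_twin",
]

MANIFEST_NAME = "manifest.json"

_STRUCTURAL_NOTE = (
    "structural per-cycle probabilities "
    + ", ".join(f"{k}={v}" for k, v in STRUCTURAL_DEFAULTS.items())
    + " are package defaults, not published estimates, unless overridden"
)


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_manifest(
    settings: ModelSettings,
    inputs: Sequence[Path] = (),
    seeds: Sequence[int] = (),
) -> dict:
    return {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "software": {"name": "esocea", "version": __version__},
        "settings": dataclasses.asdict(settings),
        "structural_defaults": dict(STRUCTURAL_DEFAULTS),
        "inputs": {str(Path(p)): _checksum(Path(p)) for p in inputs},
        "seeds": list(seeds),
    }


def write_manifest(manifest: dict, out_dir: Path) -> Path:
    path = Path(out_dir) / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def trace_frame(trace: CohortTrace, strategy: str, settings: ModelSettings) -> pd.DataFrame:
    """Long-format cohort trace: cycle, state, occupancy, discount factor."""
    cycles = np.arange(trace.occupancy.shape[0])
    df = discount_factor(cycles, settings)
    rows = [
        {
            "strategy": strategy,
            "cycle": int(t),
            "state": state,
            "occupancy": float(trace.occupancy[t, k]),
            "discount_factor": float(df[t]),
        }
        for t in cycles
        for k, state in enumerate(STATES)
    ]
    return pd.DataFrame(rows, columns=["strategy", "cycle", "state", "occupancy", "discount_factor"])


def outcomes_frame(outcomes: Sequence[StrategyOutcome]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(o) for o in outcomes])


def incremental_frame(
    results: Sequence[IncrementalResult], outcomes: Sequence[StrategyOutcome]
) -> pd.DataFrame:
    """CEA report: totals, ICERs (one decimal), status and classification."""
    totals = {o.strategy: o for o in outcomes}
    rows = []
    for r in results:
        o = totals[r.strategy]
        rows.append(
            {
                "strategy": r.strategy,
                "total_cost": o.total_cost_disc,
                "qaly": o.qaly_disc,
                "lyg": o.ly_disc,
                "comparator": r.comparator or "",
                "icer_per_qaly": round_icer(r.icer_per_qaly),
                "icer_per_ly": round_icer(r.icer_per_ly),
                "status": r.status,
                "classification": r.classification,
            }
        )
    return pd.DataFrame(rows)


def one_way_frame(results: Sequence[OneWayResult]) -> pd.DataFrame:
    """Tornado-style export: one row per varied parameter."""
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        d["icer_low"] = round_icer(r.icer_low)
        d["icer_high"] = round_icer(r.icer_high)
        rows.append(d)
    columns = [
        "strategy", "parameter", "value_low", "value_high",
        "preferred_low", "preferred_high", "icer_low", "icer_high", "switch_value",
    ]
    return pd.DataFrame(rows, columns=columns)


def cost_grid_frame(grid: CostGridResult) -> pd.DataFrame:
    """Long-format grid: cost_a, cost_b, preferred label."""
    rows = [
        {
            "cost_a": float(ca),
            "cost_b": float(cb),
            "preferred": grid.labels[i, j],
        }
        for i, ca in enumerate(grid.axis_a)
        for j, cb in enumerate(grid.axis_b)
    ]
    df = pd.DataFrame(rows, columns=["cost_a", "cost_b", "preferred"])
    df.attrs["strategy_a"] = grid.strategy_a
    df.attrs["strategy_b"] = grid.strategy_b
    return df


def write_csv(df: pd.DataFrame, path: Path, manifest_name: str = MANIFEST_NAME) -> Path:
    """UTF-8 CSV with a comment header referencing the manifest.

    Read back with ``pd.read_csv(path, comment='#')``.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# manifest: {manifest_name}\n")
        fh.write(f"# note: {_STRUCTURAL_NOTE}\n")
        df.to_csv(fh, index=False)
    return path


def write_json_twin(df: pd.DataFrame, path: Path, manifest_name: str = MANIFEST_NAME) -> Path:
    path = Path(path)
    payload = {
        "manifest": manifest_name,
        "note": _STRUCTURAL_NOTE,
        "records": json.loads(df.to_json(orient="records")),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
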