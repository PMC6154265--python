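"""Result serialization: CSV time series and snapshots, JSON run manifest.

Every run writes a manifest sufficient to reproduce it exactly: the full
config echo, the package version, the simulated interval, the closure flag
and an index of output files.  All numeric tables are CSV with units in the
headers and full float precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, _as_dict
from .protocols import SimulationResult, SweepResult

__all__ = ["RunManifest", "write_results", "write_sweep", "read_series",
           "write_pr_curve"]

_SERIES_COLUMNS = {
    "t": "t_days",
    "mu": "mu",
    "k_total": "k_total",
    "xi1": "xi1_mm",
    "xi_int": "xi_int_mm",
    "r1": "r1_loaded_mm",
    "wall_thickness": "wall_thickness_mm",
    "mean_phi_c": "mean_phi_c",
    "mean_phi_p": "mean_phi_p",
    "mean_phi_e": "mean_phi_e",
    "min_tau": "min_tau_kPa",
    "max_tau": "max_tau_kPa",
}


@dataclass
class RunManifest:
    """Reproducibility record for one simulation run."""

    config: dict
    version: str
    t_start_days: float
    t_end_days: float
    closed: bool
    aborted: str | None
    files: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_results(result: SimulationResult, out_dir) -> RunManifest:
    """Write series.csv, one snapshot CSV per requested day, and manifest.json.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    series = pd.DataFrame({col: getattr(result, name)
                           for name, col in _SERIES_COLUMNS.items()})
    series_path = out / "series.csv"
    series.to_csv(series_path, index=False, float_format="%.17g")
    files["series"] = series_path.name
    for day, snap in sorted(result.snapshots.items()):
        df = pd.DataFrame({
            "xi_mm": snap["xi"], "r_mm": snap["r"],
            "phi_c": snap["phi_c"], "phi_p": snap["phi_p"], "phi_e": snap["phi_e"],
            "k": snap["k"], "Trr_kPa": snap["Trr"], "Tth_kPa": snap["Tth"],
            "Tzz_kPa": snap["Tzz"], "tau_kPa": snap["tau"],
        })
        name = f"snapshot_day{day:g}.csv"
        df.to_csv(out / name, index=False, float_format="%.17g")
        files[f"snapshot_{day:g}"] = name
    manifest = RunManifest(
        config=_as_dict(result.config) if result.config else {},
        version=__version__,
        t_start_days=float(result.t[0]), t_end_days=float(result.t[-1]),
        closed=result.closed, aborted=result.aborted, files=files,
    )
    manifest.save(out / "manifest.json")
    return manifest


def read_series(out_dir) -> pd.DataFrame:
    """Read back a written series.csv (full-precision round trip)."""
    return pd.read_csv(Path(out_dir) / "series.csv", float_precision="round_trip")


def write_sweep(sweep: SweepResult, out_dir) -> None:
    """Write sweep surfaces as long-format CSV plus an axes JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a1, a2 = np.meshgrid(sweep.axis1_grid, sweep.axis2_grid, indexing="ij")
    df = pd.DataFrame({
        sweep.axis1_name: a1.ravel(),
        sweep.axis2_name: a2.ravel(),
        "remodelled_radius_mm": sweep.radius.ravel(),
        "resolution_days": sweep.resolution_days.ravel(),
        "closed": sweep.closed_mask.ravel(),
        "censored": sweep.censored_mask.ravel(),
    })
    df.to_csv(out / "sweep.csv", index=False, float_format="%.17g")
    (out / "sweep_axes.json").write_text(json.dumps({
        "axis1": {"name": sweep.axis1_name, "grid": sweep.axis1_grid.tolist()},
        "axis2": {"name": sweep.axis2_name, "grid": sweep.axis2_grid.tolist()},
    }, indent=2))


def write_pr_curve(rows, path) -> None:
    """Write a pressure--radius table (transmural pressure, radius, flag)."""
    df = pd.DataFrame(rows, columns=["transmural_pressure_kPa", "inner_radius_mm",
                                     "converged_flag"])
    df.to_csv(path, index=False, float_format="%.17g")
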