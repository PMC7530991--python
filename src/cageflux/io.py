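"""Plain-text I/O for traces, trajectory frames, and run configs.

Traces are two-column CSV (``time_s,signal``) with an optional YAML
metadata sidecar; trajectory fixtures are long-format CSV with one row
per atom per frame (``frame,mol_id,atom,x_A,y_A,z_A``); configs are flat
YAML with unit-suffixed keys.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .hydration import ATOM_COLUMNS, HydrationTrajectory
from .synthetic import StoppedFlowTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_frames",
    "read_frames",
    "load_config",
    "save_config",
    "load_md_trajectory",
]


def write_trace(
    trace: StoppedFlowTrace,
    path: str | Path,
    metadata: dict[str, Any] | None = None,
) -> None:
    """Write a trace as ``time_s,signal`` CSV, plus a YAML sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.times_s, "signal": trace.signal}).to_csv(
        path, index=False
    )
    if metadata is not None:
        save_config(metadata, path.with_suffix(path.suffix + ".meta.yaml"))


def read_trace(path: str | Path, channel_label: str = "") -> StoppedFlowTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "signal"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    return StoppedFlowTrace(
        times_s=df["time_s"].to_numpy(dtype=float),
        signal=df["signal"].to_numpy(dtype=float),
        channel_label=channel_label,
    )


def write_frames(traj: HydrationTrajectory, path: str | Path) -> None:
    traj.atoms[ATOM_COLUMNS].to_csv(path, index=False)


def read_frames(
    path: str | Path,
    frame_interval_ps: float = 10.0,
    channel_axis=(0.0, 0.0, 1.0),
    segment: tuple[float, float] | None = None,
) -> HydrationTrajectory:
    df = pd.read_csv(path)
    return HydrationTrajectory(
        atoms=df,
        frame_interval_ps=frame_interval_ps,
        channel_axis=np.asarray(channel_axis, dtype=float),
        segment=segment,
    )


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def load_md_trajectory(
    topology: str | Path,
    trajectory: str | Path | None = None,
    water_selection: str = "name OW O and resname SOL HOH TIP3",
    frame_interval_ps: float = 10.0,
) -> HydrationTrajectory:
    """Adapter for standard MD formats (GRO/PDB topology + XTC/TRR).

    Requires MDAnalysis (optional extra ``cageflux[md]``).  Only water
    oxygens are imported; hydrogens of the selected residues are carried
    along when present.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "MDAnalysis is required to read standard MD formats; "
            "install cageflux[md]"
        ) from exc

    uni = (
        mda.Universe(str(topology), str(trajectory))
        if trajectory is not None
        else mda.Universe(str(topology))
    )
    waters = uni.select_atoms(water_selection).residues
    rows = []
    for f, _ts in enumerate(uni.trajectory):
        for res in waters:
            names = {a.name: a.position for a in res.atoms}
            oxy = next(
                (names[n] for n in ("OW", "O") if n in names), None
            )
            if oxy is None:
                continue
            rows.append((f, int(res.resid), "O", *map(float, oxy)))
            h_idx = 1
            for name, pos in names.items():
                if name.startswith("H") and h_idx <= 2:
                    rows.append((f, int(res.resid), f"H{h_idx}", *map(float, pos)))
                    h_idx += 1
    return HydrationTrajectory(
        atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS),
        frame_interval_ps=frame_interval_ps,
    )
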