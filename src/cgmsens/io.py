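"""File I/O: marker trials, result tables, manifests and plots.

Trials are exchanged as a wide CSV of marker trajectories (one row per
frame, ``<LABEL>_{x,y,z}`` columns, mm) plus a JSON sidecar carrying
sampling rate, trial kind, units and gait events. Label aliasing and
unit conversion happen on read, so exports from other ecosystems can
be mapped onto the CGM label set. Angle curves, sensitivity tables and
association tables are tidy CSVs; a JSON run manifest records the
configuration and seeds of a pipeline run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping

import matplotlib

matplotlib.use("Agg")  # headless environments
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datamodel import AngleCurveSet, GaitEvent, MarkerTrial, SensitivityTable
from .sensitivity import ACCEPTABLE_LIMIT, OPTIMAL_LIMIT

__all__ = [
    "write_trial",
    "read_trial",
    "write_curves",
    "read_curves",
    "write_sensitivity",
    "write_association",
    "write_manifest",
    "read_manifest",
    "polar_rmsd_plot",
    "curve_overlay_plot",
]

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def write_trial(trial: MarkerTrial, directory: str | Path, name: str) -> Path:
    """Write ``<name>_markers.csv`` + ``<name>_meta.json``; returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns: Dict[str, np.ndarray] = {"frame": np.arange(trial.n_frames)}
    for label in sorted(trial.markers):
        for i, axis in enumerate("xyz"):
            columns[f"{label}_{axis}"] = trial.markers[label][:, i]
    csv_path = directory / f"{name}_markers.csv"
    pd.DataFrame(columns).to_csv(csv_path, index=False, float_format="%.9f")
    meta = {
        "sampling_rate": trial.sampling_rate,
        "kind": trial.kind,
        "units": "mm",
        "events": [
            {"frame": e.frame, "side": e.side, "kind": e.kind} for e in trial.events
        ],
    }
    (directory / f"{name}_meta.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def read_trial(
    directory: str | Path, name: str, aliases: Mapping[str, str] | None = None
) -> MarkerTrial:
    """Read a trial written by :func:`write_trial`.

    ``aliases`` maps foreign labels (e.g. ``"KNEE_L"``) to CGM names;
    units are converted to mm according to the sidecar ``units`` field.
    """
    directory = Path(directory)
    frame = pd.read_csv(directory / f"{name}_markers.csv")
    meta = json.loads((directory / f"{name}_meta.json").read_text())
    scale = _UNIT_TO_MM.get(meta.get("units", "mm"))
    if scale is None:
        raise ValueError(f"unsupported units {meta.get('units')!r}")

    labels = sorted({c[:-2] for c in frame.columns if c.endswith(("_x", "_y", "_z"))})
    aliases = dict(aliases or {})
    markers = {}
    for label in labels:
        target = aliases.get(label, label)
        markers[target] = scale * frame[[f"{label}_{a}" for a in "xyz"]].to_numpy(dtype=float)
    events = [
        GaitEvent(frame=int(e["frame"]), side=e["side"], kind=e.get("kind", "foot-strike"))
        for e in meta.get("events", [])
    ]
    return MarkerTrial(
        markers=markers,
        sampling_rate=float(meta.get("sampling_rate", 100.0)),
        kind=meta.get("kind", "gait"),
        events=events,
    )


def write_curves(curves: AngleCurveSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for (joint, plane, side), curve in curves.curves.items():
        for pct, value in enumerate(curve):
            rows.append(
                {"joint": joint, "plane": plane, "side": side, "cycle_pct": pct, "angle_deg": value}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")
    return path


def read_curves(path: str | Path) -> AngleCurveSet:
    frame = pd.read_csv(path)
    curves = {}
    for (joint, plane, side), grp in frame.groupby(["joint", "plane", "side"]):
        curves[(joint, plane, side)] = (
            grp.sort_values("cycle_pct")["angle_deg"].to_numpy(dtype=float)
        )
    return AngleCurveSet(curves=curves)


def write_sensitivity(table: SensitivityTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False, float_format="%.9f")
    return path


def write_association(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.9f")
    return path


def write_manifest(config: Mapping, path: str | Path) -> Path:
    """JSON run manifest (config, seeds, package version)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"cgmsens_version": __version__, "config": dict(config)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())["config"]


def polar_rmsd_plot(table: SensitivityTable, path: str | Path, kind: str = "gait-cycle"):
    """Polar summary of RMSD by direction/magnitude per joint angle.

    Rings mark the 2 deg (optimal) and 5 deg (acceptable) bands.
    """
    frame = table.to_frame()
    frame = frame[frame["kind"] == kind]
    keys = sorted(frame.groupby(["joint", "plane"]).groups)
    fig, axes = plt.subplots(
        3, 3, subplot_kw={"projection": "polar"}, figsize=(11, 11)
    )
    for ax, (joint, plane) in zip(axes.ravel(), keys):
        sub = frame[(frame["joint"] == joint) & (frame["plane"] == plane)]
        for mag, grp in sub.groupby("magnitude_mm"):
            grp = grp.sort_values("theta_deg")
            theta = np.radians(np.r_[grp["theta_deg"], grp["theta_deg"].iloc[0]])
            r = np.r_[grp["rmsd_deg"], grp["rmsd_deg"].iloc[0]]
            ax.plot(theta, r, label=f"{mag:g} mm")
        top = max(sub["rmsd_deg"].max() * 1.1, ACCEPTABLE_LIMIT * 1.2)
        theta_fill = np.linspace(0, 2 * np.pi, 90)
        ax.fill_between(theta_fill, 0, OPTIMAL_LIMIT, color="green", alpha=0.15)
        ax.fill_between(theta_fill, OPTIMAL_LIMIT, ACCEPTABLE_LIMIT, color="orange", alpha=0.15)
        ax.set_ylim(0, top)
        ax.set_title(f"{joint} {plane}", fontsize=9)
    handles, labels = axes.ravel()[0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower center", ncol=5)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def curve_overlay_plot(
    reference: AngleCurveSet,
    perturbed: Mapping[float, AngleCurveSet],
    side: str,
    path: str | Path,
):
    """Per-angle overlays of perturbed curves by magnitude (one side)."""
    fig, axes = plt.subplots(3, 3, figsize=(11, 8), sharex=True)
    joints = ("hip", "knee", "ankle")
    planes = ("flexion", "adduction", "rotation")
    pct = np.arange(101)
    for i, joint in enumerate(joints):
        for j, plane in enumerate(planes):
            ax = axes[i, j]
            ax.plot(pct, reference[(joint, plane, side)], "k-", lw=2, label="reference")
            for mag, curves in sorted(perturbed.items()):
                ax.plot(pct, curves[(joint, plane, side)], lw=1, label=f"{mag:g} mm")
            ax.set_title(f"{joint} {plane}", fontsize=9)
    axes[-1, 1].set_xlabel("gait cycle (%)")
    axes[1, 0].set_ylabel("angle (deg)")
    handles, labels = axes[0, 0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower center", ncol=6)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
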