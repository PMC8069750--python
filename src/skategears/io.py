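"""Readers and writers for the pipeline's plain-text formats.

Trajectory CSV: ``time_s,east_m,north_m,up_m,fix`` with fix in
{fixed,float}; ground-truth events CSV: ``event_time_s,label``; annotation
and cycle tables: ``t_start_s,t_end_s,label`` (cycle tables carry the
additional metric columns). Course plans and configs are YAML; models and
confusion matrices serialize to JSON. Times are seconds from trial start
and positions are in a local east/north/up frame — conversion from geodetic
coordinates happens upstream and is out of scope here.
"""

from __future__ import annotations

import json
import logging
import sys
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .containers import GroundTruth, TrajectorySeries
from .evaluate import ConfusionMatrix
from .synthgen import CoursePlan

log = logging.getLogger("skategears")


def setup_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("skategears")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


# -- trajectories -----------------------------------------------------------

def write_trajectory(traj: TrajectorySeries, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> TrajectorySeries:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty input file: {path}") from None
    if len(df) == 0:
        raise ValueError(f"empty input file: {path}")
    try:
        return TrajectorySeries.from_frame(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


# -- ground truth / annotations ---------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    """Events as ``event_time_s,label`` (label of the interval the event
    starts; the final event closes the last interval with label ``end``)."""
    ev = truth.cycle_events
    labels = list(truth.labels) + (["end"] if ev.size else [])
    pd.DataFrame({"event_time_s": ev, "label": labels}).to_csv(
        path, index=False, float_format="%.17g")


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path, float_precision="round_trip")
    ev = df["event_time_s"].to_numpy(dtype=float)
    labels = [str(x) for x in df["label"][:-1]] if len(df) else []
    return GroundTruth(cycle_events=ev, labels=labels)


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_annotations(path, valid_labels=None) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"t_start_s", "t_end_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation table needs {sorted(required)}")
    if valid_labels is not None:
        bad = set(map(str, df["label"])) - set(valid_labels)
        if bad:
            raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return df


# -- cycles / features ------------------------------------------------------

def write_cycles(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_cycles(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    # integral values lose their decimal point on write; metric columns are
    # floats by contract
    for col in df.columns:
        if col != "label" and pd.api.types.is_integer_dtype(df[col]):
            df[col] = df[col].astype(float)
    return df


def write_features(features: np.ndarray, labels, path) -> None:
    cols = [f"c{i}" for i in range(features.shape[1])]
    df = pd.DataFrame(features, columns=cols)
    df["label"] = list(labels)
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError(f"{path}: feature table needs a label column")
    labels = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), labels


# -- plans / reports --------------------------------------------------------

def read_plan(path) -> CoursePlan:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "segments" not in data:
        raise ValueError(f"{path}: course plan needs a 'segments' list")
    return CoursePlan.from_dict(data)


def write_confusion(cm: ConfusionMatrix, csv_path=None,
                    json_path=None) -> None:
    if csv_path is not None:
        cm.counts.to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(cm.to_json_dict(), fh, indent=1)


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


__all__ = [
    "setup_logging", "write_trajectory", "read_trajectory",
    "write_ground_truth", "read_ground_truth", "write_annotations",
    "read_annotations", "write_cycles", "read_cycles", "write_features",
    "read_features", "read_plan", "write_confusion", "write_report", "log",
]
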