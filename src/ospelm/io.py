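"""Dataset CSV and model-file readers/writers.

Dataset dialect: UTF-8 CSV with header
``mc_percent,distance_m,humidity_percent,dbh_m,rssi_control_dbm,rssi_sensing_dbm``,
'.' decimal separator, one sample per row. MC is stored in percent (the
convention of the published data tables) and converted to fraction
internally; a blank control-RSSI cell marks it missing.

Models are stored as a single portable JSON file (version-tagged, model-kind
tagged) holding all weights, the RLS matrix F, the normalization states and
the training settings. Python's JSON float representation round-trips
bit-exactly, so save→load→predict is bit-identical to the in-memory model.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .adapt import AdaptationConfig
from .baselines import ELMState
from .exceptions import ModelFormatError, ParseError
from .network import OSPELMState
from .pipeline import TrainedModel
from .preprocessing import FeatureGrouping, NormalizationState
from .rf import Sample, TreeScenario

__all__ = ["DATASET_COLUMNS", "read_dataset", "write_dataset", "save_model", "load_model"]

DATASET_COLUMNS = (
    "mc_percent",
    "distance_m",
    "humidity_percent",
    "dbh_m",
    "rssi_control_dbm",
    "rssi_sensing_dbm",
)

MODEL_FORMAT_VERSION = 1


def write_dataset(samples: Sequence[Sample], path: str | Path) -> None:
    """Write samples to CSV in the declared dialect (lossless float repr)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DATASET_COLUMNS)
        for s in samples:
            writer.writerow(
                [
                    repr(s.scenario.mc * 100.0),
                    repr(s.scenario.distance),
                    repr(s.scenario.humidity),
                    repr(s.scenario.dbh),
                    "" if s.rssi_control is None else repr(s.rssi_control),
                    repr(s.rssi_sensing),
                ]
            )


def read_dataset(path: str | Path) -> list[Sample]:
    """Read a dataset CSV, validating the header and every cell.

    Malformed rows raise :class:`ParseError` naming the line and column.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != DATASET_COLUMNS:
            unknown = set(header) - set(DATASET_COLUMNS)
            missing = set(DATASET_COLUMNS) - set(header)
            raise ParseError(
                f"{path}: bad header; unknown columns {sorted(unknown)}, missing {sorted(missing)}"
            )
        samples: list[Sample] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(DATASET_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(DATASET_COLUMNS)} cells, got {len(row)}")
            values: dict[str, float | None] = {}
            for col, cell in zip(DATASET_COLUMNS, row):
                cell = cell.strip()
                if cell == "" and col == "rssi_control_dbm":
                    values[col] = None
                    continue
                try:
                    values[col] = float(cell)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric value {cell!r} in column {col}") from None
            scenario = TreeScenario(
                mc=values["mc_percent"] / 100.0,
                distance=values["distance_m"],
                humidity=values["humidity_percent"],
                dbh=values["dbh_m"],
            )
            samples.append(
                Sample(
                    scenario=scenario,
                    rssi_control=values["rssi_control_dbm"],
                    rssi_sensing=values["rssi_sensing_dbm"],
                    timestamp_index=len(samples),
                )
            )
    return samples


def _arr(a: np.ndarray) -> list:
    return np.asarray(a, float).tolist()


def _norm_to_dict(norm: NormalizationState) -> dict:
    return {"columns": list(norm.columns), "x_min": _arr(norm.x_min), "x_max": _arr(norm.x_max)}


def _norm_from_dict(d: dict) -> NormalizationState:
    return NormalizationState(
        columns=tuple(d["columns"]), x_min=np.array(d["x_min"]), x_max=np.array(d["x_max"])
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (any kind) to a portable JSON file."""
    if model.kind == "ospelm":
        st: OSPELMState = model.state
        state_doc = {
            "rho": _arr(st.rho), "phi": _arr(st.phi),
            "b1": _arr(st.b1), "b2": _arr(st.b2),
            "beta1": _arr(st.beta1), "beta2": _arr(st.beta2), "omega": _arr(st.omega),
            "h_id": st.h_id, "g_id": st.g_id, "f_id": st.f_id,
            "F": None if st.F is None else _arr(st.F),
            "grouping": {"n": st.grouping.n, "m": st.grouping.m},
            "leaky_alpha": st.leaky_alpha,
        }
    else:
        st: ELMState = model.state
        state_doc = {
            "w": _arr(st.w), "b": _arr(st.b), "beta": _arr(st.beta),
            "activation_id": st.activation_id,
            "F": None if st.F is None else _arr(st.F),
            "leaky_alpha": st.leaky_alpha,
        }
    doc = {
        "format": "ospelm-model",
        "version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "state": state_doc,
        "feature_norm": _norm_to_dict(model.feature_norm),
        "target_norm": _norm_to_dict(model.target_norm),
        "chunk_size": model.chunk_size,
        "mu": model.mu,
        "adaptation": None if model.adaptation is None else dataclasses.asdict(model.adaptation),
        "adaptation_log": model.adaptation_log,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model(path: str | Path) -> TrainedModel:
    """Load a model file written by :func:`save_model`.

    Corruption or a version mismatch raises :class:`ModelFormatError`.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != "ospelm-model":
        raise ModelFormatError(f"{path}: not an ospelm model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version {doc.get('version')!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    try:
        sd = doc["state"]
        if doc["kind"] == "ospelm":
            state = OSPELMState(
                rho=np.array(sd["rho"], float),
                phi=np.array(sd["phi"], float),
                b1=np.array(sd["b1"], float),
                b2=np.array(sd["b2"], float),
                beta1=np.array(sd["beta1"], float),
                beta2=np.array(sd["beta2"], float),
                omega=np.array(sd["omega"], float),
                h_id=sd["h_id"], g_id=sd["g_id"], f_id=sd["f_id"],
                F=None if sd["F"] is None else np.array(sd["F"], float),
                grouping=FeatureGrouping(**sd["grouping"]),
                leaky_alpha=sd["leaky_alpha"],
            )
        elif doc["kind"] in ("oselm", "elm"):
            state = ELMState(
                w=np.array(sd["w"], float),
                b=np.array(sd["b"], float),
                beta=np.array(sd["beta"], float),
                activation_id=sd["activation_id"],
                F=None if sd["F"] is None else np.array(sd["F"], float),
                leaky_alpha=sd["leaky_alpha"],
            )
        else:
            raise ModelFormatError(f"{path}: unknown model kind {doc['kind']!r}")
        return TrainedModel(
            kind=doc["kind"],
            state=state,
            feature_norm=_norm_from_dict(doc["feature_norm"]),
            target_norm=_norm_from_dict(doc["target_norm"]),
            chunk_size=doc["chunk_size"],
            mu=doc["mu"],
            adaptation=None if doc["adaptation"] is None else AdaptationConfig(**doc["adaptation"]),
            adaptation_log=doc.get("adaptation_log", []),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"{path}: corrupted model file ({exc})") from exc
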