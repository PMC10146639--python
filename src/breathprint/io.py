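"""File formats: breath-print CSV, long-format trace CSV, model/report JSON,
YAML pipeline configuration.

Breath-print CSV schema (comma-delimited, decimal point):
``sample_id, subject_id, group, [replicate,] s01..s32`` with group in
{asthma, control, unknown}.  Trace CSV is long format:
``sample_id, [subject_id, group,] sensor, t, resistance`` with 1-based
sensor indices.  JSON artifacts carry a ``format_version`` plus, for
reports, the configuration hash and seed for provenance; floats are written
with Python's shortest-round-trip encoding, so read-back is bit-faithful.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .containers import (
    GROUPS,
    N_SENSORS,
    SENSOR_COLUMNS,
    BreathPrint,
    BreathPrintSet,
    RawSensorTrace,
    mask_from_disabled,
)
from .discriminate import DiscriminationModel
from .preprocess import PreprocessSettings
from .simulate import SimulationConfig

__all__ = [
    "PipelineConfig",
    "read_breathprints",
    "write_breathprints",
    "read_traces",
    "write_traces",
    "read_model",
    "write_model",
    "read_report",
    "write_report",
    "validate_report",
    "config_hash",
]

MODEL_FORMAT_VERSION = 1
REPORT_FORMAT_VERSION = 1


# -- breath-print CSV ------------------------------------------------------


def read_breathprints(
    path: str | Path, disabled_sensors: tuple[int, ...] | list[int] | None = None
) -> BreathPrintSet:
    """Parse a breath-print CSV with strict validation.

    Errors name the offending column or 1-based data row.  An optional
    ``disabled_sensors`` list marks those sensors inactive in every print.
    """
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "subject_id": str, "group": str},
        float_precision="round_trip",
    )
    required = ["sample_id", "subject_id", "group", *SENSOR_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    extra = [
        c
        for c in df.columns
        if c not in required and c != "replicate"
    ]
    if extra:
        raise ValueError(f"{path}: unexpected column(s) {extra}")
    mask = mask_from_disabled(disabled_sensors)
    prints: list[BreathPrint] = []
    seen: dict[str, int] = {}
    for idx, row in df.iterrows():
        rowno = int(idx) + 1
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(
                f"{path}: duplicate sample_id {sid!r} at data row {rowno} "
                f"(first at row {seen[sid]})"
            )
        seen[sid] = rowno
        if row["group"] not in GROUPS:
            raise ValueError(
                f"{path}: invalid group {row['group']!r} at data row {rowno}"
            )
        values = np.empty(N_SENSORS)
        for i, col in enumerate(SENSOR_COLUMNS):
            v = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(v):
                raise ValueError(
                    f"{path}: non-numeric value {row[col]!r} in column {col} "
                    f"at data row {rowno}"
                )
            values[i] = float(v)
        replicate = int(row["replicate"]) if "replicate" in df.columns else 1
        prints.append(
            BreathPrint(
                sample_id=str(sid),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                response=values,
                mask=mask.copy(),
                replicate=replicate,
            )
        )
    return BreathPrintSet(prints)


def write_breathprints(prints: BreathPrintSet, path: str | Path) -> None:
    df = prints.to_frame()
    if (df["replicate"] == 1).all():
        df = df.drop(columns=["replicate"])
    df.to_csv(path, index=False)


# -- trace CSV (long format) ----------------------------------------------


def write_traces(traces: list[RawSensorTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        T = tr.n_timepoints
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(tr.sample_id, N_SENSORS * T),
                    "subject_id": np.repeat(tr.subject_id, N_SENSORS * T),
                    "group": np.repeat(tr.group, N_SENSORS * T),
                    "sensor": np.repeat(np.arange(1, N_SENSORS + 1), T),
                    "t": np.tile(tr.time_axis, N_SENSORS),
                    "resistance": tr.sensor_values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(
    path: str | Path,
    baseline_window: tuple[int, int],
    exposure_window: tuple[int, int],
) -> list[RawSensorTrace]:
    """Rebuild traces from long CSV; windows are supplied by configuration
    (the CSV stores only the raw series)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"sample_id", "sensor", "t", "resistance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    traces = []
    for sid, grp in df.groupby("sample_id", sort=False):
        pivot = grp.pivot_table(index="sensor", columns="t", values="resistance", sort=True)
        if pivot.shape[0] != N_SENSORS:
            raise ValueError(
                f"{path}: sample {sid!r} has {pivot.shape[0]} sensors; expected {N_SENSORS}"
            )
        subject = str(grp["subject_id"].iloc[0]) if "subject_id" in grp else str(sid)
        group = str(grp["group"].iloc[0]) if "group" in grp else "unknown"
        traces.append(
            RawSensorTrace(
                sample_id=str(sid),
                sensor_values=pivot.to_numpy(),
                time_axis=pivot.columns.to_numpy(dtype=float),
                baseline_window=baseline_window,
                exposure_window=exposure_window,
                subject_id=subject,
                group=group,
            )
        )
    return traces


# -- model JSON ------------------------------------------------------------


def write_model(model: DiscriminationModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "sensor_mask": model.sensor_mask.astype(bool).tolist(),
        "class_labels": list(model.class_labels),
        "scaling_mean": model.scaling_mean.tolist(),
        "scaling_sd": model.scaling_sd.tolist(),
        "pc_loadings": model.pc_loadings.tolist(),
        "n_pc": int(model.n_pc),
        "canonical_axis": model.canonical_axis.tolist(),
        "centroids": model.centroids.tolist(),
        "pooled_within_cov": model.pooled_within_cov.tolist(),
        "m_distance": float(model.m_distance),
        "regularization": float(model.regularization),
        "autoscale": bool(model.autoscale),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_model(path: str | Path) -> DiscriminationModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return DiscriminationModel(
        sensor_mask=np.asarray(payload["sensor_mask"], dtype=bool),
        class_labels=tuple(payload["class_labels"]),
        scaling_mean=np.asarray(payload["scaling_mean"], dtype=float),
        scaling_sd=np.asarray(payload["scaling_sd"], dtype=float),
        pc_loadings=np.asarray(payload["pc_loadings"], dtype=float),
        n_pc=int(payload["n_pc"]),
        canonical_axis=np.asarray(payload["canonical_axis"], dtype=float),
        centroids=np.asarray(payload["centroids"], dtype=float),
        pooled_within_cov=np.asarray(payload["pooled_within_cov"], dtype=float),
        m_distance=float(payload["m_distance"]),
        regularization=float(payload["regularization"]),
        autoscale=bool(payload["autoscale"]),
    )


# -- report JSON -----------------------------------------------------------

#: minimal structural schema for report JSON (checked by validate_report)
REPORT_SCHEMA = {
    "format_version": int,
    "kind": str,
    "payload": dict,
}


def write_report(
    payload: dict,
    path: str | Path,
    kind: str = "report",
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a deterministic JSON report (fixed key order, round-trip floats)."""
    doc: dict[str, Any] = {
        "format_version": REPORT_FORMAT_VERSION,
        "kind": kind,
        "payload": _jsonable(payload),
    }
    if config is not None:
        doc["config_hash"] = config_hash(config)
    if seed is not None:
        doc["seed"] = int(seed)
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_report(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    validate_report(doc)
    return doc


def validate_report(doc: dict) -> None:
    for key, typ in REPORT_SCHEMA.items():
        if key not in doc:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(doc[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    if doc["format_version"] != REPORT_FORMAT_VERSION:
        raise ValueError(f"unsupported report format version {doc['format_version']!r}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def config_hash(config: dict) -> str:
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# -- pipeline configuration ------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration: preprocessing, model, validation, simulation.

    Unknown keys anywhere in the YAML are rejected; each section is
    validated against the constraints of its owning module.
    """

    seed: int = 0
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    n_pc: int = 4
    autoscale: bool = True
    z: float = 1.96
    positive_class: str = "asthma"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        self.preprocess.validate()
        self.simulation.validate()
        if self.n_pc < 1:
            raise ValueError("n_pc must be >= 1")
        if self.z <= 0:
            raise ValueError("z must be > 0")
        if self.positive_class not in ("asthma", "control"):
            raise ValueError("positive_class must be 'asthma' or 'control'")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "preprocess": dataclasses.asdict(self.preprocess),
            "model": {"n_pc": self.n_pc, "autoscale": self.autoscale},
            "validation": {"z": self.z, "positive_class": self.positive_class},
            "simulation": dataclasses.asdict(self.simulation),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"seed", "preprocess", "model", "validation", "simulation"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")

        def section(name: str, fields: set[str]) -> dict:
            sec = raw.get(name, {}) or {}
            bad = set(sec) - fields
            if bad:
                raise ValueError(f"unknown key(s) in '{name}': {sorted(bad)}")
            return sec

        pp = section("preprocess", set(PreprocessSettings.__dataclass_fields__))
        if "disabled_sensors" in pp:
            pp["disabled_sensors"] = tuple(pp["disabled_sensors"])
        model = section("model", {"n_pc", "autoscale"})
        val = section("validation", {"z", "positive_class"})
        sim = section("simulation", set(SimulationConfig.__dataclass_fields__))
        if "humidity_sensors" in sim:
            sim["humidity_sensors"] = tuple(sim["humidity_sensors"])
        seed = int(raw.get("seed", 0))
        sim.setdefault("seed", seed)
        cfg = cls(
            seed=seed,
            preprocess=PreprocessSettings(**pp),
            n_pc=int(model.get("n_pc", 4)),
            autoscale=bool(model.get("autoscale", True)),
            z=float(val.get("z", 1.96)),
            positive_class=str(val.get("positive_class", "asthma")),
            simulation=SimulationConfig(**sim),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(raw)
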