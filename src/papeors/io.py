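"""Reading and writing of signals, impulse responses, models and configs.

Two signal formats are supported:

``delimited``
    Inspectable two-column text (``time_s  amplitude``) with a
    ``#``-prefixed metadata header.  Values are printed with ``%.17g`` so
    float64 samples round-trip exactly.

``container``
    A JSON record (or list of records for batches) embedding samples and
    metadata.  Python's JSON float formatting uses ``repr`` and therefore
    round-trips float64 bit-exactly.

Fitted models and simulator configs are serialized as JSON objects with a
``kind`` tag.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .types import (
    GroundTruth,
    LinearModel,
    PATimeSeries,
    PiecewiseQuadModel,
    SimulatorConfig,
    TransducerIR,
)

_REQUIRED_SIGNAL_FIELDS = ("sampling_rate", "pulse_energy")
_SIGNAL_FIELDS = (
    "sampling_rate",
    "time_offset",
    "pulse_energy",
    "wavelength",
    "polarization",
    "replicate_id",
)


def _signal_record(signal: PATimeSeries) -> dict:
    return {
        "sampling_rate": signal.sampling_rate,
        "time_offset": signal.time_offset,
        "pulse_energy": signal.pulse_energy,
        "wavelength": signal.wavelength,
        "polarization": signal.polarization,
        "replicate_id": signal.replicate_id,
        "meta": signal.meta,
        "samples": [float(v) for v in signal.samples],
    }


def _signal_from_record(record: dict) -> PATimeSeries:
    for name in _REQUIRED_SIGNAL_FIELDS:
        if name not in record:
            raise ValueError(f"missing metadata field: {name}")
    samples = record.get("samples")
    if samples is None:
        raise ValueError("missing metadata field: samples")
    return PATimeSeries(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=record["sampling_rate"],
        time_offset=record.get("time_offset", 0.0),
        pulse_energy=record["pulse_energy"],
        wavelength=record.get("wavelength", 1560.0),
        polarization=record.get("polarization", "V"),
        replicate_id=record.get("replicate_id", ""),
        meta=dict(record.get("meta", {})),
    )


def write_signal(signal: PATimeSeries, path, format: str = "container") -> None:
    """Write one trace to ``path`` in the requested format."""
    path = Path(path)
    if format == "container":
        path.write_text(json.dumps(_signal_record(signal), indent=1))
    elif format == "delimited":
        lines = []
        for name in _SIGNAL_FIELDS:
            lines.append(f"# {name}: {getattr(signal, name)}")
        lines.append(f"# meta: {json.dumps(signal.meta)}")
        for t, v in zip(signal.times(), signal.samples):
            lines.append(f"{t:.17g}\t{v:.17g}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown signal format: {format!r}")


def read_signal(path, format: str = "container") -> PATimeSeries:
    """Read one validated trace from ``path``.

    Raises ``ValueError`` naming the missing metadata field, or a parse
    error for non-numeric samples.
    """
    path = Path(path)
    text = path.read_text()
    if format == "container":
        try:
            record = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"could not parse container signal {path}: {exc}") from exc
        if not isinstance(record, dict):
            raise ValueError("container signal must be a single JSON object")
        return _signal_from_record(record)
    if format == "delimited":
        header: dict = {}
        samples = []
        times = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                samples.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric sample value") from exc
        for name in _REQUIRED_SIGNAL_FIELDS:
            if name not in header:
                raise ValueError(f"missing metadata field: {name}")
        meta = json.loads(header["meta"]) if "meta" in header else {}
        return PATimeSeries(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=float(header["sampling_rate"]),
            time_offset=float(header.get("time_offset", times[0] if times else 0.0)),
            pulse_energy=float(header["pulse_energy"]),
            wavelength=float(header.get("wavelength", 1560.0)),
            polarization=header.get("polarization", "V"),
            replicate_id=header.get("replicate_id", ""),
            meta=meta,
        )
    raise ValueError(f"unknown signal format: {format!r}")


def write_signals(signals, path) -> None:
    """Write a batch of traces as a JSON container archive."""
    records = [_signal_record(s) for s in signals]
    Path(path).write_text(json.dumps(records, indent=1))


def read_signals(path) -> list:
    """Read a batch of traces from a JSON container archive."""
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"could not parse container archive {path}: {exc}") from exc
    if not isinstance(records, list):
        raise ValueError("container archive must be a JSON list of records")
    return [_signal_from_record(r) for r in records]


# ---------------------------------------------------------------------------
# impulse responses

def write_impulse_response(ir: TransducerIR, path) -> None:
    record = {
        "kind": "transducer_ir",
        "sampling_rate": ir.sampling_rate,
        "center_frequency": ir.center_frequency,
        "fractional_bandwidth": ir.fractional_bandwidth,
        "samples": [float(v) for v in ir.samples],
    }
    Path(path).write_text(json.dumps(record, indent=1))


def read_impulse_response(path) -> TransducerIR:
    record = json.loads(Path(path).read_text())
    for key in ("sampling_rate", "center_frequency", "fractional_bandwidth", "samples"):
        if key not in record:
            raise ValueError(f"impulse response file missing key: {key}")
    return TransducerIR(
        samples=np.asarray(record["samples"], dtype=float),
        sampling_rate=record["sampling_rate"],
        center_frequency=record["center_frequency"],
        fractional_bandwidth=record["fractional_bandwidth"],
    )


# ---------------------------------------------------------------------------
# fitted models

_MODEL_KINDS = {
    "piecewise_quadratic": PiecewiseQuadModel,
    "linear": LinearModel,
}


def write_model(model, path) -> None:
    """Serialize a fitted calibration model as structured text (JSON)."""
    if isinstance(model, PiecewiseQuadModel):
        kind = "piecewise_quadratic"
    elif isinstance(model, LinearModel):
        kind = "linear"
    else:
        raise ValueError(f"unsupported model type: {type(model).__name__}")
    record = {"kind": kind, **dataclasses.asdict(model)}
    Path(path).write_text(json.dumps(record, indent=1))


def read_model(path):
    """Read a calibration model; ``read_model(write_model(m)) == m``."""
    try:
        record = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"could not parse model file {path}: {exc}") from exc
    kind = record.pop("kind", None)
    if kind not in _MODEL_KINDS:
        raise ValueError(f"model file has unknown or missing kind: {kind!r}")
    cls = _MODEL_KINDS[kind]
    expected = {f.name for f in dataclasses.fields(cls)}
    missing = expected - record.keys()
    if missing:
        raise ValueError(f"model file missing key: {sorted(missing)[0]}")
    extra = record.keys() - expected
    if extra:
        raise ValueError(f"model file has unknown key: {sorted(extra)[0]}")
    return cls(**record)


# ---------------------------------------------------------------------------
# simulator configs and ground truth sidecars

def write_config(config: SimulatorConfig, path) -> None:
    record = {"kind": "simulator_config", **dataclasses.asdict(config)}
    Path(path).write_text(json.dumps(record, indent=1))


def read_config(path) -> SimulatorConfig:
    record = json.loads(Path(path).read_text())
    if record.pop("kind", "simulator_config") != "simulator_config":
        raise ValueError("not a simulator config file")
    return SimulatorConfig(**record)


def write_ground_truths(truths, path) -> None:
    records = [
        {"concentration": t.concentration, "config": dataclasses.asdict(t.config)}
        for t in truths
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_ground_truths(path) -> list:
    records = json.loads(Path(path).read_text())
    return [
        GroundTruth(concentration=r["concentration"], config=SimulatorConfig(**r["config"]))
        for r in records
    ]
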