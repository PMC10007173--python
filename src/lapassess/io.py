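"""Readers and writers for detection streams and session results.

Two detection-stream dialects are supported:

* **JSON Lines** (``.jsonl``) — one frame per line::

      {"camera": "top", "frame_index": 0, "timestamp": 0.0,
       "detections": [{"label": "right_grasper", "score": 0.9,
                       "bbox": [xmin, ymin, xmax, ymax]}]}

* **CSV** — one detection per row with columns
  ``camera,frame_index,timestamp,label,score,xmin,ymin,xmax,ymax``;
  frames with no detections appear as a row with empty label/score/bbox.

Results are written as a CSV time series plus a JSON summary.  Malformed
input is rejected with the offending line number.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ContractViolationError, StreamFormatError
from .geometry import BoundingBox
from .streams import Detection, DetectionRecord, SessionResult, validate_stream

__all__ = [
    "read_detection_stream",
    "write_detection_stream",
    "write_series_csv",
    "write_summary_json",
    "read_truth_sidecar",
    "write_truth_sidecar",
]

_CSV_FIELDS = [
    "camera",
    "frame_index",
    "timestamp",
    "label",
    "score",
    "xmin",
    "ymin",
    "xmax",
    "ymax",
]


class _DetectionModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    score: float = Field(ge=0, le=1)
    bbox: tuple[float, float, float, float]


class _RecordModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    camera: str
    frame_index: int = Field(ge=0)
    timestamp: float
    detections: list[_DetectionModel] = []


def _build_record(model: _RecordModel, where: str) -> DetectionRecord:
    dets = []
    for d in model.detections:
        try:
            bbox = BoundingBox(*d.bbox)
            dets.append(Detection(d.label, d.score, bbox))
        except ContractViolationError as exc:
            raise StreamFormatError(f"{where}: {exc}") from exc
    try:
        return DetectionRecord(
            model.camera, model.frame_index, model.timestamp, tuple(dets)
        )
    except ContractViolationError as exc:
        raise StreamFormatError(f"{where}: {exc}") from exc


def _infer_format(path: Path, format: str | None) -> str:
    if format:
        return format
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if path.suffix.lower() == ".csv":
        return "csv"
    raise StreamFormatError(
        f"cannot infer stream format from suffix {path.suffix!r}; "
        "pass format='jsonl' or 'csv'"
    )


def read_detection_stream(
    path: str | Path, format: str | None = None
) -> list[DetectionRecord]:
    """Read, validate and order-check a detection stream file."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = _read_jsonl(path) if fmt == "jsonl" else _read_csv(path)
    validate_stream(records)
    return records


def _read_jsonl(path: Path) -> list[DetectionRecord]:
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path.name} line {lineno}"
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(f"{where}: invalid JSON: {exc}") from exc
            try:
                model = _RecordModel.model_validate(payload)
            except ValidationError as exc:
                fields = ", ".join(
                    "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
                    for err in exc.errors()
                )
                raise StreamFormatError(f"{where}: {fields}") from exc
            records.append(_build_record(model, where))
    return records


def _read_csv(path: Path) -> list[DetectionRecord]:
    by_frame: dict[tuple[str, int], dict] = {}
    order: list[tuple[str, int]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise StreamFormatError(
                f"{path.name}: missing CSV columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name} line {lineno}"
            try:
                key = (row["camera"], int(row["frame_index"]))
                ts = float(row["timestamp"])
            except (TypeError, ValueError) as exc:
                raise StreamFormatError(f"{where}: {exc}") from exc
            if key not in by_frame:
                by_frame[key] = {"timestamp": ts, "detections": []}
                order.append(key)
            if row["label"]:
                try:
                    det = _DetectionModel(
                        label=row["label"],
                        score=float(row["score"]),
                        bbox=(
                            float(row["xmin"]),
                            float(row["ymin"]),
                            float(row["xmax"]),
                            float(row["ymax"]),
                        ),
                    )
                except (ValueError, ValidationError) as exc:
                    raise StreamFormatError(f"{where}: {exc}") from exc
                by_frame[key]["detections"].append((where, det))
    records = []
    for camera, frame_index in order:
        entry = by_frame[(camera, frame_index)]
        model = _RecordModel(
            camera=camera,
            frame_index=frame_index,
            timestamp=entry["timestamp"],
            detections=[d for _, d in entry["detections"]],
        )
        where = entry["detections"][0][0] if entry["detections"] else path.name
        records.append(_build_record(model, where))
    return records


def write_detection_stream(
    records: Sequence[DetectionRecord], path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                payload = {
                    "camera": rec.camera,
                    "frame_index": rec.frame_index,
                    "timestamp": rec.timestamp,
                    "detections": [
                        {
                            "label": d.label,
                            "score": d.score,
                            "bbox": [d.bbox.xmin, d.bbox.ymin, d.bbox.xmax, d.bbox.ymax],
                        }
                        for d in rec.detections
                    ],
                }
                fh.write(json.dumps(payload) + "\n")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_FIELDS)
            for rec in records:
                base = [rec.camera, rec.frame_index, rec.timestamp]
                if not rec.detections:
                    writer.writerow(base + [""] * 6)
                for d in rec.detections:
                    writer.writerow(
                        base
                        + [d.label, d.score, d.bbox.xmin, d.bbox.ymin, d.bbox.xmax, d.bbox.ymax]
                    )


def write_series_csv(result: SessionResult, path: str | Path) -> None:
    result.series.to_csv(path, index=False)


def write_summary_json(result: SessionResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_truth_sidecar(truth: Sequence[dict], path: str | Path) -> None:
    """Ground-truth sidecar from the simulator: one JSON object per frame."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in truth:
            fh.write(json.dumps(row) + "\n")


def read_truth_sidecar(path: str | Path) -> list[dict]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    return rows
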