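"""Record serialisation: JSON (canonical) and long-format CSV.

A record file holds one or more nodules, each with its type, morphology
token sets, context flags and time-ordered measurement series.  JSON is
the canonical format; CSV is a lossless long-format alternative with one
row per (nodule, component, timepoint) and semicolon-joined morphology
tokens.  All ``NoduleRecord`` invariants are enforced at load time and
validation errors name the offending nodule id or token.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .engine import (
    BENIGN_TOKENS,
    SUSPICIOUS_TOKENS,
    NoduleContext,
    NoduleRecord,
    Recommendation,
)
from .errors import InvalidInputError
from .measurement import Method, SegQuality, SizeMeasurement

__all__ = [
    "read_records",
    "write_records",
    "records_from_dicts",
    "records_to_dicts",
    "recommendation_to_dict",
]

_CSV_COLUMNS = [
    "nodule_id",
    "type",
    "component",
    "t_days",
    "volume_mm3",
    "d1_mm",
    "d2_mm",
    "d3_mm",
    "seg_quality",
    "method",
    "morphology_suspicious",
    "morphology_benign",
    "morphology_changed",
    "context",
]

_CONTEXT_BOOL_FLAGS = (
    "is_new",
    "visible_in_retrospect",
    "evident_growth",
    "infectious_pattern_1mo",
    "pneumonia_differential",
)


def _measurement_from_dict(d: dict) -> SizeMeasurement:
    diam = d.get("diameters_mm")
    return SizeMeasurement(
        t_days=float(d["t_days"]),
        volume_mm3=None if d.get("volume_mm3") is None else float(d["volume_mm3"]),
        diameters_mm=None if diam is None else tuple(float(x) for x in diam),
        seg_quality=None if d.get("seg_quality") is None else SegQuality(d["seg_quality"]),
        method=Method(d.get("method", "volumetry")),
    )


def _measurement_to_dict(m: SizeMeasurement) -> dict:
    return {
        "t_days": m.t_days,
        "volume_mm3": m.volume_mm3,
        "diameters_mm": None if m.diameters_mm is None else list(m.diameters_mm),
        "seg_quality": None if m.seg_quality is None else m.seg_quality.value,
        "method": m.method.value,
    }


def records_from_dicts(dicts: Sequence[dict]) -> List[NoduleRecord]:
    records = []
    seen_ids = set()
    for d in dicts:
        if "id" not in d:
            raise InvalidInputError("nodule entry lacks an 'id' field")
        nid = str(d["id"])
        if nid in seen_ids:
            raise InvalidInputError(f"duplicate nodule id {nid!r}")
        seen_ids.add(nid)
        ctx = dict(d.get("context") or {})
        records.append(
            NoduleRecord(
                id=nid,
                type=d["type"],
                total_series=tuple(
                    _measurement_from_dict(m) for m in d.get("total_series", ())
                ),
                solid_series=tuple(
                    _measurement_from_dict(m) for m in d.get("solid_series", ())
                ),
                morphology_suspicious=frozenset(d.get("morphology_suspicious", ())),
                morphology_benign=frozenset(d.get("morphology_benign", ())),
                morphology_changed=bool(d.get("morphology_changed", False)),
                context=NoduleContext(**ctx),
            )
        )
    return records


def records_to_dicts(records: Sequence[NoduleRecord]) -> List[dict]:
    out = []
    for r in records:
        ctx = asdict(r.context)
        if ctx["bronchus_location"] is not None:
            ctx["bronchus_location"] = r.context.bronchus_location.value
        out.append(
            {
                "id": r.id,
                "type": r.type.value,
                "total_series": [_measurement_to_dict(m) for m in r.total_series],
                "solid_series": [_measurement_to_dict(m) for m in r.solid_series],
                "morphology_suspicious": sorted(r.morphology_suspicious),
                "morphology_benign": sorted(r.morphology_benign),
                "morphology_changed": r.morphology_changed,
                "context": ctx,
            }
        )
    return out


# -- JSON ------------------------------------------------------------------


def _read_json(path: Path) -> List[NoduleRecord]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise InvalidInputError(f"{path}: JSON parse error at line {e.lineno}: {e.msg}")
    if isinstance(doc, dict):
        doc = doc.get("nodules", doc)
    if not isinstance(doc, list):
        raise InvalidInputError(f"{path}: expected a list of nodules or a 'nodules' key")
    return records_from_dicts(doc)


def _write_json(records: Sequence[NoduleRecord], path: Path) -> None:
    path.write_text(
        json.dumps({"nodules": records_to_dicts(records)}, indent=1, sort_keys=True)
        + "\n"
    )


# -- CSV long format -------------------------------------------------------


def _parse_tokens(cell: str) -> frozenset:
    if not cell:
        return frozenset()
    return frozenset(t for t in cell.split(";") if t)


def _parse_context(cell: str) -> NoduleContext:
    kwargs: Dict[str, object] = {}
    for token in (t for t in (cell or "").split(";") if t):
        if "=" in token:
            key, value = token.split("=", 1)
            if key == "bronchus_location":
                kwargs[key] = value
            elif key == "bronchus_diameter_mm":
                kwargs[key] = float(value)
            else:
                raise InvalidInputError(f"unknown context key {key!r}")
        elif token in _CONTEXT_BOOL_FLAGS:
            kwargs[token] = True
        else:
            raise InvalidInputError(f"unknown context token {token!r}")
    return NoduleContext(**kwargs)


def _format_context(ctx: NoduleContext) -> str:
    parts = [f for f in _CONTEXT_BOOL_FLAGS if getattr(ctx, f)]
    if ctx.bronchus_location is not None:
        parts.append(f"bronchus_location={ctx.bronchus_location.value}")
    if ctx.bronchus_diameter_mm is not None:
        parts.append(f"bronchus_diameter_mm={ctx.bronchus_diameter_mm!r}")
    return ";".join(parts)


def _read_csv(path: Path) -> List[NoduleRecord]:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise InvalidInputError(f"{path}: missing CSV columns: {sorted(missing)}")
        rows = list(reader)

    by_id: Dict[str, dict] = {}
    seen_keys = set()
    for lineno, row in enumerate(rows, start=2):
        nid = row["nodule_id"]
        if not nid:
            raise InvalidInputError(f"{path}:{lineno}: empty nodule_id")
        key = (nid, row["component"], float(row["t_days"]))
        if key in seen_keys:
            raise InvalidInputError(
                f"{path}:{lineno}: duplicate timepoint for nodule {nid!r} "
                f"(component={row['component']}, t_days={row['t_days']})"
            )
        seen_keys.add(key)
        entry = by_id.setdefault(
            nid,
            {
                "id": nid,
                "type": row["type"],
                "total_series": [],
                "solid_series": [],
                "morphology_suspicious": _parse_tokens(row["morphology_suspicious"]),
                "morphology_benign": _parse_tokens(row["morphology_benign"]),
                "morphology_changed": row["morphology_changed"].lower()
                in ("1", "true", "yes"),
                "context": None,
                "_ctx_raw": row["context"],
            },
        )
        diam = None
        if row["d1_mm"]:
            diam = [float(row["d1_mm"]), float(row["d2_mm"]), float(row["d3_mm"])]
        measurement = {
            "t_days": float(row["t_days"]),
            "volume_mm3": float(row["volume_mm3"]) if row["volume_mm3"] else None,
            "diameters_mm": diam,
            "seg_quality": row["seg_quality"] or None,
            "method": row["method"] or "volumetry",
        }
        component = row["component"]
        if component not in ("total", "solid"):
            raise InvalidInputError(
                f"{path}:{lineno}: component must be 'total' or 'solid', "
                f"got {component!r}"
            )
        entry[f"{component}_series"].append(measurement)

    records = []
    for nid, entry in by_id.items():
        for tok in entry["morphology_suspicious"] - SUSPICIOUS_TOKENS:
            raise InvalidInputError(
                f"{path}: nodule {nid!r}: unknown morphology_suspicious token {tok!r}"
            )
        for tok in entry["morphology_benign"] - BENIGN_TOKENS:
            raise InvalidInputError(
                f"{path}: nodule {nid!r}: unknown morphology_benign token {tok!r}"
            )
        records.append(
            NoduleRecord(
                id=nid,
                type=entry["type"],
                total_series=tuple(
                    _measurement_from_dict(m)
                    for m in sorted(entry["total_series"], key=lambda m: m["t_days"])
                ),
                solid_series=tuple(
                    _measurement_from_dict(m)
                    for m in sorted(entry["solid_series"], key=lambda m: m["t_days"])
                ),
                morphology_suspicious=entry["morphology_suspicious"],
                morphology_benign=entry["morphology_benign"],
                morphology_changed=entry["morphology_changed"],
                context=_parse_context(entry["_ctx_raw"]),
            )
        )
    return records


def _write_csv(records: Sequence[NoduleRecord], path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for r in records:
            for component, series in (("total", r.total_series), ("solid", r.solid_series)):
                for m in series:
                    writer.writerow(
                        {
                            "nodule_id": r.id,
                            "type": r.type.value,
                            "component": component,
                            "t_days": repr(m.t_days),
                            "volume_mm3": "" if m.volume_mm3 is None else repr(m.volume_mm3),
                            "d1_mm": "" if m.diameters_mm is None else repr(m.diameters_mm[0]),
                            "d2_mm": "" if m.diameters_mm is None else repr(m.diameters_mm[1]),
                            "d3_mm": "" if m.diameters_mm is None else repr(m.diameters_mm[2]),
                            "seg_quality": "" if m.seg_quality is None else m.seg_quality.value,
                            "method": m.method.value,
                            "morphology_suspicious": ";".join(sorted(r.morphology_suspicious)),
                            "morphology_benign": ";".join(sorted(r.morphology_benign)),
                            "morphology_changed": "true" if r.morphology_changed else "",
                            "context": _format_context(r.context),
                        }
                    )


def read_records(path: Union[str, Path]) -> List[NoduleRecord]:
    """Load and validate nodule records from a JSON or CSV file (by
    extension; anything not ``.csv`` is parsed as JSON)."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"record file not found: {path}")
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    return _read_json(path)


def write_records(records: Sequence[NoduleRecord], path: Union[str, Path]) -> None:
    """Write records to JSON (canonical) or long-format CSV by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv(records, path)
    else:
        _write_json(records, path)


# -- output serialisation --------------------------------------------------


def _days_value(x: Optional[float]):
    """JSON-safe day count: unbounded VDTs serialise as 'inf'/'-inf'."""
    if x is None:
        return None
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return x


def recommendation_to_dict(rec: Recommendation, nodule_id: Optional[str] = None) -> dict:
    d = {
        "action": rec.action.value,
        "interval_months": rec.interval_months,
        "screen_result": rec.screen_result.value,
        "category": rec.category.name.lower(),
        "rule_trace": list(rec.rule_trace),
    }
    if nodule_id is not None:
        d = {"nodule_id": nodule_id, **d}
    return d
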