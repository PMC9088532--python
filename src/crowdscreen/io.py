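"""Readers and writers for the package's exchange formats.

CSV is the canonical interchange format (streams, decisions, reference
standards, corpora); RIS is accepted as read-only input for bibliographic
records, since search exports commonly arrive that way.  All round-trips
through the CSV writers/readers are lossless.

Machine-readable reports are JSON validated against the schema shipped at
``crowdscreen/schemas/report.schema.json``; a Markdown rendering is provided
for humans.  Every CLI run additionally records a :class:`RunManifest`
sufficient to re-run the command bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .aggregation import (
    ClassificationEvent,
    CrowdDecision,
    DecisionStatus,
    MalformedStreamError,
    Verdict,
)
from .evaluation import PerformanceReport, RecordEntry, ReferenceLabel

PathLike = Union[str, Path]

STREAM_COLUMNS = ["record_id", "contributor_id", "ordinal", "verdict", "timestamp_hours"]
DECISION_COLUMNS = [
    "record_id",
    "status",
    "reached_by_consensus",
    "n_classifications",
    "resolver_verdict",
]
RECORD_COLUMNS = ["record_id", "title", "abstract", "title_only", "reference_label"]
REFERENCE_COLUMNS = ["record_id", "reference_label"]


class SchemaError(ValueError):
    """A file does not conform to its expected column schema or vocabulary."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _nan_to_none(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value == "":
        return None
    return value


# ---------------------------------------------------------------------------
# records (corpus): RIS and CSV


def _parse_ris(path: Path) -> list[RecordEntry]:
    """Minimal RIS reader: TI (title), AB (abstract), ID/AN (identifier),
    ER (end of record).  Continuation lines extend the previous tag."""
    records: list[RecordEntry] = []
    current: dict[str, str] = {}
    tag: Optional[str] = None
    n_anonymous = 0

    def _flush(lineno: int) -> None:
        nonlocal n_anonymous
        if not current:
            return
        title = current.get("TI") or current.get("T1")
        if not title:
            raise SchemaError(f"{path}:{lineno}: RIS record has no TI/T1 title")
        record_id = current.get("ID") or current.get("AN")
        if not record_id:
            n_anonymous += 1
            record_id = f"ris-{n_anonymous:05d}"
        records.append(
            RecordEntry(
                record_id=record_id,
                title=title.strip(),
                abstract=(current.get("AB") or "").strip() or None,
            )
        )
        current.clear()

    with open(path, encoding="utf-8-sig") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if len(line) >= 6 and line[2:6] == "  - ":
                tag = line[:2]
                value = line[6:]
                if tag == "ER":
                    _flush(lineno)
                    tag = None
                elif tag in current:
                    current[tag] += " " + value
                else:
                    current[tag] = value
            elif tag is not None:
                current[tag] += " " + line.strip()
            else:
                raise SchemaError(f"{path}:{lineno}: unparseable RIS line {line!r}")
    _flush(lineno if records or current else 0)
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"{path}: duplicate record_id(s) {dupes}")
    return records


def read_records(path: PathLike, format: Optional[str] = None) -> list[RecordEntry]:
    """Read a corpus from RIS or CSV; format inferred from the extension
    when not given (``.ris``/``.txt`` → RIS, ``.csv`` → CSV)."""
    path = Path(path)
    if format is None:
        format = "ris" if path.suffix.lower() in {".ris", ".txt"} else "csv"
    format = format.lower()
    if format == "ris":
        return _parse_ris(path)
    if format != "csv":
        raise ValueError(f"unknown record format {format!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["record_id", "title"], path)
    records = []
    seen: set[str] = set()
    for row in df.to_dict("records"):
        record_id = row["record_id"]
        if record_id in seen:
            raise SchemaError(f"{path}: duplicate record_id {record_id!r}")
        seen.add(record_id)
        label = row.get("reference_label") or "unknown"
        try:
            records.append(
                RecordEntry(
                    record_id=record_id,
                    title=row["title"],
                    abstract=_nan_to_none(row.get("abstract")),
                    reference_label=ReferenceLabel(label),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: record {record_id!r}: {exc}") from exc
    return records


def write_records(path: PathLike, records: Sequence[RecordEntry]) -> None:
    pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "title": r.title,
                "abstract": r.abstract or "",
                "title_only": r.title_only,
                "reference_label": r.reference_label.value,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# classification streams


def read_stream(path: PathLike) -> list[ClassificationEvent]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, STREAM_COLUMNS[:4], path)
    events = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # header = line 1
        try:
            ts = _nan_to_none(row.get("timestamp_hours"))
            events.append(
                ClassificationEvent(
                    record_id=row["record_id"],
                    contributor_id=row["contributor_id"],
                    verdict=Verdict(row["verdict"]),
                    ordinal=int(row["ordinal"]),
                    timestamp_hours=float(ts) if ts is not None else None,
                )
            )
        except (ValueError, MalformedStreamError) as exc:
            raise SchemaError(f"{path}: line {i}: {exc}") from exc
    return events


def write_stream(path: PathLike, stream: Iterable[ClassificationEvent]) -> None:
    pd.DataFrame(
        [
            {
                "record_id": e.record_id,
                "contributor_id": e.contributor_id,
                "ordinal": e.ordinal,
                "verdict": e.verdict.value,
                "timestamp_hours": (
                    "" if e.timestamp_hours is None else repr(e.timestamp_hours)
                ),
            }
            for e in stream
        ],
        columns=STREAM_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reference standard


def read_reference(path: PathLike) -> dict[str, ReferenceLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, REFERENCE_COLUMNS, path)
    reference: dict[str, ReferenceLabel] = {}
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            reference[row["record_id"]] = ReferenceLabel(row["reference_label"])
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i}: {exc}") from exc
    return reference


def write_reference(path: PathLike, reference: Mapping[str, ReferenceLabel]) -> None:
    pd.DataFrame(
        [{"record_id": k, "reference_label": ReferenceLabel(v).value} for k, v in reference.items()],
        columns=REFERENCE_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# decisions


def read_decisions(path: PathLike) -> list[CrowdDecision]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DECISION_COLUMNS, path)
    decisions = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            resolver = _nan_to_none(row["resolver_verdict"])
            decisions.append(
                CrowdDecision(
                    record_id=row["record_id"],
                    status=DecisionStatus(row["status"]),
                    reached_by_consensus=row["reached_by_consensus"].lower() == "true",
                    n_classifications=int(row["n_classifications"]),
                    resolver_verdict=Verdict(resolver) if resolver else None,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: line {i}: {exc}") from exc
    return decisions


def write_decisions(path: PathLike, decisions: Sequence[CrowdDecision]) -> None:
    pd.DataFrame(
        [
            {
                "record_id": d.record_id,
                "status": d.status.value,
                "reached_by_consensus": d.reached_by_consensus,
                "n_classifications": d.n_classifications,
                "resolver_verdict": d.resolver_verdict.value if d.resolver_verdict else "",
            }
            for d in decisions
        ],
        columns=DECISION_COLUMNS,
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports


def report_to_dict(report: PerformanceReport) -> dict:
    return {
        "counts": {
            "tp": report.counts.tp,
            "tn": report.counts.tn,
            "fp": report.counts.fp,
            "fn": report.counts.fn,
            "total": report.counts.total,
        },
        "sensitivity_pct": report.sensitivity_pct,
        "specificity_pct": report.specificity_pct,
        "consensus_pct": report.consensus_pct,
        "included_consensus_pct": report.included_consensus_pct,
        "title_only_consensus_pct": report.title_only_consensus_pct,
        "missed_record_ids": list(report.missed_record_ids),
    }


def report_to_markdown(report: PerformanceReport, title: str = "Screening report") -> str:
    c = report.counts
    lines = [
        f"# {title}",
        "",
        f"Records evaluated: {c.total}",
        "",
        "| metric | value |",
        "|---|---|",
        f"| TP / TN / FP / FN | {c.tp} / {c.tn} / {c.fp} / {c.fn} |",
        f"| sensitivity | {report.sensitivity_pct}% |",
        f"| specificity | {report.specificity_pct}% |",
        f"| consensus | {report.consensus_pct}% |",
    ]
    if report.included_consensus_pct is not None:
        lines.append(f"| consensus (includable studies) | {report.included_consensus_pct}% |")
    if report.title_only_consensus_pct is not None:
        lines.append(f"| consensus (title-only records) | {report.title_only_consensus_pct}% |")
    lines.append("")
    if report.missed_record_ids:
        lines.append("Missed studies (false negatives):")
        lines.extend(f"- {rid}" for rid in report.missed_record_ids)
    else:
        lines.append("No includable studies were missed.")
    lines.append("")
    return "\n".join(lines)


def load_report_schema() -> dict:
    with resources.files("crowdscreen").joinpath("schemas/report.schema.json").open() as fh:
        return json.load(fh)


_JSON_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def validate_against_schema(instance, schema: dict, path: str = "$") -> None:
    """Validate ``instance`` against the subset of JSON Schema the report
    schema uses (type, required, properties, items).  Raises SchemaError."""
    expected = schema.get("type")
    if expected is not None:
        types = expected if isinstance(expected, list) else [expected]
        ok = any(
            isinstance(instance, _JSON_TYPES[t])
            and not (t in {"integer", "number"} and isinstance(instance, bool))
            for t in types
        )
        if not ok:
            raise SchemaError(f"{path}: expected type {expected}, got {type(instance).__name__}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise SchemaError(f"{path}: missing required key {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in instance:
                validate_against_schema(instance[key], subschema, f"{path}.{key}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            validate_against_schema(item, schema["items"], f"{path}[{i}]")


def write_report(
    report: PerformanceReport,
    json_path: Optional[PathLike] = None,
    markdown_path: Optional[PathLike] = None,
    title: str = "Screening report",
) -> dict:
    """Emit a report as JSON (validated against the shipped schema) and/or
    Markdown; returns the JSON-ready dict."""
    payload = report_to_dict(report)
    validate_against_schema(payload, load_report_schema())
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    if markdown_path is not None:
        Path(markdown_path).write_text(report_to_markdown(report, title=title))
    return payload


# ---------------------------------------------------------------------------
# run manifest


def file_digest(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to re-run it bit-identically:
    the command and its configuration, all seeds, input digests, package
    version, per-stage timings and every output path."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timings_seconds: dict = field(default_factory=dict)
    package_version: str = ""

    def add_input(self, path: PathLike) -> None:
        self.input_digests[str(path)] = file_digest(path)

    def add_output(self, path: PathLike) -> None:
        self.outputs.append(str(path))

    def write(self, path: PathLike) -> None:
        if self.package_version == "":
            from . import __version__

            self.package_version = __version__
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
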