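"""File formats: record CSVs, rule-set files, review exports, reports.

Records travel as CSV in two dialects:

* ``long`` — columns ``record_id, hospital_id, age, code``, one row per
  diagnosis code; rows sharing a record id merge into one code set.
* ``wide`` — columns ``record_id, hospital_id, age, dx1 .. dx25``, one
  row per record with blank trailing diagnosis cells.

Codes are accepted dotted or dot-free and always written in canonical
dotted four-character form.  Malformed rows are collected (with line
numbers) rather than failing one by one; a file with more than 10%
malformed rows aborts.

Rule sets are versioned JSON documents that round-trip losslessly,
accompanied by a flat review CSV (one rule per row) for expert-panel
style reading.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .icd import InvalidCodeError, parse_code
from .mining import AssociationRule
from .records import MAX_CODES_PER_RECORD, DischargeRecord

RULESET_FORMAT_VERSION = 1
_DIALECTS = ("long", "wide")
_MALFORMED_ABORT_FRACTION = 0.10


class RecordReadError(ValueError):
    """Unreadable file, unknown dialect, or too many malformed rows."""


@dataclass
class RecordReadReport:
    n_records: int = 0
    n_dropped_empty: int = 0
    #: (line number, message) per malformed row.
    errors: list[tuple[int, str]] = field(default_factory=list)


# ----------------------------------------------------------------------
# Records
# ----------------------------------------------------------------------

def read_records(path: Union[str, Path], dialect: str = "long"
                 ) -> tuple[list[DischargeRecord], RecordReadReport]:
    """Read discharge records from CSV (see module docstring)."""
    if dialect not in _DIALECTS:
        raise RecordReadError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise RecordReadError(f"cannot read {path}: {exc}") from exc

    report = RecordReadReport()
    # line number of each row in the file (1-based, header is line 1)
    lines = df.index.to_numpy() + 2

    parsed: dict[int, tuple[str, int, set[str]]] = {}
    n_rows = len(df)
    for i in range(n_rows):
        row = df.iloc[i]
        line = int(lines[i])
        try:
            record_id = int(str(row["record_id"]).strip())
            hospital_id = str(row["hospital_id"]).strip()
            age = int(str(row["age"]).strip())
            if age < 0:
                raise ValueError("negative age")
            if not hospital_id:
                raise ValueError("missing hospital id")
        except (KeyError, ValueError) as exc:
            report.errors.append((line, f"bad row: {exc}"))
            continue
        raw_codes = []
        if dialect == "long":
            raw_codes = [row.get("code", "")]
        else:
            raw_codes = [row.get(f"dx{j}", "")
                         for j in range(1, MAX_CODES_PER_RECORD + 1)]
        codes: set[str] = set()
        bad = False
        for raw in raw_codes:
            raw = (raw or "").strip()
            if not raw:
                continue
            try:
                codes.add(parse_code(raw).code)
            except InvalidCodeError as exc:
                report.errors.append((line, str(exc)))
                bad = True
        if bad:
            continue
        if record_id in parsed:
            prev_h, prev_a, prev_codes = parsed[record_id]
            if dialect == "long" and (prev_h, prev_a) == (hospital_id, age):
                prev_codes |= codes
            else:
                report.errors.append((line, f"conflicting duplicate "
                                            f"record_id {record_id}"))
            continue
        parsed[record_id] = (hospital_id, age, codes)

    if n_rows and len(report.errors) > _MALFORMED_ABORT_FRACTION * n_rows:
        raise RecordReadError(
            f"{len(report.errors)} malformed rows out of {n_rows} "
            f"(> {_MALFORMED_ABORT_FRACTION:.0%}); aborting"
        )

    records: list[DischargeRecord] = []
    for record_id in sorted(parsed):
        hospital_id, age, codes = parsed[record_id]
        if not codes:
            report.n_dropped_empty += 1
            continue
        records.append(DischargeRecord(record_id=record_id,
                                       hospital_id=hospital_id, age=age,
                                       codes=frozenset(codes)))
    report.n_records = len(records)
    return records, report


def write_records(records: Sequence[DischargeRecord],
                  path: Union[str, Path], dialect: str = "long") -> None:
    if dialect not in _DIALECTS:
        raise RecordReadError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "long":
            writer.writerow(["record_id", "hospital_id", "age", "code"])
            for r in records:
                for code in sorted(r.codes):
                    writer.writerow([r.record_id, r.hospital_id, r.age,
                                     code])
        else:
            writer.writerow(["record_id", "hospital_id", "age"]
                            + [f"dx{j}"
                               for j in range(1, MAX_CODES_PER_RECORD + 1)])
            for r in records:
                codes = sorted(r.codes)
                codes += [""] * (MAX_CODES_PER_RECORD - len(codes))
                writer.writerow([r.record_id, r.hospital_id, r.age] + codes)


# ----------------------------------------------------------------------
# Rule sets
# ----------------------------------------------------------------------

@dataclass
class RuleSetFile:
    rules: list[AssociationRule]
    provenance: dict = field(default_factory=dict)
    format_version: int = RULESET_FORMAT_VERSION


def _rule_to_dict(rule: AssociationRule) -> dict:
    return {
        "rule_id": rule.rule_id,
        "lhs": sorted(rule.lhs),
        "rhs": rule.rhs,
        "age_group": rule.age_group,
        "level": rule.level,
        "joint_count": rule.joint_count,
        "lhs_count": rule.lhs_count,
        "n": rule.n,
        "support": rule.support,
        "lhs_support": rule.lhs_support,
        "confidence": rule.confidence,
        "p_value": rule.p_value,
        "p_adjusted": rule.p_adjusted,
        "confidence_validation": rule.confidence_validation,
        "reference_confidence": rule.reference_confidence,
    }


def _rule_from_dict(d: dict) -> AssociationRule:
    return AssociationRule(
        rule_id=d["rule_id"], lhs=frozenset(d["lhs"]), rhs=d["rhs"],
        age_group=d["age_group"], level=int(d["level"]),
        joint_count=int(d["joint_count"]), lhs_count=int(d["lhs_count"]),
        n=int(d["n"]), p_value=d.get("p_value"),
        p_adjusted=d.get("p_adjusted"),
        confidence_validation=d.get("confidence_validation"),
        reference_confidence=d.get("reference_confidence"),
    )


def ruleset_to_json(ruleset: RuleSetFile) -> str:
    ids = [r.rule_id for r in ruleset.rules]
    if len(set(ids)) != len(ids):
        raise ValueError("rule ids must be unique")
    doc = {
        "format_version": ruleset.format_version,
        "provenance": ruleset.provenance,
        "rules": [_rule_to_dict(r) for r in ruleset.rules],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def write_ruleset(rules: Sequence[AssociationRule], path: Union[str, Path],
                  provenance: Optional[dict] = None) -> RuleSetFile:
    ruleset = RuleSetFile(rules=list(rules), provenance=provenance or {})
    Path(path).write_text(ruleset_to_json(ruleset))
    return ruleset


def read_ruleset(path: Union[str, Path]) -> RuleSetFile:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != RULESET_FORMAT_VERSION:
        raise ValueError(
            f"rule-set format version {version!r} not supported "
            f"(expected {RULESET_FORMAT_VERSION})"
        )
    return RuleSetFile(
        rules=[_rule_from_dict(d) for d in doc["rules"]],
        provenance=doc.get("provenance", {}),
        format_version=version,
    )


def rule_display(rule: AssociationRule) -> str:
    """Flat rendering for review, e.g. ``"P07.3 => P59.0"``."""
    return f"{'+'.join(sorted(rule.lhs))} => {rule.rhs}"


def write_review_csv(rules: Sequence[AssociationRule],
                     path: Union[str, Path]) -> None:
    """One rule per row for expert review, LHS codes joined by ``+``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rule", "lhs", "rhs", "confidence", "support",
                         "support_count", "age_group", "level"])
        for r in rules:
            writer.writerow([rule_display(r), "+".join(sorted(r.lhs)),
                             r.rhs, f"{r.confidence:.6f}",
                             f"{r.support:.6f}", r.joint_count,
                             r.age_group, r.level])


# ----------------------------------------------------------------------
# Reports
# ----------------------------------------------------------------------

def write_filter_report(rows: Iterable[tuple[str, str, str]],
                        path: Union[str, Path]) -> None:
    """TSV of per-rule removals: stage, rule id, reason."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["stage", "rule_id", "reason"])
        for stage, rule_id, reason in rows:
            writer.writerow([stage, rule_id, reason])


def read_hospital_groups(path: Union[str, Path]) -> dict[str, str]:
    """Two-column CSV mapping hospital id to peer-group label."""
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].str.strip(), df[cols[1]].str.strip()))
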