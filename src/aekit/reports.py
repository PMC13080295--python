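"""Domain types for adverse-event reports, text normalization, and grouped splitting.

An adverse-event report for an infant incubator is modelled as a free-text
narrative plus a structured *element map* over six fields: three core fields
(occurrence date, abnormal condition of the device, follow-up risk-control
measures), two secondary fields (failure cause, triggered risk) and one
supplementary field for anything else captured from the original text.
Core fields carry weight 1.0 and secondary fields 0.8 in downstream scoring.

Datasets are split at the *report* level: every item derived from the same
report lands in the same partition, so no report leaks across train/test/
validation.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

CORE_FIELDS: tuple[str, ...] = (
    "occurrence_date",
    "abnormal_condition",
    "follow_up_measures",
)
SECONDARY_FIELDS: tuple[str, ...] = ("failure_cause", "triggered_risk")
SUPPLEMENTARY_FIELD: str = "additional_information"

DEFAULT_SPLIT_RATIOS: tuple[float, float, float] = (0.6, 0.3, 0.1)
PARTITIONS: tuple[str, ...] = ("train", "test", "validation")


@dataclass(frozen=True)
class ElementSchema:
    """The six-field report structure and per-category weights."""

    core_fields: tuple[str, ...] = CORE_FIELDS
    secondary_fields: tuple[str, ...] = SECONDARY_FIELDS
    supplementary_field: str = SUPPLEMENTARY_FIELD
    core_weight: float = 1.0
    secondary_weight: float = 0.8

    def __post_init__(self) -> None:
        if len(self.core_fields) != 3:
            raise ValueError("schema requires exactly 3 core fields")
        if len(self.secondary_fields) != 2:
            raise ValueError("schema requires exactly 2 secondary fields")
        names = [*self.core_fields, *self.secondary_fields, self.supplementary_field]
        if len(set(names)) != len(names):
            raise ValueError("field names must be unique across categories")
        if self.core_weight <= 0 or self.secondary_weight <= 0:
            raise ValueError("weights must be positive")

    @property
    def required_fields(self) -> tuple[str, ...]:
        """Core plus secondary fields — the m=5 fields scored for coverage."""
        return self.core_fields + self.secondary_fields

    @property
    def all_fields(self) -> tuple[str, ...]:
        return self.required_fields + (self.supplementary_field,)

    def weight(self, field_name: str) -> float:
        if field_name in self.core_fields:
            return self.core_weight
        if field_name in self.secondary_fields:
            return self.secondary_weight
        raise KeyError(f"{field_name!r} carries no coverage weight")

    @property
    def weights(self) -> dict[str, float]:
        return {f: self.weight(f) for f in self.required_fields}


DEFAULT_SCHEMA = ElementSchema()


def _check_elements(elements: Mapping[str, object], schema: ElementSchema) -> None:
    for key in elements:
        if key not in schema.all_fields:
            raise ValueError(f"unknown element field {key!r}")


@dataclass
class AEReport:
    """A reference adverse-event report: narrative plus structured elements."""

    report_id: str
    narrative: str
    elements: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)
    schema: ElementSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        _check_elements(self.elements, self.schema)
        for key, spans in self.elements.items():
            if any(not s for s in spans):
                raise ValueError(f"empty span in field {key!r}")


@dataclass
class PredictionRecord:
    """A model's structured answer for one report."""

    report_id: str
    elements: dict[str, str] = field(default_factory=dict)
    free_text: str = ""
    schema: ElementSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        _check_elements(self.elements, self.schema)


# ---------------------------------------------------------------------------
# Text normalization
# ---------------------------------------------------------------------------

_WS_RE = re.compile(r"\s+")


def normalize_text(
    s: str,
    dictionary: Mapping[str, str] | None = None,
    rules: Sequence[tuple[str, str]] | None = None,
) -> str:
    """Normalize a narrative span for matching.

    Applies, in order: Unicode compatibility folding (full-width digits,
    letters and punctuation to their half-width forms), the regex *rules*
    (pattern -> replacement, in the given order), dictionary substitution of
    variant terms to canonical terms (longest variant first, iterated to a
    fixed point), and whitespace collapsing.  Idempotent: normalizing twice
    equals normalizing once.
    """
    if not s:
        return ""
    out = unicodedata.normalize("NFKC", s)
    for pattern, repl in rules or ():
        out = re.sub(pattern, repl, out)
    if dictionary:
        # canonical terms participate in the scan and map to themselves, so
        # a variant embedded in an already-canonical span is never rewritten
        # and the substitution is idempotent by construction
        table = {v: v for v in dictionary.values()}
        table.update({k: v for k, v in dictionary.items() if k not in table})
        keys = sorted(table, key=len, reverse=True)
        pat = re.compile("|".join(re.escape(v) for v in keys))
        out = pat.sub(lambda m: table[m.group(0)], out)
    out = _WS_RE.sub(" ", out).strip()
    return out


# ---------------------------------------------------------------------------
# Report-level dataset splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitAssignment:
    """A report-id -> partition assignment under the 60/30/10 rule."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def partition(self, name: str) -> list[str]:
        return [rid for rid, p in self.assignment.items() if p == name]

    def sizes(self, item_to_report: Mapping[str, str] | None = None) -> dict[str, int]:
        """Partition sizes in items (or in reports if no item map given)."""
        counts = dict.fromkeys(PARTITIONS, 0)
        if item_to_report is None:
            for p in self.assignment.values():
                counts[p] += 1
        else:
            for rid in item_to_report.values():
                counts[self.assignment[rid]] += 1
        return counts

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["report_id", "partition"])
            for rid, p in self.assignment.items():
                w.writerow([rid, p])


def _round_half_away(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_targets(n: int, ratios: tuple[float, float, float] = DEFAULT_SPLIT_RATIOS) -> tuple[int, int, int]:
    """Item-count targets: train and test rounded half-away-from-zero, the
    remainder to validation.  This is the convention under which 4095 items
    yield 2457/1229/409 and 1488 yield 893/446/149."""
    train = _round_half_away(ratios[0] * n)
    test = _round_half_away(ratios[1] * n)
    return train, test, n - train - test


def split_dataset(
    item_to_report: Mapping[str, str],
    ratios: tuple[float, float, float] = DEFAULT_SPLIT_RATIOS,
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole report groups to train/test/validation.

    Groups are shuffled by *seed*, stably sorted largest-first, and each is
    placed greedily in the partition with the greatest remaining item need
    relative to the 60/30/10 targets.  With singleton groups this reproduces
    the targets exactly; with multi-item groups it minimizes the deviation
    greedily.  Deterministic given seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    groups: dict[str, int] = {}
    for rid in item_to_report.values():
        groups[rid] = groups.get(rid, 0) + 1
    if len(groups) < len(PARTITIONS):
        raise ValueError(
            f"cannot split {len(groups)} report groups into {len(PARTITIONS)} partitions"
        )
    n_items = len(item_to_report)
    targets = dict(zip(PARTITIONS, split_targets(n_items, ratios)))

    import numpy as np

    rng = np.random.default_rng(seed)
    rids = list(groups)
    rng.shuffle(rids)
    rids.sort(key=lambda r: -groups[r])  # stable: shuffle breaks ties

    filled = dict.fromkeys(PARTITIONS, 0)
    assignment: dict[str, str] = {}
    for rid in rids:
        size = groups[rid]
        best = max(PARTITIONS, key=lambda p: (targets[p] - filled[p], -PARTITIONS.index(p)))
        assignment[rid] = best
        filled[best] += size
    return SplitAssignment(assignment=assignment, ratios=tuple(ratios), seed=seed)


# ---------------------------------------------------------------------------
# JSON Lines / CSV I/O
# ---------------------------------------------------------------------------


def read_reports_jsonl(path: str | Path, schema: ElementSchema = DEFAULT_SCHEMA) -> list[AEReport]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                AEReport(
                    report_id=obj["report_id"],
                    narrative=obj.get("narrative", ""),
                    elements={k: list(v) for k, v in obj.get("elements", {}).items()},
                    metadata=obj.get("metadata", {}),
                    schema=schema,
                )
            )
    return out


def write_reports_jsonl(reports: Iterable[AEReport], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "narrative": r.narrative,
                        "elements": r.elements,
                        "metadata": r.metadata,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_predictions_jsonl(
    path: str | Path, schema: ElementSchema = DEFAULT_SCHEMA
) -> list[PredictionRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                PredictionRecord(
                    report_id=obj["report_id"],
                    elements=dict(obj.get("elements", {})),
                    free_text=obj.get("free_text", ""),
                    schema=schema,
                )
            )
    return out


def write_predictions_jsonl(preds: Iterable[PredictionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in preds:
            fh.write(
                json.dumps(
                    {
                        "report_id": p.report_id,
                        "elements": p.elements,
                        "free_text": p.free_text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_term_dictionary(path: str | Path) -> dict[str, str]:
    """Two-column CSV (variant, canonical) -> mapping."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh):
            if len(row) >= 2 and row[0] != "variant":
                out[row[0]] = row[1]
    return out
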