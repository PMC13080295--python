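"""Bespoke scoring for incubator adverse-event reports.

Implements the hierarchical element matcher (exact containment, then fuzzy
edit-distance similarity above a threshold), the element recall rate over the
three core fields, the information-density index (IDIAE) with its redundancy/
terminology correction factor

    beta = 1 + alpha * (N_red / 10) + gamma * M_error,

the six-item risk recall, and the comparative arithmetic (relative
improvement, long-text attenuation) used when ranking models.  BLEU-4 and
ROUGE-L are provided as standard surface metrics.

All matching operates on normalized text (see :mod:`aekit.reports`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import edlib

from .reports import DEFAULT_SCHEMA, AEReport, ElementSchema, PredictionRecord, normalize_text

# ---------------------------------------------------------------------------
# Hierarchical element matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchOutcome:
    matched: bool
    mode: Literal["exact", "fuzzy", "none"]
    similarity: float

    def __post_init__(self) -> None:
        if self.mode == "exact" and not self.matched:
            raise ValueError("exact mode implies matched")
        if self.mode == "none" and self.matched:
            raise ValueError("mode none implies not matched")


def edit_similarity(a: str, b: str, method: Literal["max_len", "two_sided"] = "max_len") -> float:
    """Edit-distance similarity ratio in [0, 1].

    ``max_len``: 1 - Levenshtein(a, b) / max(|a|, |b|) (the default).
    ``two_sided``: 1 - Levenshtein(a, b) / (|a| + |b|), a gentler ratio.
    """
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    denom = max(len(a), len(b)) if method == "max_len" else len(a) + len(b)
    return max(0.0, 1.0 - dist / denom)


def match_element(
    ref_text: str,
    pred_text: str,
    threshold: float = 0.8,
    similarity_method: Literal["max_len", "two_sided"] = "max_len",
) -> MatchOutcome:
    """Hierarchical match of a reference span against a predicted span.

    Exact when the (already normalized) reference is contained in the
    prediction; otherwise fuzzy iff the edit-distance similarity *strictly*
    exceeds *threshold*.  The boundary value is a non-match.
    """
    if not ref_text:
        raise ValueError("reference text must be non-empty")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    sim = edit_similarity(ref_text, pred_text, similarity_method)
    if pred_text and ref_text in pred_text:
        return MatchOutcome(matched=True, mode="exact", similarity=sim)
    if sim > threshold:
        return MatchOutcome(matched=True, mode="fuzzy", similarity=sim)
    return MatchOutcome(matched=False, mode="none", similarity=sim)


# ---------------------------------------------------------------------------
# Element recall rate (ERR)
# ---------------------------------------------------------------------------


def _ref_span(report: AEReport, field_name: str) -> str:
    spans = report.elements.get(field_name, [])
    return " ".join(spans)


def element_recall_rate(
    refs: Sequence[AEReport],
    preds: Sequence[PredictionRecord],
    schema: ElementSchema = DEFAULT_SCHEMA,
    threshold: float = 0.8,
) -> float:
    """Mean over reports of the fraction of core elements recovered.

    Per report, each of the three core fields contributes 1/3 when the
    reference span matches the predicted span (hierarchically).  A missing
    predicted field counts as a non-match; an unmatched report_id is an error.
    """
    pred_by_id = {p.report_id: p for p in preds}
    if len(pred_by_id) != len(preds):
        raise ValueError("duplicate report_id among predictions")
    per_report = []
    for ref in refs:
        if ref.report_id not in pred_by_id:
            raise KeyError(f"no prediction for report {ref.report_id!r}")
        pred = pred_by_id[ref.report_id]
        hits = 0
        for k in schema.core_fields:
            ref_text = _ref_span(ref, k)
            pred_text = pred.elements.get(k, "")
            if not ref_text:
                continue  # nothing to recall for this field
            if pred_text and match_element(ref_text, pred_text, threshold).matched:
                hits += 1
        per_report.append(hits / len(schema.core_fields))
    if not per_report:
        raise ValueError("no reports to score")
    return float(sum(per_report) / len(per_report))


# ---------------------------------------------------------------------------
# IDIAE: information density with correction factor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IDIAEConfig:
    alpha: float = 0.1
    gamma: float = 0.2
    core_weight: float = 1.0
    secondary_weight: float = 0.8
    normalization_mode: Literal["weight_sum", "field_count"] = "weight_sum"
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be non-negative")
        if self.core_weight <= 0 or self.secondary_weight <= 0:
            raise ValueError("weights must be positive")


@dataclass(frozen=True)
class IDIAEBreakdown:
    coverage: dict[str, int]
    m: int
    n_red: int
    m_error: int
    beta: float
    score: float

    def __post_init__(self) -> None:
        if self.beta < 1.0:
            raise ValueError("beta must be >= 1")


def correction_factor(n_red: int, m_error: int, config: IDIAEConfig = IDIAEConfig()) -> float:
    """beta = 1 + alpha * (N_red / 10) + gamma * M_error."""
    if n_red < 0 or m_error < 0:
        raise ValueError("penalty counts must be non-negative")
    return 1.0 + config.alpha * (n_red / 10.0) + config.gamma * m_error


def count_term_errors(
    text: str,
    term_lexicon: Iterable[str],
    threshold: float = 0.8,
) -> int:
    """Count near-miss terminology: tokens fuzzy-similar to a canonical term
    (similarity > threshold) but not identical to any canonical term."""
    terms = list(term_lexicon)
    canon = set(terms)
    errors = 0
    for token in text.split():
        if token in canon:
            continue
        for t in terms:
            if edit_similarity(token, t) > threshold:
                errors += 1
                break
    return errors


def count_redundant_chars(
    pred: PredictionRecord,
    recognized_spans: Iterable[str],
) -> int:
    """Characters of the free text assignable to no recognized field span.

    Greedy: every occurrence of each recognized span is blanked out of the
    free text; remaining non-whitespace characters count as redundant.
    """
    residue = pred.free_text
    for span in sorted((s for s in recognized_spans if s), key=len, reverse=True):
        residue = residue.replace(span, "")
    return sum(1 for ch in residue if not ch.isspace())


def idiae(
    ref: AEReport,
    pred: PredictionRecord,
    config: IDIAEConfig = IDIAEConfig(),
    term_lexicon: Iterable[str] = (),
    schema: ElementSchema = DEFAULT_SCHEMA,
    n_red: int | None = None,
    m_error: int | None = None,
) -> IDIAEBreakdown:
    """Information-density score of a predicted report against its reference.

    Coverage C_j is 1 iff required field j matches hierarchically; the score
    is sum_j(w_j * C_j) divided by (sum_j w_j) * beta under ``weight_sum``
    normalization, or by m * beta under ``field_count``.  ``n_red`` and
    ``m_error`` may be supplied directly (e.g. synthetic ground truth);
    otherwise they are detected from the free text.
    """
    required = schema.required_fields
    ref_spans = {k: _ref_span(ref, k) for k in required}
    if not any(ref_spans.values()):
        raise ValueError("reference report has no required-field content")

    weights = {
        k: (config.core_weight if k in schema.core_fields else config.secondary_weight)
        for k in required
    }
    coverage: dict[str, int] = {}
    for k in required:
        pred_text = pred.elements.get(k, "")
        if ref_spans[k] and pred_text:
            coverage[k] = int(match_element(ref_spans[k], pred_text, config.threshold).matched)
        else:
            coverage[k] = 0

    if n_red is None:
        n_red = count_redundant_chars(pred, pred.elements.values())
    if m_error is None:
        m_error = count_term_errors(pred.free_text, term_lexicon, config.threshold)
    beta = correction_factor(n_red, m_error, config)

    numerator = sum(weights[k] * coverage[k] for k in required)
    if config.normalization_mode == "weight_sum":
        denominator = sum(weights.values()) * beta
    else:
        denominator = len(required) * beta
    return IDIAEBreakdown(
        coverage=coverage,
        m=len(required),
        n_red=n_red,
        m_error=m_error,
        beta=beta,
        score=numerator / denominator,
    )


# ---------------------------------------------------------------------------
# Risk recall over the six-item safety list
# ---------------------------------------------------------------------------

SAFETY_ITEMS: tuple[str, ...] = (
    "phenomenon_identification",
    "safety_risk_identification",
    "immediate_patient_safety_measures",
    "equipment_disposal_measures",
    "reporting_measures",
    "risk_cause_localization",
)


@dataclass(frozen=True)
class SafetyItemList:
    items: tuple[str, ...] = SAFETY_ITEMS

    def __post_init__(self) -> None:
        if len(self.items) != 6:
            raise ValueError("the safety item list has exactly 6 items")


def risk_recall(
    identified: Sequence[Iterable[str]],
    item_list: SafetyItemList = SafetyItemList(),
) -> tuple[float, float]:
    """(mean recall, mean item count) over reports.

    Per report the recall is |identified| / 6; the mean recall therefore
    equals the mean identified-item count divided by 6 exactly.
    """
    valid = set(item_list.items)
    counts = []
    for items in identified:
        s = set(items)
        unknown = s - valid
        if unknown:
            raise ValueError(f"unknown safety items: {sorted(unknown)}")
        counts.append(len(s))
    if not counts:
        raise ValueError("no reports")
    mean_count = sum(counts) / len(counts)
    return mean_count / len(item_list.items), mean_count


# ---------------------------------------------------------------------------
# Comparative arithmetic
# ---------------------------------------------------------------------------


def _one_decimal(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def relative_improvement(value: float, baseline: float) -> float:
    """100 * (value - baseline) / baseline, to one decimal."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return _one_decimal(100.0 * (value - baseline) / baseline)


def attenuation(short_score: float, long_score: float) -> float:
    """Percent drop from short-text to long-text performance, to one decimal."""
    if short_score <= 0:
        raise ValueError("short-text score must be positive")
    return _one_decimal(100.0 * (short_score - long_score) / short_score)


# ---------------------------------------------------------------------------
# Surface metrics: BLEU-4 and ROUGE-L (standard definitions)
# ---------------------------------------------------------------------------


def _ngram_counts(tokens: Sequence[str], n: int) -> dict[tuple[str, ...], int]:
    out: dict[tuple[str, ...], int] = {}
    for i in range(len(tokens) - n + 1):
        g = tuple(tokens[i : i + n])
        out[g] = out.get(g, 0) + 1
    return out


def bleu4(ref_text: str, pred_text: str, smoothing: bool = False) -> float:
    """Sentence BLEU with uniform 1..4-gram weights and brevity penalty.

    With smoothing off, any zero n-gram precision gives BLEU 0; with
    smoothing on, zero counts are floored by add-one on higher-order n-grams.
    """
    ref = ref_text.split()
    pred = pred_text.split()
    if not pred:
        return 0.0
    log_p = 0.0
    for n in range(1, 5):
        ref_counts = _ngram_counts(ref, n)
        pred_counts = _ngram_counts(pred, n)
        clipped = sum(min(c, ref_counts.get(g, 0)) for g, c in pred_counts.items())
        total = max(1, len(pred) - n + 1)
        if clipped == 0:
            if not smoothing:
                return 0.0
            clipped, total = 1, total + 1
        log_p += 0.25 * math.log(clipped / total)
    bp = 1.0 if len(pred) >= len(ref) else math.exp(1.0 - len(ref) / max(1, len(pred)))
    return bp * math.exp(log_p)


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_l(ref_text: str, pred_text: str) -> float:
    """ROUGE-L F1: harmonic mean of LCS-based precision and recall."""
    ref = ref_text.split()
    pred = pred_text.split()
    lcs = _lcs_len(ref, pred)
    if lcs == 0:
        return 0.0
    p = lcs / len(pred)
    r = lcs / len(ref)
    return 2 * p * r / (p + r)


def surface_metrics(ref_text: str, pred_text: str, smoothing: bool = False) -> dict[str, float]:
    if not ref_text or not pred_text:
        raise ValueError("texts must be non-empty")
    return {"bleu4": bleu4(ref_text, pred_text, smoothing), "rouge_l": rouge_l(ref_text, pred_text)}


# ---------------------------------------------------------------------------
# Score table output
# ---------------------------------------------------------------------------


def write_score_csv(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
) -> None:
    """One row per report (report_id, err, idiae, beta, n_red, m_error[,
    risk_recall]) plus a trailing mean-summary row."""
    if not rows:
        raise ValueError("no rows to write")
    fields = list(rows[0].keys())
    numeric = [f for f in fields if f != "report_id"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for row in rows:
            w.writerow(row)
        summary: dict[str, object] = {"report_id": "MEAN"}
        for f in numeric:
            vals = [float(r[f]) for r in rows if r.get(f) is not None]
            summary[f] = round(sum(vals) / len(vals), 6) if vals else ""
        w.writerow(summary)
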