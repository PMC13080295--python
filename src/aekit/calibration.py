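"""Agreement statistics used to calibrate the information-density score
against blinded expert ratings, plus the annotation quality-control gate.

The headline statistic is a two-way random-effects, single-measure,
absolute-agreement intraclass correlation (ICC(A,1) in McGraw & Wong's
nomenclature), computed from ANOVA mean squares with an F-distribution
confidence interval.  A grid search over the redundancy and terminology
penalty weights (alpha, gamma) re-scores every report at each grid cell and
reports the ICC against the expert panel, returning the argmax cell.

The QC gate mirrors a batch-release rule for double-blind annotation:
a batch ships only if the arbitrated "significant drift" rate is at most 5%,
with inter-annotator kappa reported against a 0.78 floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .metrics import IDIAEBreakdown, IDIAEConfig, correction_factor
from .reports import DEFAULT_SCHEMA, ElementSchema

QC_LABELS: tuple[str, ...] = ("perfect_equivalence", "minor_drift", "significant_drift")


@dataclass
class RaterMatrix:
    """n_subjects x n_raters score matrix, optionally with categorical grades."""

    scores: np.ndarray
    grades: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-dimensional (subjects x raters)")
        n, k = self.scores.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("missing or non-finite cells are not allowed")


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False
    form: str = "ICC(A,1): two-way random, single measure, absolute agreement"


def icc(matrix: RaterMatrix, confidence: float = 0.95) -> ICCResult:
    """Two-way random-effects, single-measure, absolute-agreement ICC.

    Computed from the two-way ANOVA mean squares (rows = subjects,
    columns = raters); the confidence interval follows the F-distribution
    construction of McGraw & Wong.  Zero between-subject variance returns 0
    with the degenerate flag set.
    """
    x = matrix.scores
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if msr <= 1e-12:
        return ICCResult(0.0, 0.0, 0.0, degenerate=True)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) <= 1e-12:
        return ICCResult(0.0, 0.0, 0.0, degenerate=True)
    r = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 1e-12 and msc <= 1e-12:
        # perfect agreement: interval collapses
        return ICCResult(float(r), float(r), float(r))
    a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if not np.isfinite(a):
        return ICCResult(float(r), float(r), float(r))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(float(r), float(lower), float(upper))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def cohen_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Chance-corrected categorical agreement with marginal-product expectation."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    labels = sorted(set(a) | set(b))
    if len(labels) < 2:
        raise ValueError("expected agreement is 1 for a single shared category")
    return float(cohen_kappa_score(list(a), list(b), labels=labels))


def grades_from_scores(
    scores: Sequence[float],
    cuts: tuple[float, float] | None = None,
    labels: tuple[str, str, str] = ("low", "medium", "high"),
) -> list[str]:
    """Discretize continuous scores into 3 grades.

    Default cut points are the tertiles of the given distribution; fixed cut
    points may be supplied for comparability across panels.
    """
    s = np.asarray(scores, dtype=float)
    if cuts is None:
        cuts = (float(np.quantile(s, 1 / 3)), float(np.quantile(s, 2 / 3)))
    lo, hi = cuts
    return [labels[0] if v <= lo else labels[1] if v <= hi else labels[2] for v in s]


# ---------------------------------------------------------------------------
# alpha/gamma grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSearchResult:
    alpha_grid: tuple[float, ...]
    gamma_grid: tuple[float, ...]
    icc_matrix: np.ndarray  # len(alpha_grid) x len(gamma_grid)
    best_alpha: float
    best_gamma: float
    best_icc: float


def _rescore(bd: IDIAEBreakdown, alpha: float, gamma: float, config: IDIAEConfig,
             schema: ElementSchema) -> float:
    weights = {
        k: (config.core_weight if k in schema.core_fields else config.secondary_weight)
        for k in schema.required_fields
    }
    numerator = sum(weights[k] * bd.coverage.get(k, 0) for k in schema.required_fields)
    beta = correction_factor(bd.n_red, bd.m_error, IDIAEConfig(alpha=alpha, gamma=gamma))
    if config.normalization_mode == "weight_sum":
        denom = sum(weights.values()) * beta
    else:
        denom = len(schema.required_fields) * beta
    return numerator / denom


def grid_search_weights(
    breakdowns: Sequence[IDIAEBreakdown],
    expert_scores: np.ndarray,
    alpha_grid: Sequence[float],
    gamma_grid: Sequence[float],
    config: IDIAEConfig = IDIAEConfig(),
    schema: ElementSchema = DEFAULT_SCHEMA,
) -> GridSearchResult:
    """ICC between re-scored IDIAE and the expert panel for every (alpha, gamma).

    Each grid cell recomputes the index on every report using that cell's
    penalty weights (coverage and penalty counts are fixed per report), stacks
    the index column against the expert columns, and evaluates the ICC.
    Returns the full matrix and the argmax cell.
    """
    if not alpha_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    experts = np.asarray(expert_scores, dtype=float)
    if experts.ndim != 2 or experts.shape[1] < 2:
        raise ValueError("expert_scores must be n_subjects x n_raters with >= 2 raters")
    if experts.shape[0] != len(breakdowns):
        raise ValueError("one expert row per report is required")

    out = np.empty((len(alpha_grid), len(gamma_grid)))
    for i, a in enumerate(alpha_grid):
        for j, g in enumerate(gamma_grid):
            scores = np.array([_rescore(bd, a, g, config, schema) for bd in breakdowns])
            mat = np.column_stack([scores, experts])
            out[i, j] = icc(RaterMatrix(mat)).estimate
    best_flat = int(np.argmax(out))
    bi, bj = divmod(best_flat, len(gamma_grid))
    return GridSearchResult(
        alpha_grid=tuple(alpha_grid),
        gamma_grid=tuple(gamma_grid),
        icc_matrix=out,
        best_alpha=float(alpha_grid[bi]),
        best_gamma=float(gamma_grid[bj]),
        best_icc=float(out[bi, bj]),
    )


# ---------------------------------------------------------------------------
# Annotation QC gate
# ---------------------------------------------------------------------------


@dataclass
class QCBatch:
    """Double-blind annotation triples (annotator A, annotator B, arbitrated)."""

    items: list[tuple[str, str, str]] = field(default_factory=list)
    batch_size: int = 100

    def __post_init__(self) -> None:
        for a, b, arb in self.items:
            for lab in (a, b, arb):
                if lab not in QC_LABELS:
                    raise ValueError(f"unknown QC label {lab!r}")


@dataclass(frozen=True)
class QCDecision:
    release: bool
    drift_rate: float
    kappa: float | None
    kappa_below_floor: bool
    n_items: int


def qc_gate(batch: QCBatch, max_drift: float = 0.05, kappa_floor: float = 0.78) -> QCDecision:
    """Release a batch iff the arbitrated significant-drift rate is <= max_drift.

    Also reports the inter-annotator kappa on the (A, B) labels with a flag
    when it falls below the training floor.  Kappa is None when the batch is
    degenerate (a single shared category).
    """
    if not batch.items:
        raise ValueError("empty batch")
    n = len(batch.items)
    drift = sum(1 for _, _, arb in batch.items if arb == "significant_drift") / n
    a = [t[0] for t in batch.items]
    b = [t[1] for t in batch.items]
    try:
        kap: float | None = cohen_kappa(a, b)
    except ValueError:
        kap = 1.0 if a == b else None
    below = kap is not None and kap < kappa_floor
    return QCDecision(
        release=drift <= max_drift,
        drift_rate=drift,
        kappa=kap,
        kappa_below_floor=below,
        n_items=n,
    )
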