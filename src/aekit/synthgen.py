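"""Seeded generators for every input the rest of the package consumes.

The real monitoring-system corpus is confidential, so this module emulates
its *structure* with ground truth attached: six-field adverse-event reports
with controlled element dropout, injected redundant characters (the exact
count recorded as the true N_red) and injected near-miss terminology (true
M_error recorded); clause-numbered regulatory documents with paraphrase
queries and gold clause ids; token corpora with long-range causal-chain
motifs for adapter training; and multi-rater expert scores driven by a known
latent quality.  Every generator is a pure function of its spec and seed.

Phrase banks ship in English (default, for test readability) and Chinese
(to exercise width normalization and character-level edit distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .calibration import RaterMatrix, grades_from_scores
from .metrics import IDIAEConfig, correction_factor
from .reports import DEFAULT_SCHEMA, AEReport, ElementSchema, PredictionRecord
from .retrieval import RegDocument, parse_document

# ---------------------------------------------------------------------------
# Phrase banks
# ---------------------------------------------------------------------------

PHRASES_EN = {
    "abnormal_condition": [
        "temperature alarm triggered continuously during operation",
        "skin temperature probe reading drifted from the set point",
        "humidity control failed and condensation formed in the hood",
        "air circulation fan stalled with an audible clack-clack sound",
        "display panel froze and stopped updating the air temperature",
        "oxygen concentration sensor reported implausible values",
        "heater element failed to reach the configured temperature",
        "door latch did not engage and the canopy seal leaked",
    ],
    "failure_cause": [
        "aging of the heating element connector",
        "calibration drift of the skin temperature probe",
        "loose wiring harness behind the control board",
        "blocked air filter reducing circulation",
        "firmware fault in the alarm management module",
        "worn fan bearing causing intermittent stalls",
    ],
    "triggered_risk": [
        "risk of neonatal hypothermia",
        "risk of overheating and skin injury",
        "risk of delayed alarm response by nursing staff",
        "risk of inaccurate thermal regulation",
        "risk of hypoxia from misreported oxygen levels",
    ],
    "follow_up_measures": [
        "immediately transferred the infant to a backup incubator",
        "monitored the infant's temperature and pulse oxygen saturation",
        "took the device out of service and reported to the equipment department",
        "replaced the faulty probe and revalidated the calibration",
        "notified the manufacturer and filed an adverse event report",
        "quarantined the unit pending engineering inspection",
    ],
    "additional_information": [
        "equipment model YP-90B with five years of service",
        "device located in the neonatal intensive care unit",
        "maintenance record shows the last inspection six months ago",
        "root cause analysis of the fault is ongoing",
        "similar alarms were recorded twice in the preceding week",
    ],
}

PHRASES_ZH = {
    "abnormal_condition": [
        "运行期间温度报警持续触发",
        "皮肤温度探头读数偏离设定值",
        "湿度控制失效罩内出现冷凝",
        "风机卡滞并发出咔哒咔哒异响",
        "显示面板冻结不再更新箱温",
    ],
    "failure_cause": [
        "加热元件接插件老化",
        "皮肤温度探头校准漂移",
        "控制板后线束松动",
        "空气过滤器堵塞导致循环不足",
    ],
    "triggered_risk": [
        "新生儿低体温风险",
        "过热及皮肤损伤风险",
        "护理人员报警响应延迟风险",
    ],
    "follow_up_measures": [
        "立即将患儿转移至备用培养箱",
        "监测患儿体温与脉搏血氧饱和度",
        "停用设备并上报设备科检修",
        "更换故障探头并重新校准",
    ],
    "additional_information": [
        "设备型号YP-90B已使用五年",
        "设备位于新生儿重症监护病房",
        "故障根本原因分析正在进行",
    ],
}

# canonical domain terms used for near-miss terminology injection
TERM_LEXICON_EN = [
    "incubator",
    "hypothermia",
    "calibration",
    "saturation",
    "thermistor",
    "ventilation",
]

_GARBAGE = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class ReportGroundTruth:
    """Exact bookkeeping of what was injected into one prediction."""

    report_id: str
    coverage: dict[str, int]
    n_red: int
    m_error: int
    latent_quality: float


@dataclass(frozen=True)
class ReportGenSpec:
    n_reports: int = 200
    dropout: dict[str, float] = field(default_factory=dict)  # field -> P(drop)
    redundancy_rate: float = 20.0  # expected irrelevant characters per report
    term_error_rate: float = 1.0  # expected near-miss terms per report
    language: Literal["en", "zh"] = "en"
    date_range: tuple[int, int] = (2021, 2024)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.dropout.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("dropout probabilities must lie in [0, 1]")
        if self.redundancy_rate < 0 or self.term_error_rate < 0:
            raise ValueError("rates must be non-negative")


def _random_date(rng: np.random.Generator, years: tuple[int, int]) -> str:
    y = int(rng.integers(years[0], years[1] + 1))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    return f"{y:04d}-{m:02d}-{d:02d}"


def _perturb_term(term: str, rng: np.random.Generator) -> str:
    """One-character near miss: similarity > 0.8 for terms of length >= 6."""
    i = int(rng.integers(0, len(term)))
    repl = _GARBAGE[int(rng.integers(0, len(_GARBAGE)))]
    while repl == term[i]:
        repl = _GARBAGE[int(rng.integers(0, len(_GARBAGE)))]
    return term[:i] + repl + term[i + 1 :]


def gen_reports(
    spec: ReportGenSpec = ReportGenSpec(),
    schema: ElementSchema = DEFAULT_SCHEMA,
    idiae_config: IDIAEConfig = IDIAEConfig(),
) -> tuple[list[AEReport], list[PredictionRecord], list[ReportGroundTruth]]:
    """Paired reference reports and controlled-degradation predictions.

    References populate all six fields from the phrase banks.  Predictions
    copy the reference elements, drop whole fields with the per-field dropout
    probability, append Poisson(redundancy_rate) irrelevant characters to the
    free text, and inject Poisson(term_error_rate) near-miss terms.  The
    latent quality recorded per report is the information-density score
    implied by the true coverage and injected counts.
    """
    banks = PHRASES_EN if spec.language == "en" else PHRASES_ZH
    for k, v in banks.items():
        if not v:
            raise ValueError(f"empty phrase bank for {k}")
    rng = np.random.default_rng(spec.seed)
    refs: list[AEReport] = []
    preds: list[PredictionRecord] = []
    truths: list[ReportGroundTruth] = []

    weights = schema.weights
    weight_sum = sum(weights.values())

    for i in range(spec.n_reports):
        rid = f"R{i:05d}"
        elements: dict[str, list[str]] = {
            "occurrence_date": [_random_date(rng, spec.date_range)]
        }
        for fname in (*schema.required_fields, schema.supplementary_field):
            if fname == "occurrence_date":
                continue
            bank = banks[fname]
            elements[fname] = [bank[int(rng.integers(0, len(bank)))]]
        narrative = " ".join(s for spans in elements.values() for s in spans)
        refs.append(
            AEReport(report_id=rid, narrative=narrative, elements=elements, schema=schema)
        )

        pred_elements: dict[str, str] = {}
        coverage: dict[str, int] = {}
        for fname in schema.required_fields:
            drop = rng.random() < spec.dropout.get(fname, 0.0)
            coverage[fname] = 0 if drop else 1
            if not drop:
                pred_elements[fname] = " ".join(elements[fname])
        pred_elements[schema.supplementary_field] = " ".join(
            elements[schema.supplementary_field]
        )

        n_red = int(rng.poisson(spec.redundancy_rate))
        m_error = int(rng.poisson(spec.term_error_rate))
        free_parts = [v for v in pred_elements.values()]
        if n_red:
            free_parts.append(
                "".join(_GARBAGE[int(rng.integers(0, len(_GARBAGE)))] for _ in range(n_red))
            )
        for _ in range(m_error):
            term = TERM_LEXICON_EN[int(rng.integers(0, len(TERM_LEXICON_EN)))]
            free_parts.append(_perturb_term(term, rng))
        preds.append(
            PredictionRecord(
                report_id=rid,
                elements=pred_elements,
                free_text=" ".join(free_parts),
                schema=schema,
            )
        )

        beta = correction_factor(n_red, m_error, idiae_config)
        numerator = sum(weights[f] * coverage[f] for f in schema.required_fields)
        latent = numerator / (weight_sum * beta)
        truths.append(
            ReportGroundTruth(
                report_id=rid,
                coverage=coverage,
                n_red=n_red,
                m_error=m_error,
                latent_quality=latent,
            )
        )
    return refs, preds, truths


def gen_study_reports(
    n_high: int = 26,
    n_medium: int = 28,
    n_low: int = 26,
    seed: int = 0,
) -> tuple[list[AEReport], list[PredictionRecord], list[ReportGroundTruth]]:
    """A quality-stratified report set shaped like an 80-report expert study.

    High / medium / low strata differ in element dropout and injected noise,
    so the latent quality spans the full range and agreement statistics
    against simulated raters are informative.
    """
    strata = [
        (n_high, {}, 2.0, 0.1),
        (n_medium, {"failure_cause": 0.5, "triggered_risk": 0.5}, 15.0, 0.8),
        (
            n_low,
            {
                "occurrence_date": 0.4,
                "abnormal_condition": 0.4,
                "follow_up_measures": 0.4,
                "failure_cause": 0.8,
                "triggered_risk": 0.8,
            },
            40.0,
            2.0,
        ),
    ]
    refs: list[AEReport] = []
    preds: list[PredictionRecord] = []
    truths: list[ReportGroundTruth] = []
    for si, (n, dropout, red, terr) in enumerate(strata):
        spec = ReportGenSpec(
            n_reports=n,
            dropout=dropout,
            redundancy_rate=red,
            term_error_rate=terr,
            seed=seed * 10 + si,
        )
        r, p, t = gen_reports(spec)
        prefix = f"S{si}"
        for rr, pp, tt in zip(r, p, t):
            rid = prefix + rr.report_id
            refs.append(replace_report_id(rr, rid))
            preds.append(
                PredictionRecord(
                    report_id=rid, elements=pp.elements, free_text=pp.free_text, schema=pp.schema
                )
            )
            truths.append(replace(tt, report_id=rid))
    return refs, preds, truths


def replace_report_id(report: AEReport, new_id: str) -> AEReport:
    return AEReport(
        report_id=new_id,
        narrative=report.narrative,
        elements=report.elements,
        metadata=report.metadata,
        schema=report.schema,
    )


# ---------------------------------------------------------------------------
# Regulatory corpus with gold-labelled QA pairs
# ---------------------------------------------------------------------------

THEME_WORDS = [
    "registration", "manufacturer", "distributor", "monitoring", "surveillance",
    "incubator", "neonatal", "thermal", "alarm", "calibration", "sterilization",
    "labelling", "traceability", "recall", "inspection", "clinical", "evaluation",
    "sampling", "reporting", "timeline", "penalty", "license", "filing", "audit",
    "risk", "classification", "quality", "maintenance", "training", "records",
    "importer", "exporter", "standards", "certification", "complaint", "investigation",
    "corrective", "preventive", "suspension", "revocation", "disclosure", "archive",
    "supervision", "enforcement", "liability", "compensation", "warning", "notice",
]

_CLAUSE_SCAFFOLDS = [
    "The responsible party shall ensure that {w} procedures are established and maintained.",
    "Where {w} requirements are not met, the authority may order corrective action.",
    "Records concerning {w} shall be retained for no less than five years.",
    "Any entity engaged in {w} activities shall file the prescribed documents.",
    "Failure to comply with {w} obligations results in the penalties of this chapter.",
]

_QUERY_SCAFFOLDS = [
    "What does the regulation require about {w}?",
    "Which obligations apply to {w} under these measures?",
    "How long and in what form must {w} duties be fulfilled?",
    "Who is responsible for {w} and what happens on non-compliance?",
]


@dataclass(frozen=True)
class CorpusGenSpec:
    n_docs: int = 5
    clauses_per_doc: int = 20
    n_qa_pairs: int = 50
    words_per_clause: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.n_docs, self.clauses_per_doc, self.n_qa_pairs, self.words_per_clause):
            if v < 1:
                raise ValueError("all counts must be >= 1")


@dataclass(frozen=True)
class QAPair:
    query: str
    gold_doc_id: str
    gold_clause: str  # clause number within the document

    @property
    def gold_id(self) -> tuple[str, str]:
        return (self.gold_doc_id, self.gold_clause)


def gen_regulatory_corpus(
    spec: CorpusGenSpec = CorpusGenSpec(),
) -> tuple[list[RegDocument], list[QAPair]]:
    """Clause-numbered documents plus paraphrase queries with gold clause ids.

    Each clause combines a scaffold sentence (shared across the corpus, which
    makes surface matching deliberately ambiguous) with a few theme content
    words; each query paraphrases exactly one clause by re-using its content
    words inside a different scaffold.  Deterministic given seed.
    """
    total = spec.n_docs * spec.clauses_per_doc
    if spec.n_qa_pairs > total:
        raise ValueError("cannot ask for more QA pairs than clauses")
    rng = np.random.default_rng(spec.seed)
    docs: list[RegDocument] = []
    clause_words: dict[tuple[str, str], list[str]] = {}
    seen_subsets: set[frozenset[str]] = set()
    for d in range(spec.n_docs):
        doc_id = f"reg{d:02d}"
        lines = [f"Administrative Measures No. {d + 1} on Medical Device Surveillance"]
        for c in range(1, spec.clauses_per_doc + 1):
            # each clause gets a unique content-word subset: the corpus is
            # separable by construction even though scaffolds repeat
            for _ in range(1000):
                words = [
                    THEME_WORDS[i]
                    for i in rng.choice(len(THEME_WORDS), spec.words_per_clause, replace=False)
                ]
                if frozenset(words) not in seen_subsets:
                    seen_subsets.add(frozenset(words))
                    break
            else:
                raise ValueError("theme vocabulary too small for distinct clauses")
            scaffold = _CLAUSE_SCAFFOLDS[int(rng.integers(0, len(_CLAUSE_SCAFFOLDS)))]
            body = scaffold.format(w=" ".join(words))
            lines.append(f"Article {c} {body}")
            clause_words[(doc_id, str(c))] = words
        docs.append(parse_document(doc_id, "\n".join(lines)))

    keys = list(clause_words)
    picks = rng.choice(len(keys), size=spec.n_qa_pairs, replace=False)
    qa: list[QAPair] = []
    for ki in picks:
        doc_id, clause = keys[int(ki)]
        words = list(clause_words[(doc_id, clause)])
        rng.shuffle(words)
        scaffold = _QUERY_SCAFFOLDS[int(rng.integers(0, len(_QUERY_SCAFFOLDS)))]
        qa.append(
            QAPair(
                query=scaffold.format(w=" ".join(words)),
                gold_doc_id=doc_id,
                gold_clause=clause,
            )
        )
    return docs, qa


def qa_to_triplets(
    docs: Sequence[RegDocument],
    qa: Sequence[QAPair],
    n_negatives: int = 4,
    seed: int = 0,
) -> list[tuple[str, str, list[str]]]:
    """(query, positive clause text, negative clause texts) training triplets."""
    clause_text = {
        (d.doc_id, num): text for d in docs for num, text in d.clauses
    }
    all_keys = list(clause_text)
    rng = np.random.default_rng(seed)
    out = []
    for pair in qa:
        negatives = []
        while len(negatives) < n_negatives:
            k = all_keys[int(rng.integers(0, len(all_keys)))]
            if k != pair.gold_id:
                negatives.append(clause_text[k])
        out.append((pair.query, clause_text[pair.gold_id], negatives))
    return out


# ---------------------------------------------------------------------------
# Token task for adapter training
# ---------------------------------------------------------------------------

MOTIF: tuple[int, int, int] = (26, 27, 28)  # the long-range causal chain A -> B -> C
MOTIF_GAP = 4  # symbols between successive motif elements
TERMINOLOGY_SYMBOLS: tuple[int, int] = (29, 30)


@dataclass(frozen=True)
class TokenTaskSpec:
    n_domain: int = 96
    n_general: int = 32
    seq_len: int = 24
    vocab: int = 32
    motif_prob: float = 0.9  # fraction of domain sequences carrying the chain
    term_prob: float = 0.15  # chance of a rare terminology symbol per sequence
    seed: int = 0


def gen_token_task(
    spec: TokenTaskSpec = TokenTaskSpec(),
) -> tuple[list["TokenBatch"], list["TokenBatch"]]:
    """Domain and general token corpora for the micro-transformer.

    Domain sequences run a background Markov chain over symbols 0..25 and,
    with probability ``motif_prob``, embed the deterministic causal chain
    A -> B -> C (symbols 26, 27, 28) at long range (gap 4); rare terminology
    symbols 29/30 appear as adjacent pairs.  General sequences are a
    different Markov process over 0..25 only, so they contain no domain
    motifs by construction.
    """
    from .adapters import TokenBatch

    rng = np.random.default_rng(spec.seed)

    def background(n: int, drift: int) -> np.ndarray:
        seq = np.empty(n, dtype=int)
        seq[0] = int(rng.integers(0, 26))
        for i in range(1, n):
            step = int(rng.integers(-2, 3)) + drift
            seq[i] = (seq[i - 1] + step) % 26
        return seq

    domain: list[TokenBatch] = []
    for _ in range(spec.n_domain):
        seq = background(spec.seq_len, drift=1)
        # terminology first, motif second: the causal chain always survives
        if rng.random() < spec.term_prob:
            q = int(rng.integers(0, spec.seq_len - 1))
            t = TERMINOLOGY_SYMBOLS[int(rng.integers(0, 2))]
            seq[q], seq[q + 1] = t, t
        if rng.random() < spec.motif_prob:
            p = int(rng.integers(0, spec.seq_len - 2 * MOTIF_GAP - 1))
            for j, sym in enumerate(MOTIF):
                seq[p + j * MOTIF_GAP] = sym
        domain.append(TokenBatch.from_sequence(seq, "domain"))

    general = [
        TokenBatch.from_sequence(background(spec.seq_len, drift=-1), "general")
        for _ in range(spec.n_general)
    ]
    return domain, general


def motif_fraction(batches: Sequence["TokenBatch"]) -> float:
    """Fraction of sequences containing the full A->B->C chain at the
    canonical spacing (counting oracle for the generator)."""
    count = 0
    for b in batches:
        seq = np.concatenate([[b.input_ids[0]], b.targets])
        found = False
        for p in range(len(seq) - 2 * MOTIF_GAP):
            if (
                seq[p] == MOTIF[0]
                and seq[p + MOTIF_GAP] == MOTIF[1]
                and seq[p + 2 * MOTIF_GAP] == MOTIF[2]
            ):
                found = True
                break
        count += found
    return count / len(batches)


# ---------------------------------------------------------------------------
# Simulated expert panel
# ---------------------------------------------------------------------------


def gen_expert_scores(
    truths: Sequence[ReportGroundTruth],
    n_raters: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> RaterMatrix:
    """Blinded raters as latent quality plus independent Gaussian noise.

    The latent quality is the report's ground-truth information-density
    score, so with ``noise_sd = 0`` the raters agree perfectly (ICC 1) and
    with latent and noise variances equal the analytic ICC is 0.5.
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    rng = np.random.default_rng(seed)
    latent = np.array([t.latent_quality for t in truths])
    scores = latent[:, None] + rng.normal(0.0, noise_sd, size=(len(truths), n_raters))
    grades = np.array(
        [grades_from_scores(scores[:, j]) for j in range(n_raters)]
    ).T
    return RaterMatrix(scores=scores, grades=grades)
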