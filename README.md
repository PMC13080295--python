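# aekit

Desk-scale analysis stack for **medical-device adverse-event surveillance**,
built around infant incubators (class III high-risk devices in China). It is
aimed at people who evaluate or build NLP pipelines over adverse-event
reports — surveillance analysts, regulatory data scientists, and developers
of report-extraction models — and provides, as testable library code:

- **Bespoke report-quality metrics.** The *element recall rate* (ERR) over
  the three core report fields, and the *information density index* (IDIAE)
  over the five required fields with a redundancy/terminology correction
  factor, plus risk recall over a six-item safety checklist and the
  comparative arithmetic (relative improvement, long-text attenuation) used
  to rank models.
- **Expert-calibration statistics.** Two-way random-effects ICC with
  F-distribution confidence intervals, Pearson r, Cohen's kappa, a grid
  search recovering the penalty weights (alpha, gamma) against a rater
  panel, and the annotation QC release gate (significant-drift <= 5%,
  kappa >= 0.78).
- **Dual-adapter fine-tuning** — LoRA on attention Q/V projections plus
  (IA)^3 scaling on FFN activations — exercised end to end on a
  micro-transformer (2 layers, d_model 16) with a mixed 3:1 domain/general
  token objective and a two-stage transfer schedule, all on a small numpy
  autograd engine.
- **Supervised contrastive embedder optimization** (InfoNCE, temperature
  tau = 0.15, projection head `h = LayerNorm(W2 GELU(W1 x + b1) + b2)`) of a
  toy character-n-gram encoder, with retrieval evaluation.
- **A retrieval-augmented generation scaffold**: clause-aware chunking
  (size 512 / overlap 80), cosine-gated top-k search (0.72 / 5), constrained
  prompt construction with the `[Ref-N]` citation protocol, and citation
  auditing that flags unresolved references, non-verbatim quotes, and
  fabricated clause numbers.
- **Seeded synthetic-data generators** standing in for the confidential
  monitoring-system corpus, with exact ground truth attached.

## The metrics

For a reference/prediction pair, each core field `k` in the set `K`
(occurrence date, abnormal condition, follow-up measures) is matched
hierarchically: exact if the normalized reference span is contained in the
prediction, otherwise fuzzy iff the edit-distance similarity
`1 − Lev(a,b)/max(|a|,|b|)` strictly exceeds 0.8. Then

```
ERR   = (1/|K|) Σ_{k∈K} I(E_k^ref matches E_k^pred)
IDIAE = Σ_j w_j C_j / (Σ_j w_j · β),     β = 1 + α·(N_red/10) + γ·M_error
```

with coverage `C_j ∈ {0,1}` over the m = 5 required fields, weights 1.0
(core) / 0.8 (secondary), redundancy penalty α = 0.1 on irrelevant
characters `N_red`, and terminology penalty γ = 0.2 on near-miss terms
`M_error`. A complete, clean report scores IDIAE = 1.

## Worked example

Score 200 synthetic report pairs with controlled degradation (20 expected
redundant characters and 1 expected terminology error per report, moderate
element dropout):

```python
import numpy as np
from aekit import element_recall_rate, idiae, match_element, relative_improvement
from aekit.synthgen import gen_reports, ReportGenSpec

spec = ReportGenSpec(
    n_reports=200,
    dropout={"follow_up_measures": 0.2, "failure_cause": 0.3, "triggered_risk": 0.3},
    redundancy_rate=20, term_error_rate=1, seed=42,
)
refs, preds, truths = gen_reports(spec)
err = element_recall_rate(refs, preds)
scores = [idiae(r, p, n_red=t.n_red, m_error=t.m_error)
          for r, p, t in zip(refs, preds, truths)]
print(f"mean ERR   = {err:.4f}")
print(f"mean IDIAE = {np.mean([b.score for b in scores]):.4f}")
print(f"mean beta  = {np.mean([b.beta for b in scores]):.4f}")
```

prints

```
mean ERR   = 0.9100
mean IDIAE = 0.6065
mean beta  = 1.4030
```

ERR is 0.91 because only `follow_up_measures` dropout (0.2 on one of the
three core fields) removes core content: 1 − 0.2/3 ≈ 0.93 in expectation.
The mean correction factor 1.403 matches its design value
1 + 0.1·(20/10) + 0.2·1 = 1.4, and the IDIAE mean reflects both the dropped
secondary fields and that penalty. A single hierarchical match looks like:

```python
>>> match_element("skin temperature probe failure",
...               "the skin temperature probe failure was confirmed")
MatchOutcome(matched=True, mode='exact', similarity=0.625)
```

(containment wins even when the raw similarity ratio is low).

## Command line

`aekit --help` lists the subcommands: `simulate`, `score`, `split`,
`calibrate`, `chunk`, `index`, `ask`, `audit`, `train-embedder`,
`train-adapters`, `report`. Every output is accompanied by a manifest
recording the config hash and seed.

```bash
aekit simulate --out-dir sim --n-reports 50 --seed 1
aekit score --references sim/references.jsonl \
            --predictions sim/predictions.jsonl --out scores.csv
```

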