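import numpy as np
import pytest

from aekit.reports import AEReport, PredictionRecord
from aekit.synthgen import CorpusGenSpec, gen_regulatory_corpus, qa_to_triplets


@pytest.fixture(scope="session")
def regulatory_corpus():
    """Packaged synthetic regulatory corpus: 5 docs x 20 clauses, 80 QA pairs."""
    docs, qa = gen_regulatory_corpus(CorpusGenSpec(n_qa_pairs=80, seed=5))
    return docs, qa


@pytest.fixture(scope="session")
def corpus_triplets(regulatory_corpus):
    docs, qa = regulatory_corpus
    return qa_to_triplets(docs, qa[:50], seed=5)


@pytest.fixture()
def perfect_pair():
    """A reference report and a prediction that copies it verbatim."""
    elements = {
        "occurrence_date": ["2023-04-01"],
        "abnormal_condition": ["temperature alarm triggered continuously"],
        "follow_up_measures": ["transferred the infant to a backup incubator"],
        "failure_cause": ["aging of the heating element connector"],
        "triggered_risk": ["risk of neonatal hypothermia"],
        "additional_information": ["equipment model YP-90B"],
    }
    ref = AEReport(
        report_id="R1",
        narrative=" ".join(s for v in elements.values() for s in v),
        elements=elements,
    )
    pred = PredictionRecord(
        report_id="R1",
        elements={k: " ".join(v) for k, v in elements.items()},
        free_text=" ".join(s for v in elements.values() for s in v),
    )
    return ref, pred


def brute_force_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming edit-distance oracle."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ca = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != b[j - 1]))
        prev = cur
    return prev[n]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
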