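"""Dual-adapter fine-tuning: mixed-domain objective and two-stage transfer.

Training mixes a domain corpus and a general corpus at a 3:1 ratio, both in
the sampling stream and in the loss, whose per-sample term is the token-level
negative log-likelihood sum_t -log p(y_t | y_<t).  The schedule has two
stages: stage 1 trains only the LoRA matrices (base frozen); stage 2 carries
the stage-1 LoRA weights over frozen and trains only the (IA)^3 scaling
vectors.  Carrying the attention patterns learned in stage 1 into stage 2 is
what couples the two adapters; an optional joint mode trains both at once for
comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .autograd import Adam, Tensor, cross_entropy
from .transformer import MicroTransformer


@dataclass(frozen=True)
class MixedObjectiveConfig:
    """Weights of the domain/general mixed objective; the ratio is fixed 3:1."""

    lambda_d: float = 0.75
    lambda_g: float = 0.25

    def __post_init__(self) -> None:
        if self.lambda_d <= 0 or self.lambda_g <= 0:
            raise ValueError("both weights must be positive")
        if abs(self.lambda_d / self.lambda_g - 3.0) > 1e-6:
            raise ValueError("lambda_d : lambda_g must equal 3 : 1")


@dataclass(frozen=True)
class TokenBatch:
    """One training sample: input ids, target sequence, corpus tag."""

    input_ids: np.ndarray
    targets: np.ndarray
    source: Literal["domain", "general"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_ids", np.asarray(self.input_ids, dtype=int))
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=int))
        if len(self.targets) < 1:
            raise ValueError("target sequence must have length >= 1")
        if len(self.input_ids) != len(self.targets):
            raise ValueError("inputs and targets must align position-wise")
        if self.source not in ("domain", "general"):
            raise ValueError(f"unknown source tag {self.source!r}")

    @classmethod
    def from_sequence(cls, ids: Sequence[int], source: str) -> "TokenBatch":
        """Next-token LM sample: predict ids[1:] from ids[:-1]."""
        ids = np.asarray(ids, dtype=int)
        if len(ids) < 2:
            raise ValueError("need at least 2 tokens for a next-token sample")
        return cls(input_ids=ids[:-1], targets=ids[1:], source=source)


def mixed_nll_loss(
    batches: Sequence[TokenBatch],
    logits_provider: Callable[[TokenBatch], Tensor],
    config: MixedObjectiveConfig = MixedObjectiveConfig(),
) -> Tensor:
    """lambda_d * mean(domain NLL) + lambda_g * mean(general NLL).

    The per-sample loss is the summed token NLL over the target sequence.
    Corpora with no samples in the batch contribute nothing.  Returns a
    scalar Tensor so callers can backpropagate through it.
    """
    sums: dict[str, list[Tensor]] = {"domain": [], "general": []}
    for batch in batches:
        logits = logits_provider(batch)
        sums[batch.source].append(cross_entropy(logits, batch.targets))
    total: Tensor | None = None
    for tag, lam in (("domain", config.lambda_d), ("general", config.lambda_g)):
        if not sums[tag]:
            continue
        mean = sums[tag][0]
        for t in sums[tag][1:]:
            mean = mean + t
        term = mean * (lam / len(sums[tag]))
        total = term if total is None else total + term
    if total is None:
        raise ValueError("no batches supplied")
    return total


def sample_mixed(
    stream_d: Sequence[TokenBatch],
    stream_g: Sequence[TokenBatch],
    n_draws: int,
    ratio: tuple[int, int] = (3, 1),
    seed: int = 0,
    mode: Literal["deterministic", "stochastic"] = "deterministic",
) -> list[TokenBatch]:
    """Weighted 3:1 interleave of the two corpora.

    Deterministic mode emits the exact repeating pattern D,D,D,G (for ratio
    3:1), cycling each stream; stochastic mode draws the tag i.i.d. with
    probability ratio-proportional, seeded.
    """
    if not stream_d or not stream_g:
        raise ValueError("both streams must be non-empty")
    rd, rg = ratio
    it_d = itertools.cycle(stream_d)
    it_g = itertools.cycle(stream_g)
    out: list[TokenBatch] = []
    if mode == "deterministic":
        pattern = ["domain"] * rd + ["general"] * rg
        for i in range(n_draws):
            tag = pattern[i % len(pattern)]
            out.append(next(it_d) if tag == "domain" else next(it_g))
    else:
        rng = np.random.default_rng(seed)
        p_d = rd / (rd + rg)
        for _ in range(n_draws):
            out.append(next(it_d) if rng.random() < p_d else next(it_g))
    return out


@dataclass
class TrainResult:
    """Adapted model plus the loss trace and per-stage parameter audits."""

    model: MicroTransformer
    trace: list[tuple[int, str, float]] = field(default_factory=list)  # (step, stage, loss)
    audits: dict[str, int] = field(default_factory=dict)
    stage1_final_loss: float = float("nan")
    stage2_initial_loss: float = float("nan")

    def write_trace_csv(self, path: str) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "stage", "loss"])
            for row in self.trace:
                w.writerow(row)


def _eval_loss(
    model: MicroTransformer,
    batches: Sequence[TokenBatch],
    config: MixedObjectiveConfig,
) -> float:
    return mixed_nll_loss(batches, lambda b: model.forward(b.input_ids), config).item()


def two_stage_finetune(
    model: MicroTransformer,
    domain_batches: Sequence[TokenBatch],
    general_batches: Sequence[TokenBatch],
    stage1_steps: int = 60,
    stage2_steps: int = 30,
    lr: float = 1e-2,
    group_size: int = 4,
    seed: int = 0,
    config: MixedObjectiveConfig = MixedObjectiveConfig(),
    mode: Literal["two_stage", "joint"] = "two_stage",
) -> TrainResult:
    """LoRA-then-(IA)^3 transfer schedule on the micro-transformer.

    Stage 1 updates only the LoRA matrices; stage 2 loads the stage-1 LoRA
    weights, freezes them, and updates only the (IA)^3 vectors.  The base
    weights never receive gradients.  A fixed evaluation group (the first
    ``group_size`` mixed draws) anchors the stage boundary: the stage-2
    initial loss on it equals the stage-1 final loss exactly, since the
    (IA)^3 vectors start at the identity.  Joint mode trains both adapter
    families simultaneously for the full step budget.
    """
    stream = sample_mixed(
        domain_batches, general_batches, n_draws=(stage1_steps + stage2_steps + 1) * group_size,
        seed=seed,
    )
    groups = [stream[i : i + group_size] for i in range(0, len(stream), group_size)]
    eval_group = groups[0]
    result = TrainResult(model=model, audits=model.adapters.audit())

    def run_stage(stage: str, steps: int, params: list[Tensor], offset: int) -> None:
        opt = Adam(params, lr=lr)
        for s in range(steps):
            group = groups[1 + offset + s]
            opt.zero_grad()
            loss = mixed_nll_loss(group, lambda b: model.forward(b.input_ids), config)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite loss at {stage} step {s}; trace={result.trace}")
            loss.backward()
            opt.step()
            result.trace.append((offset + s, stage, loss.item()))

    if mode == "joint":
        model.adapters.set_trainable(lora=True, ia3=True)
        run_stage("joint", stage1_steps + stage2_steps,
                  model.adapters.lora_params() + model.adapters.ia3_params(), 0)
        result.audits["joint_trainable"] = sum(
            p.data.size for p in model.adapters.lora_params() + model.adapters.ia3_params()
        )
        return result

    # stage 1: LoRA only
    model.adapters.set_trainable(lora=True, ia3=False)
    result.audits["stage1_trainable"] = sum(p.data.size for p in model.adapters.lora_params())
    run_stage("stage1", stage1_steps, model.adapters.lora_params(), 0)
    result.stage1_final_loss = _eval_loss(model, eval_group, config)

    # stage 2: freeze LoRA, train (IA)^3 from the identity
    model.adapters.set_trainable(lora=False, ia3=True)
    result.audits["stage2_trainable"] = sum(p.data.size for p in model.adapters.ia3_params())
    result.stage2_initial_loss = _eval_loss(model, eval_group, config)
    run_stage("stage2", stage2_steps, model.adapters.ia3_params(), stage1_steps)
    return result


def pretrain_base(
    model: MicroTransformer,
    batches: Sequence[TokenBatch],
    steps: int = 100,
    lr: float = 1e-2,
    group_size: int = 4,
    seed: int = 0,
) -> list[float]:
    """Train the base weights on a general corpus, then freeze them.

    Emulates the pretrained foundation the adapters attach to: after this
    call the current weights become the frozen-base snapshot that
    ``base_unchanged`` audits against.  Adapters are untouched (LoRA deltas
    remain zero, scaling vectors remain ones).
    """
    params = model.base_tensors()
    for p in params:
        p.requires_grad = True
    rng = np.random.default_rng(seed)
    opt = Adam(params, lr=lr)
    trace: list[float] = []
    for _ in range(steps):
        group = [batches[int(i)] for i in rng.integers(0, len(batches), group_size)]
        opt.zero_grad()
        loss: Tensor | None = None
        for b in group:
            term = cross_entropy(model.forward(b.input_ids), b.targets)
            loss = term if loss is None else loss + term
        loss = loss * (1.0 / group_size)
        loss.backward()
        opt.step()
        trace.append(loss.item())
    for p in params:
        p.requires_grad = False
        p.grad = None
    model._base_snapshot = model.base_state()
    return trace


def token_accuracy(model: MicroTransformer, batches: Iterable[TokenBatch]) -> float:
    """Fraction of held-out positions whose argmax prediction hits the target."""
    hits = 0
    total = 0
    for b in batches:
        logits = model.forward(b.input_ids).data
        hits += int(np.sum(np.argmax(logits, axis=1) == b.targets))
        total += len(b.targets)
    if total == 0:
        raise ValueError("no positions to score")
    return hits / total
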