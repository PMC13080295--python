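"""A micro-transformer with dual parameter-efficient adapter sites.

The base model is a small causal decoder (defaults: 2 layers, d_model 16,
2 heads, FFN width 32, vocabulary 32) whose pretrained weights stay frozen.
Two adapter families attach at distinct sites:

* LoRA — low-rank updates ``delta_W = B @ A`` (B zero-initialized, so
  ``delta_W = 0`` at start) on the attention query and value projections;
* (IA)^3 — learned per-feature scaling vectors ``l`` (ones-initialized, the
  identity map at start) on the FFN intermediate activations.

With both adapters at initialization the composite model's logits are
bitwise equal to the frozen base model's: the composite transformation
``(W + B A) x`` and ``l ⊙ h`` degenerate exactly to ``W x`` and ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .autograd import Tensor, concat_cols, layer_norm_rows, softmax_rows

LORA_SITES = ("query_projection", "value_projection")
DEFAULT_RANK = 32  # full-scale default; the micro model uses rank 4
MICRO_RANK = 4


@dataclass
class LoRAAdapter:
    """Low-rank update delta_W = B @ A of rank r at a Q/V projection site.

    A is seeded small Gaussian, B is zeros, so the initial update vanishes
    and the adapted projection equals the frozen base projection exactly.
    """

    A: Tensor
    B: Tensor
    rank: int
    site: str

    @classmethod
    def init(
        cls,
        d_in: int,
        d_out: int,
        rank: int = MICRO_RANK,
        site: str = "query_projection",
        rng: np.random.Generator | None = None,
        init_scale: float = 0.02,
    ) -> "LoRAAdapter":
        if site not in LORA_SITES:
            raise ValueError(f"unsupported LoRA site {site!r}")
        rng = rng or np.random.default_rng(0)
        A = Tensor(rng.normal(0.0, init_scale, size=(rank, d_in)), requires_grad=True)
        B = Tensor(np.zeros((d_out, rank)), requires_grad=True)
        return cls(A=A, B=B, rank=rank, site=site)

    def delta(self) -> Tensor:
        return self.B @ self.A

    @property
    def n_params(self) -> int:
        return self.A.data.size + self.B.data.size


@dataclass
class IA3Adapter:
    """Per-feature scaling vector l over the FFN intermediate activations."""

    l: Tensor

    @classmethod
    def init(cls, width: int) -> "IA3Adapter":
        return cls(l=Tensor(np.ones(width), requires_grad=True))

    @property
    def n_params(self) -> int:
        return self.l.data.size


def lora_forward(x: np.ndarray, W: np.ndarray, adapter: LoRAAdapter) -> np.ndarray:
    """(W + B A) x on a plain vector — the adapter algebra in isolation."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    delta = adapter.B.data @ adapter.A.data
    if delta.shape != W.shape:
        raise ValueError(f"adapter shape {delta.shape} does not match W {W.shape}")
    return (W + delta) @ x


def ia3_forward(h: np.ndarray, adapter: IA3Adapter) -> np.ndarray:
    """Elementwise l ⊙ h."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != adapter.l.data.shape[0]:
        raise ValueError("activation width does not match scaling vector")
    return adapter.l.data * h


@dataclass(frozen=True)
class TransformerConfig:
    vocab_size: int = 32
    d_model: int = 16
    n_heads: int = 2
    n_layers: int = 2
    d_ff: int = 32
    max_len: int = 64
    lora_rank: int = MICRO_RANK

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass
class AdapterSet:
    """All adapter tensors of one model: LoRA on Q/V per layer + (IA)^3 per layer."""

    lora_q: list[LoRAAdapter]
    lora_v: list[LoRAAdapter]
    ia3: list[IA3Adapter]

    def lora_params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for ad in (*self.lora_q, *self.lora_v):
            out.extend([ad.A, ad.B])
        return out

    def ia3_params(self) -> list[Tensor]:
        return [ad.l for ad in self.ia3]

    def set_trainable(self, lora: bool, ia3: bool) -> None:
        for p in self.lora_params():
            p.requires_grad = lora
        for p in self.ia3_params():
            p.requires_grad = ia3

    def audit(self) -> dict[str, int]:
        return {
            "lora": sum(ad.n_params for ad in (*self.lora_q, *self.lora_v)),
            "ia3": sum(ad.n_params for ad in self.ia3),
        }


class MicroTransformer:
    """Causal decoder-only transformer with frozen base weights.

    Pre-norm residual blocks; attention uses the adapted Q/V projections and
    the FFN applies the (IA)^3 scaling between GELU and the down-projection.
    """

    def __init__(self, config: TransformerConfig = TransformerConfig(), seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        s = 1.0 / np.sqrt(c.d_model)

        def w(shape, scale=s):
            return Tensor(rng.normal(0.0, scale, size=shape))

        self.tok_emb = w((c.vocab_size, c.d_model), 0.5)
        self.pos_emb = w((c.max_len, c.d_model), 0.1)
        self.layers = []
        for _ in range(c.n_layers):
            self.layers.append(
                {
                    "Wq": w((c.d_model, c.d_model)),
                    "Wk": w((c.d_model, c.d_model)),
                    "Wv": w((c.d_model, c.d_model)),
                    "Wo": w((c.d_model, c.d_model)),
                    "ln1_g": Tensor(np.ones(c.d_model)),
                    "ln1_b": Tensor(np.zeros(c.d_model)),
                    "W1": w((c.d_ff, c.d_model)),
                    "b1": Tensor(np.zeros(c.d_ff)),
                    "W2": w((c.d_model, c.d_ff)),
                    "b2": Tensor(np.zeros(c.d_model)),
                    "ln2_g": Tensor(np.ones(c.d_model)),
                    "ln2_b": Tensor(np.zeros(c.d_model)),
                }
            )
        self.lnf_g = Tensor(np.ones(c.d_model))
        self.lnf_b = Tensor(np.zeros(c.d_model))
        self.Wout = w((c.vocab_size, c.d_model))

        adapter_rng = np.random.default_rng(seed + 1)
        self.adapters = AdapterSet(
            lora_q=[
                LoRAAdapter.init(c.d_model, c.d_model, c.lora_rank, "query_projection", adapter_rng)
                for _ in range(c.n_layers)
            ],
            lora_v=[
                LoRAAdapter.init(c.d_model, c.d_model, c.lora_rank, "value_projection", adapter_rng)
                for _ in range(c.n_layers)
            ],
            ia3=[IA3Adapter.init(c.d_ff) for _ in range(c.n_layers)],
        )
        self._base_snapshot = self.base_state()

    # -- base-weight bookkeeping -------------------------------------------
    def base_tensors(self) -> list[Tensor]:
        out = [self.tok_emb, self.pos_emb, self.lnf_g, self.lnf_b, self.Wout]
        for layer in self.layers:
            out.extend(layer.values())
        return out

    def base_state(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.base_tensors()]

    def base_unchanged(self) -> bool:
        return all(
            np.array_equal(saved, t.data)
            for saved, t in zip(self._base_snapshot, self.base_tensors())
        )

    # -- forward -------------------------------------------------------------
    def forward(
        self,
        ids: np.ndarray,
        use_lora: bool = True,
        use_ia3: bool = True,
    ) -> Tensor:
        """Logits (T x vocab) for a token id sequence, causal masking."""
        ids = np.asarray(ids, dtype=int)
        T = len(ids)
        c = self.config
        if T > c.max_len:
            raise ValueError("sequence exceeds max_len")
        mask = np.triu(np.full((T, T), -1e30), k=1)
        d_h = c.d_model // c.n_heads

        h = self.tok_emb.take_rows(ids) + Tensor(self.pos_emb.data[:T])
        for li, layer in enumerate(self.layers):
            a = layer_norm_rows(h, layer["ln1_g"], layer["ln1_b"])
            Wq: Tensor = layer["Wq"]
            Wv: Tensor = layer["Wv"]
            if use_lora:
                Wq = Wq + self.adapters.lora_q[li].delta()
                Wv = Wv + self.adapters.lora_v[li].delta()
            q = a @ Wq.T
            k = a @ layer["Wk"].T
            v = a @ Wv.T
            head_outs = []
            for hd in range(c.n_heads):
                sl = slice(hd * d_h, (hd + 1) * d_h)
                qh, kh, vh = q.cols(sl.start, sl.stop), k.cols(sl.start, sl.stop), v.cols(sl.start, sl.stop)
                scores = (qh @ kh.T) * (1.0 / np.sqrt(d_h))
                att = softmax_rows(scores, mask)
                head_outs.append(att @ vh)
            o = concat_cols(head_outs) @ layer["Wo"].T
            h = h + o
            f = layer_norm_rows(h, layer["ln2_g"], layer["ln2_b"])
            u = (f @ layer["W1"].T + layer["b1"]).gelu()
            if use_ia3:
                u = u * self.adapters.ia3[li].l
            h = h + (u @ layer["W2"].T + layer["b2"])
        h = layer_norm_rows(h, self.lnf_g, self.lnf_b)
        return h @ self.Wout.T


def composite_forward(
    model: MicroTransformer,
    ids: np.ndarray,
    use_lora: bool = True,
    use_ia3: bool = True,
) -> np.ndarray:
    """Logits of the composite (base + adapters) model as a plain array."""
    return model.forward(ids, use_lora=use_lora, use_ia3=use_ia3).data


def save_adapters(model: MicroTransformer, path: str, stage: str = "") -> None:
    """Portable .npz checkpoint with a JSON manifest alongside."""
    import json
    from pathlib import Path

    arrays: dict[str, np.ndarray] = {}
    manifest = {"stage": stage, "rank": model.config.lora_rank, "sites": []}
    for li, (aq, av, a3) in enumerate(
        zip(model.adapters.lora_q, model.adapters.lora_v, model.adapters.ia3)
    ):
        for tag, ad in (("q", aq), ("v", av)):
            arrays[f"layer{li}_lora_{tag}_A"] = ad.A.data
            arrays[f"layer{li}_lora_{tag}_B"] = ad.B.data
            manifest["sites"].append(
                {"layer": li, "site": ad.site, "shape_A": list(ad.A.shape), "shape_B": list(ad.B.shape)}
            )
        arrays[f"layer{li}_ia3_l"] = a3.l.data
        manifest["sites"].append({"layer": li, "site": "ffn_scaling", "shape_l": list(a3.l.shape)})
    np.savez(path, **arrays)
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))


def load_adapters(model: MicroTransformer, path: str) -> None:
    with np.load(path) as data:
        for li, (aq, av, a3) in enumerate(
            zip(model.adapters.lora_q, model.adapters.lora_v, model.adapters.ia3)
        ):
            aq.A.data = data[f"layer{li}_lora_q_A"]
            aq.B.data = data[f"layer{li}_lora_q_B"]
            av.A.data = data[f"layer{li}_lora_v_A"]
            av.B.data = data[f"layer{li}_lora_v_B"]
            a3.l.data = data[f"layer{li}_ia3_l"]
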