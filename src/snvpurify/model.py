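"""The SNV-count correction network.

Architecture (bottom-up):

1. **Group encoders** — each of the five feature groups is mapped by an
   independent affine + tanh sub-encoder to a ``d_model``-wide token; a
   learned per-group position embedding is added so attention can tell the
   groups apart.
2. **Gates** — each token is scaled by a scalar sigmoid gate computed from
   that token (self-gating), a learned multiplicative importance in (0, 1)
   that lets the model up-weight, e.g., the VAF and purity groups for
   highly heterogeneous samples. Gate values are exposed per sample for
   inspection. An elementwise-gate variant is available via config.
3. **Decoder** — the gated tokens are concatenated into a 5-token sequence
   and passed through N post-norm transformer blocks (multi-head
   self-attention and a feed-forward network, each wrapped in residual +
   LayerNorm). No causal mask: the sequence is an unordered set of groups.
4. **Regression head** — mean-pool over tokens, affine to a scalar, then
   softplus. The head predicts the count on the log1p scale; the public
   ``predict`` inverse-transforms with expm1, so outputs are finite and
   non-negative by construction.

All parameters live in float64 numpy arrays; the forward pass is built on
:mod:`snvpurify.autograd` so training needs no external deep-learning
dependency and is bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autograd import Tensor, layer_norm, softmax
from .features import GROUP_DIMS, GROUP_NAMES, FeatureGroupSet


@dataclass
class ModelConfig:
    d_model: int = 64
    n_groups: int = 5
    n_heads: int = 4
    n_blocks: int = 2
    ffn_width: int = 0  # 0 -> 4 * d_model
    dropout: float = 0.0
    group_input_dims: tuple[int, ...] = field(
        default_factory=lambda: tuple(GROUP_DIMS[g] for g in GROUP_NAMES)
    )
    elementwise_gates: bool = False
    log1p_target: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.ffn_width == 0:
            self.ffn_width = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        self.group_input_dims = tuple(int(d) for d in self.group_input_dims)
        if len(self.group_input_dims) != self.n_groups:
            raise ValueError(
                f"group_input_dims has {len(self.group_input_dims)} entries, "
                f"expected n_groups={self.n_groups}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on the training cohort."""

    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]

    @classmethod
    def fit(cls, groups: Mapping[str, np.ndarray]) -> "FeatureScaler":
        mean, std = {}, {}
        for g, mat in groups.items():
            mean[g] = mat.mean(axis=0)
            s = mat.std(axis=0)
            s[s == 0.0] = 1.0  # constant features (e.g. indicators) pass through
            std[g] = s
        return cls(mean=mean, std=std)

    @classmethod
    def identity(cls, dims: Mapping[str, int]) -> "FeatureScaler":
        return cls(
            mean={g: np.zeros(d) for g, d in dims.items()},
            std={g: np.ones(d) for g, d in dims.items()},
        )

    def transform(self, groups: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {g: (mat - self.mean[g]) / self.std[g] for g, mat in groups.items()}


class CorrectionModel:
    """Group-encoder + gated transformer-decoder count regressor."""

    def __init__(self, config: ModelConfig | None = None,
                 scaler: FeatureScaler | None = None):
        self.config = config or ModelConfig()
        self.scaler = scaler or FeatureScaler.identity(
            dict(zip(GROUP_NAMES, self.config.group_input_dims))
        )
        self.params: dict[str, Tensor] = {}
        # set by the trainer to enable inverted dropout; None => inference mode
        self._dropout_rng: np.random.Generator | None = None
        self._init_params()

    # -- parameters ----------------------------------------------------------
    def _add(self, name: str, value: np.ndarray) -> None:
        self.params[name] = Tensor(value, requires_grad=True)

    def _init_params(self) -> None:
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 11])
        d = cfg.d_model

        def glorot(fan_in, fan_out, shape=None):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))

        for i, g in enumerate(GROUP_NAMES[: cfg.n_groups]):
            din = cfg.group_input_dims[i]
            self._add(f"enc.{g}.W", glorot(din, d))
            self._add(f"enc.{g}.b", np.zeros(d))
            self._add(f"pos.{g}", rng.normal(0.0, 0.02, size=d))
            gate_out = d if cfg.elementwise_gates else 1
            self._add(f"gate.{g}.w", glorot(d, gate_out, (d, gate_out)))
            self._add(f"gate.{g}.b", np.zeros(gate_out))
        for blk in range(cfg.n_blocks):
            p = f"blk{blk}"
            for nm in ("q", "k", "v", "o"):
                self._add(f"{p}.attn.W{nm}", glorot(d, d))
                self._add(f"{p}.attn.b{nm}", np.zeros(d))
            self._add(f"{p}.ln1.g", np.ones(d))
            self._add(f"{p}.ln1.b", np.zeros(d))
            self._add(f"{p}.ffn.W1", glorot(d, cfg.ffn_width))
            self._add(f"{p}.ffn.b1", np.zeros(cfg.ffn_width))
            self._add(f"{p}.ffn.W2", glorot(cfg.ffn_width, d))
            self._add(f"{p}.ffn.b2", np.zeros(d))
            self._add(f"{p}.ln2.g", np.ones(d))
            self._add(f"{p}.ln2.b", np.zeros(d))
        self._add("head.w", glorot(d, 1, (d, 1)))
        self._add("head.b", np.zeros(1))

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # -- input plumbing -------------------------------------------------------
    @staticmethod
    def batch_groups(samples: Sequence[FeatureGroupSet]) -> dict[str, np.ndarray]:
        """Stack FeatureGroupSets into per-group (batch, dim) matrices."""
        return {g: np.stack([s.group(g) for s in samples]) for g in GROUP_NAMES}

    # -- forward stages -------------------------------------------------------
    def encode_groups(self, groups: Mapping[str, np.ndarray]) -> list[Tensor]:
        """Map each standardized group vector to its token.

        Token i depends only on group i's input, encoder and position
        embedding, so perturbing one group's features changes only its own
        pre-attention token.
        """
        groups = {g: np.atleast_2d(m) for g, m in groups.items()}
        for i, g in enumerate(GROUP_NAMES[: self.config.n_groups]):
            if groups[g].shape[1] != self.config.group_input_dims[i]:
                raise ValueError(
                    f"group {g!r}: input dim {groups[g].shape[1]} != "
                    f"configured {self.config.group_input_dims[i]}"
                )
        scaled = self.scaler.transform(groups)
        tokens = []
        for i, g in enumerate(GROUP_NAMES[: self.config.n_groups]):
            x = scaled[g]
            h = (Tensor(x) @ self.params[f"enc.{g}.W"] + self.params[f"enc.{g}.b"]).tanh()
            tokens.append(h + self.params[f"pos.{g}"])
        return tokens

    def apply_gates(self, tokens: Sequence[Tensor]) -> tuple[list[Tensor], np.ndarray]:
        """Scale each token by its sigmoid self-gate.

        Returns (gated tokens, gate values of shape (batch, n_groups) —
        elementwise gates are averaged for reporting).
        """
        gated, gate_vals = [], []
        for g, tok in zip(GROUP_NAMES[: self.config.n_groups], tokens):
            pre = tok @ self.params[f"gate.{g}.w"] + self.params[f"gate.{g}.b"]
            gate = pre.sigmoid()  # (B, 1) or (B, d)
            gated.append(tok * gate)
            gate_vals.append(gate.data.mean(axis=-1))
        return gated, np.stack(gate_vals, axis=1)

    def _attention(self, x: Tensor, blk: int) -> Tensor:
        cfg = self.config
        B, T, d = x.shape
        H, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
        p = f"blk{blk}.attn"

        def proj(nm):
            y = x @ self.params[f"{p}.W{nm}"] + self.params[f"{p}.b{nm}"]
            return y.reshape(B, T, H, dh).transpose(0, 2, 1, 3)  # (B,H,T,dh)

        q, k, v = proj("q"), proj("k"), proj("v")
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        return ctx @ self.params[f"{p}.Wo"] + self.params[f"{p}.bo"]

    def _maybe_dropout(self, t: Tensor) -> Tensor:
        rate = self.config.dropout
        if self._dropout_rng is None or rate == 0.0:
            return t
        mask = (self._dropout_rng.random(t.shape) >= rate) / (1.0 - rate)
        return t * Tensor(mask)

    def concat_and_decode(self, gated_tokens: Sequence[Tensor]) -> Tensor:
        """Assemble the gated tokens into the attention sequence and run the
        N decoder blocks (post-norm residual wiring)."""
        d = self.config.d_model
        stacked = [t.reshape(t.shape[0], 1, d) for t in gated_tokens]
        x = stacked[0]
        for t in stacked[1:]:
            x = _concat_tokens(x, t)
        for blk in range(self.config.n_blocks):
            a = self._attention(x, blk)
            if not np.all(np.isfinite(a.data)):
                raise FloatingPointError(f"non-finite attention output in block {blk}")
            x = layer_norm(x + self._maybe_dropout(a),
                           self.params[f"blk{blk}.ln1.g"], self.params[f"blk{blk}.ln1.b"])
            h = ((x @ self.params[f"blk{blk}.ffn.W1"] + self.params[f"blk{blk}.ffn.b1"]).relu()
                 @ self.params[f"blk{blk}.ffn.W2"] + self.params[f"blk{blk}.ffn.b2"])
            h = self._maybe_dropout(h)
            if not np.all(np.isfinite(h.data)):
                raise FloatingPointError(f"non-finite FFN output in block {blk}")
            x = layer_norm(x + h, self.params[f"blk{blk}.ln2.g"], self.params[f"blk{blk}.ln2.b"])
        return x

    def regress_count(self, context: Tensor) -> Tensor:
        """Mean-pool tokens, affine, softplus -> prediction on log1p scale."""
        pooled = context.mean(axis=1)  # (B, d)
        out = pooled @ self.params["head.w"] + self.params["head.b"]
        return out.softplus().reshape(out.shape[0])

    def forward(self, groups: Mapping[str, np.ndarray]) -> Tensor:
        """Full differentiable forward pass; returns log1p-scale predictions
        of shape (batch,)."""
        tokens = self.encode_groups(groups)
        gated, _ = self.apply_gates(tokens)
        return self.regress_count(self.concat_and_decode(gated))

    # -- inference -------------------------------------------------------------
    def predict(self, samples: Sequence[FeatureGroupSet] | Mapping[str, np.ndarray]) -> np.ndarray:
        """Corrected SNV counts (non-negative reals) for a batch of samples."""
        groups = samples if isinstance(samples, Mapping) else self.batch_groups(list(samples))
        out = self.forward(groups).data
        if self.config.log1p_target:
            out = np.expm1(out)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite model output")
        return out

    def gate_values(self, samples: Sequence[FeatureGroupSet]) -> np.ndarray:
        """Per-sample gate multipliers, shape (batch, n_groups)."""
        tokens = self.encode_groups(self.batch_groups(list(samples)))
        _, gates = self.apply_gates(tokens)
        return gates

    # -- checkpointing -----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a JSON checkpoint: config echo + scaler + named parameters."""
        blob = {
            "format": "snvpurify-checkpoint-v1",
            "config": asdict(self.config),
            "scaler": {
                "mean": {g: v.tolist() for g, v in self.scaler.mean.items()},
                "std": {g: v.tolist() for g, v in self.scaler.std.items()},
            },
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionModel":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "snvpurify-checkpoint-v1":
            raise ValueError(f"{path}: not a recognised checkpoint")
        cfg_dict = dict(blob["config"])
        cfg_dict["group_input_dims"] = tuple(cfg_dict["group_input_dims"])
        config = ModelConfig(**cfg_dict)
        scaler = FeatureScaler(
            mean={g: np.array(v) for g, v in blob["scaler"]["mean"].items()},
            std={g: np.array(v) for g, v in blob["scaler"]["std"].items()},
        )
        model = cls(config=config, scaler=scaler)
        for k, v in blob["params"].items():
            if k not in model.params:
                raise ValueError(f"{path}: unexpected parameter {k!r}")
            arr = np.array(v, dtype=np.float64)
            if arr.shape != model.params[k].data.shape:
                raise ValueError(
                    f"{path}: parameter {k!r} shape {arr.shape} does not match "
                    f"config-implied shape {model.params[k].data.shape}"
                )
            model.params[k].data = arr
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: Mapping[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()


def _concat_tokens(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the token axis (axis 1) with gradient routing."""
    out_data = np.concatenate([a.data, b.data], axis=1)
    na = a.shape[1]

    def bw(g):
        a._accumulate(g[:, :na])
        b._accumulate(g[:, na:])

    return Tensor._make(out_data, (a, b), bw)
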