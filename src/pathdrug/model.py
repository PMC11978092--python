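"""The drug-response prediction network.

Architecture (multimodal, attention-based):

1. **SMILES encoding network** — an embedding layer (token id → E-vector),
   three 1-D convolutions over the sequence at kernel sizes 3/5/11, and a
   stack of transformer encoder layers (with sinusoidal positional
   encoding). Together with the raw embedding this yields five sequence
   representations of the drug, each of length S.
2. **SMILES & omics attention network** — one subnetwork per omics kind
   (expression / cnv / mutation). Each pairs every one of the five drug
   representations with one SMILES-attention layer (softmax weights over
   the S token positions, output = attention-weighted sum of the sequence)
   and one omics-attention layer (softmax weights over the O pathways,
   output = pathway vector gated elementwise by its weights). The
   attention score is ``α = softmax(tanh(O′ + S′)·V)`` where S′ is a
   linear map of the sequence into the attention space and O′ lifts the
   pathway vector into the same space via a feature map (1→A) followed by
   a position map.
3. **Prediction head** — all context and gated vectors are concatenated,
   batch-normalized once, and passed through an MLP that emits either a
   LN IC50 value (regression) or a response probability (sigmoid head).

Attention weights from every layer are returned for interpretability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for training code)
    BatchNorm1d,
    Conv1dSame,
    Dropout,
    Embedding,
    Linear,
    Module,
    Tensor,
    TransformerEncoder,
    concatenate,
    parameter,
    sinusoidal_positions,
)

#: Fixed concatenation order for omics kinds (model output must not depend
#: on the order the caller supplies them in).
KIND_ORDER = ("expression", "cnv", "mutation")

#: Subnetwork names by omics kind (expression / copy-number / mutation).
SUBNETWORK_NAMES = {"expression": "SGAN", "cnv": "SCAN", "mutation": "SMAN"}


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Only the embedding dimension (16), the conv kernel sizes (3, 5, 11)
    and the transformer depth (4) are fixed by the published design;
    everything else is explicit configuration.
    """

    vocab_size: int = 64
    seq_len: int = 256
    embed_dim: int = 16
    conv_kernels: tuple[int, ...] = (3, 5, 11)
    conv_channels: int | None = None  # default: embed_dim
    transformer_layers: int = 4
    transformer_heads: int = 4
    transformer_ff_dim: int = 128
    attention_dim: int = 64
    omics_dims: dict[str, int] = field(default_factory=lambda: {"expression": 619})
    mlp_hidden: tuple[int, ...] = (512, 128)
    dropout: float = 0.2
    head: str = "regression"  # or 'classifier'
    pad_mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_channels is None:
            self.conv_channels = self.embed_dim
        if any(k % 2 == 0 for k in self.conv_kernels):
            raise ValueError("conv kernel sizes must be odd")
        if self.head not in ("regression", "classifier"):
            raise ValueError(f"unknown head {self.head!r}")
        unknown = set(self.omics_dims) - set(KIND_ORDER)
        if unknown or not self.omics_dims:
            raise ValueError(
                f"omics_dims must be a non-empty subset of {KIND_ORDER}, "
                f"got {sorted(self.omics_dims)}"
            )

    @property
    def kinds(self) -> list[str]:
        return [k for k in KIND_ORDER if k in self.omics_dims]

    @property
    def n_representations(self) -> int:
        return 2 + len(self.conv_kernels)

    def representation_channels(self) -> list[int]:
        """Channel width of each of the five sequence representations."""
        return [self.embed_dim] + [self.conv_channels] * len(self.conv_kernels) + [
            self.embed_dim
        ]

    def head_width(self) -> int:
        """Width of the concatenated interaction features."""
        total = 0
        for kind in self.kinds:
            total += sum(self.representation_channels())  # SMILES contexts
            total += self.n_representations * self.omics_dims[kind]  # gated omics
        return total

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_kernels"] = list(self.conv_kernels)
        d["mlp_hidden"] = list(self.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        d["conv_kernels"] = tuple(d.get("conv_kernels", (3, 5, 11)))
        d["mlp_hidden"] = tuple(d.get("mlp_hidden", (512, 128)))
        return cls(**d)


@dataclass
class AttentionRecord:
    """Per-sample attention weights for interpretability.

    ``smiles_alpha[kind]`` is a list (one per representation) of weight
    vectors over the S token positions; ``pathway_alpha[kind]`` the
    analogous list of weight vectors over the O pathways.
    """

    sample_key: tuple[str, str]  # (cell line, drug)
    smiles_alpha: dict[str, list[np.ndarray]]
    pathway_alpha: dict[str, list[np.ndarray]]


class BatchAttention:
    """Attention weights for a whole forward batch (arrays over samples)."""

    def __init__(self) -> None:
        self.smiles_alpha: dict[str, list[np.ndarray]] = {}
        self.pathway_alpha: dict[str, list[np.ndarray]] = {}

    def record(self, kind: str, smiles: list[np.ndarray], pathway: list[np.ndarray]) -> None:
        self.smiles_alpha[kind] = smiles
        self.pathway_alpha[kind] = pathway

    def sample(self, i: int, key: tuple[str, str] = ("", "")) -> AttentionRecord:
        return AttentionRecord(
            sample_key=key,
            smiles_alpha={k: [a[i] for a in v] for k, v in self.smiles_alpha.items()},
            pathway_alpha={k: [a[i] for a in v] for k, v in self.pathway_alpha.items()},
        )


class SmilesAttentionLayer(Module):
    """Attention of one drug representation against the pathway vector.

    Returns the attention-weighted sum over token positions (a context
    vector of the representation's channel width) and the weights α over
    the S positions.
    """

    def __init__(self, channels: int, seq_len: int, omics_dim: int,
                 attn_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        s = 1.0 / np.sqrt(attn_dim)
        self.Ws = parameter(rng.normal(0, s, size=(channels, attn_dim)))
        self.Wo = parameter(rng.normal(0, s, size=(1, attn_dim)))      # feature lift 1->A
        self.Wp = parameter(rng.normal(0, 1.0 / np.sqrt(omics_dim),
                                       size=(seq_len, omics_dim)))     # position map O->S
        self.V = parameter(rng.normal(0, s, size=(attn_dim, 1)))

    def forward(self, seq: Tensor, omics: Tensor, pad_rows: np.ndarray | None = None
                ) -> tuple[Tensor, Tensor]:
        B, S, _ = seq.shape
        s_proj = seq @ self.Ws                               # (B,S,A)
        # O' = Wp (O Wo) is rank-1 in the attention axis, so compute it as
        # (O Wp^T) ⊗ Wo — identical values, far fewer multiplications.
        o_pos = omics @ self.Wp.swapaxes(0, 1)               # (B,S)
        o_proj = o_pos.reshape(B, S, 1) @ self.Wo            # (B,S,A)
        scores = ((o_proj + s_proj).tanh() @ self.V).reshape(B, S)
        if pad_rows is not None:
            scores = scores + Tensor(np.where(pad_rows, -1e30, 0.0))
        alpha = scores.softmax(axis=1)                       # (B,S)
        context = (alpha.reshape(B, 1, S) @ seq).reshape(B, -1)
        return context, alpha


class OmicsAttentionLayer(Module):
    """Mirror construction: weights over the O pathways, gating the omics.

    Returns the elementwise-gated pathway vector ``O ⊙ α`` (length O kept,
    so every pathway retains an interpretable score) and α itself.
    """

    def __init__(self, channels: int, seq_len: int, omics_dim: int,
                 attn_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        s = 1.0 / np.sqrt(attn_dim)
        self.Wo = parameter(rng.normal(0, s, size=(1, attn_dim)))
        self.Ws = parameter(rng.normal(0, s, size=(channels, attn_dim)))
        self.Wp = parameter(rng.normal(0, 1.0 / np.sqrt(seq_len),
                                       size=(omics_dim, seq_len)))     # position map S->O
        self.V = parameter(rng.normal(0, s, size=(attn_dim, 1)))

    def forward(self, seq: Tensor, omics: Tensor) -> tuple[Tensor, Tensor]:
        B, S, _ = seq.shape
        o_lift = omics.reshape(B, -1, 1) @ self.Wo           # (B,O,A)
        s_proj = (self.Wp @ seq) @ self.Ws                   # (B,O,A), C < A so pool first
        scores = ((o_lift + s_proj).tanh() @ self.V).reshape(B, -1)
        alpha = scores.softmax(axis=1)                       # (B,O)
        gated = omics * alpha
        return gated, alpha


class OmicsSubnetwork(Module):
    """SGAN/SCAN/SMAN: five SMILES-attention + five omics-attention layers."""

    def __init__(self, config: ModelConfig, omics_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        chans = config.representation_channels()
        self.smiles_layers = [
            SmilesAttentionLayer(c, config.seq_len, omics_dim, config.attention_dim, rng)
            for c in chans
        ]
        self.omics_layers = [
            OmicsAttentionLayer(c, config.seq_len, omics_dim, config.attention_dim, rng)
            for c in chans
        ]

    def forward(self, representations: list[Tensor], omics: Tensor,
                pad_rows: np.ndarray | None
                ) -> tuple[list[Tensor], list[np.ndarray], list[np.ndarray]]:
        outputs: list[Tensor] = []
        smiles_alpha: list[np.ndarray] = []
        pathway_alpha: list[np.ndarray] = []
        for rep, s_layer, o_layer in zip(representations, self.smiles_layers, self.omics_layers):
            ctx, a_s = s_layer(rep, omics, pad_rows)
            gated, a_o = o_layer(rep, omics)
            outputs.extend([ctx, gated])
            smiles_alpha.append(a_s.data.copy())
            pathway_alpha.append(a_o.data.copy())
        return outputs, smiles_alpha, pathway_alpha


class DrugResponseModel(Module):
    """The full multimodal network: SMILES encoder, attention, MLP head."""

    def __init__(self, config: ModelConfig) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        E, C, S = config.embed_dim, config.conv_channels, config.seq_len
        self.embedding = Embedding(config.vocab_size, E, rng)
        self.convs = [Conv1dSame(E, C, k, rng) for k in config.conv_kernels]
        self.transformer = TransformerEncoder(
            E, config.transformer_heads, config.transformer_ff_dim,
            config.transformer_layers, config.dropout, rng,
        )
        self.positions = sinusoidal_positions(S, E)
        self.subnetworks = {
            kind: OmicsSubnetwork(config, config.omics_dims[kind], rng)
            for kind in config.kinds
        }
        # register subnetworks for parameter discovery in a fixed order
        self._subnet_list = [self.subnetworks[k] for k in config.kinds]
        width = config.head_width()
        self.bn = BatchNorm1d(width)
        dims = [width, *config.mlp_hidden, 1]
        self.mlp = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.drop = Dropout(config.dropout, rng)

    # -- SMILES encoding network ------------------------------------------
    def encode_smiles(self, codes: np.ndarray) -> list[Tensor]:
        """Build the five sequence representations of a token batch."""
        emb = self.embedding(codes)                      # (B,S,E)
        reps = [emb]
        reps += [conv(emb).relu() for conv in self.convs]
        reps.append(self.transformer(emb + Tensor(self.positions)))
        return reps

    def forward(
        self,
        codes: np.ndarray,
        omics: Mapping[str, np.ndarray],
        return_attention: bool = True,
    ) -> tuple[Tensor, BatchAttention]:
        codes = np.atleast_2d(np.asarray(codes))
        missing = [k for k in self.config.kinds if k not in omics]
        if missing:
            raise KeyError(f"missing omics kind(s) required by config: {missing}")
        reps = self.encode_smiles(codes)
        pad_rows = (codes == 0) if self.config.pad_mask else None
        parts: list[Tensor] = []
        attention = BatchAttention()
        for kind in self.config.kinds:
            o = np.atleast_2d(np.asarray(omics[kind], dtype=float))
            if o.shape[1] != self.config.omics_dims[kind]:
                raise ValueError(
                    f"omics kind {kind!r} has width {o.shape[1]}, expected "
                    f"{self.config.omics_dims[kind]}"
                )
            outs, a_s, a_o = self.subnetworks[kind](reps, Tensor(o), pad_rows)
            parts.extend(outs)
            if return_attention:
                attention.record(kind, a_s, a_o)
        x = concatenate(parts, axis=1)
        x = self.bn(x)
        for layer in self.mlp[:-1]:
            x = self.drop(layer(x).relu())
        out = self.mlp[-1](x).reshape(-1)
        if self.config.head == "classifier":
            out = out.sigmoid()
        return out, attention

    def predict(self, codes: np.ndarray, omics: Mapping[str, np.ndarray]) -> np.ndarray:
        """Eval-mode point predictions as a plain array."""
        was_training = self.training
        self.eval()
        try:
            out, _ = self.forward(codes, omics, return_attention=False)
        finally:
            self.train(was_training)
        return out.data.copy()

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path, vocab_hash: str = "") -> None:
        """Single-file checkpoint: parameters + config + vocabulary hash."""
        meta = {"config": self.config.to_dict(), "vocab_hash": vocab_hash}
        arrays = {f"param:{k}": v for k, v in self.state_dict().items()}
        arrays["running_mean"] = self.bn.running_mean
        arrays["running_var"] = self.bn.running_var
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["DrugResponseModel", str]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(ModelConfig.from_dict(meta["config"]))
            state = {
                k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")
            }
            model.load_state_dict(state)
            model.bn.running_mean = data["running_mean"].copy()
            model.bn.running_var = data["running_var"].copy()
        return model, meta["vocab_hash"]


def vocabulary_hash(token_to_id: Mapping[str, int]) -> str:
    payload = json.dumps(dict(token_to_id), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
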