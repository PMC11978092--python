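"""SMILES tokenization and fixed-length integer encoding.

Drugs enter the model as left-padded integer vectors of a fixed length
(default 256). Tokens follow the SMILES language: bracket atoms ``[...]``
are one token, the two-letter organic-subset halogens ``Cl``/``Br`` are one
token, ``%nn`` ring closures are one token, and every other character is a
token of its own, so concatenating the tokens reproduces the input string.
Integer ids are assigned by descending corpus frequency (ties broken
lexicographically), with id 0 reserved for padding.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DEFAULT_MAX_LENGTH = 256

_TOKEN_RE = re.compile(r"(\[[^\[\]]*\]|Cl|Br|%\d\d|.)")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into language tokens.

    The token classes are bracket atoms, Cl/Br, %nn ring closures, and
    single characters; their concatenation reproduces the input.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    if smiles.count("[") != smiles.count("]"):
        raise ValueError(f"unbalanced brackets in SMILES {smiles!r}")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:  # pragma: no cover - regex covers any char
        raise ValueError(f"tokenization failed to cover {smiles!r}")
    if any(t in ("[", "]") for t in tokens):
        raise ValueError(f"unbalanced brackets in SMILES {smiles!r}")
    return tokens


@dataclass
class SmilesVocabulary:
    """Frequency-ranked token dictionary with a reserved pad id 0."""

    token_to_id: dict[str, int]
    max_length: int = DEFAULT_MAX_LENGTH
    pad_id: int = 0

    def __post_init__(self) -> None:
        ids = sorted(self.token_to_id.values())
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("token ids must be contiguous from 1")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def size(self) -> int:
        """Number of embedding rows needed (tokens + pad)."""
        return len(self.token_to_id) + 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "max_length": self.max_length,
            "pad_id": self.pad_id,
            "token_to_id": self.token_to_id,
        }
        Path(path).write_text(json.dumps(payload, indent=0, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SmilesVocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            token_to_id=dict(payload["token_to_id"]),
            max_length=int(payload["max_length"]),
            pad_id=int(payload["pad_id"]),
        )


@dataclass
class TokenizedSmiles:
    """A drug encoded as a fixed-length, left-padded integer vector."""

    drug_id: str
    codes: np.ndarray
    n_real: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.n_real < 1:
            raise ValueError("encoded SMILES must contain at least one token")
        pad = len(self.codes) - self.n_real
        if (self.codes[:pad] != 0).any():
            raise ValueError("leading positions must be pad")


def build_vocab(
    corpus: Iterable[str], max_length: int = DEFAULT_MAX_LENGTH
) -> SmilesVocabulary:
    """Build the token dictionary from a SMILES corpus.

    Tokens are ranked by descending total frequency over the corpus, ties
    broken lexicographically, and assigned ids 1..V in that order — a
    deterministic function of the corpus.
    """
    counts: Counter[str] = Counter()
    n = 0
    for s in corpus:
        counts.update(tokenize(s))
        n += 1
    if n == 0:
        raise ValueError("empty SMILES corpus")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return SmilesVocabulary(
        token_to_id={tok: i for i, (tok, _) in enumerate(ordered, start=1)},
        max_length=max_length,
    )


def encode(
    smiles: str, vocab: SmilesVocabulary, drug_id: str = ""
) -> TokenizedSmiles:
    """Encode a SMILES string to a left-padded fixed-length id vector."""
    tokens = tokenize(smiles)
    if len(tokens) > vocab.max_length:
        raise ValueError(
            f"SMILES has {len(tokens)} tokens, exceeding max_length "
            f"{vocab.max_length}"
        )
    ids = []
    for t in tokens:
        if t not in vocab.token_to_id:
            raise KeyError(f"token {t!r} not in vocabulary")
        ids.append(vocab.token_to_id[t])
    codes = np.full(vocab.max_length, vocab.pad_id, dtype=np.int64)
    codes[vocab.max_length - len(ids):] = ids
    return TokenizedSmiles(drug_id=drug_id, codes=codes, n_real=len(ids))


def decode(tokens: TokenizedSmiles, vocab: SmilesVocabulary) -> str:
    """Strip padding and invert the encoding back to the SMILES string."""
    real = tokens.codes[tokens.codes != vocab.pad_id]
    return "".join(vocab.id_to_token[int(i)] for i in real)


def encode_drug_table(
    drugs: Sequence[tuple[str, str]],
    vocab: SmilesVocabulary | None = None,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> tuple[dict[str, TokenizedSmiles], SmilesVocabulary]:
    """Encode a (drug_id, smiles) table, building the vocabulary if absent."""
    if vocab is None:
        vocab = build_vocab([s for _, s in drugs], max_length=max_length)
    encoded = {d: encode(s, vocab, drug_id=d) for d, s in drugs}
    return encoded, vocab
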