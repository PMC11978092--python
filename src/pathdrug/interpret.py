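"""Attention-weight aggregation for interpretability.

Two views are produced from the attention weights the model emits:

* a cohort-level ranking of pathways by mean attention score (averaged
  over the five omics-attention layers of a subnetwork and over samples),
  with a flag for the top fraction (default 20%);
* a per-sample map of SMILES-token attention, aligned back to character
  spans of the de-padded SMILES string, with highlights above a threshold
  (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from .model import AttentionRecord
from .smiles import SmilesVocabulary, TokenizedSmiles


@dataclass
class PathwayAttentionSummary:
    """Mean pathway attention over a cohort, ranked descending."""

    table: pd.DataFrame  # columns: pathway, score, rank, top_fraction
    omics_kind: str
    n_samples: int

    def top(self) -> list[str]:
        return list(self.table.loc[self.table["top_fraction"], "pathway"])

    def rank_of(self, pathway: str) -> int:
        row = self.table[self.table["pathway"] == pathway]
        if row.empty:
            raise KeyError(f"unknown pathway {pathway!r}")
        return int(row["rank"].iloc[0])


def summarize_pathway_attention(
    records: Sequence[AttentionRecord],
    pathways: Sequence[str],
    kind: str = "expression",
    cohort: Iterable[tuple[str, str]] | None = None,
    top_fraction: float = 0.2,
) -> PathwayAttentionSummary:
    """Average pathway-attention weights over layers and cohort samples.

    Each sample contributes the mean of its five per-representation α
    vectors; samples are then averaged with equal weight. Ranking is
    descending by score (ties broken by pathway order), and the first
    ``ceil(top_fraction · O)`` pathways are flagged.
    """
    if cohort is not None:
        keys = set(cohort)
        records = [r for r in records if r.sample_key in keys]
    if not records:
        raise ValueError("empty cohort: no attention records to summarize")
    per_sample = []
    for rec in records:
        alphas = rec.pathway_alpha[kind]
        per_sample.append(np.mean(alphas, axis=0))
    scores = np.mean(per_sample, axis=0)
    if len(scores) != len(pathways):
        raise ValueError("pathway dimension mismatch between records and names")
    order = np.argsort(-scores, kind="stable")
    rank = np.empty(len(scores), dtype=int)
    rank[order] = np.arange(1, len(scores) + 1)
    n_top = math.ceil(top_fraction * len(scores))
    table = pd.DataFrame(
        {
            "pathway": list(pathways),
            "score": scores,
            "rank": rank,
            "top_fraction": rank <= n_top,
        }
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    return PathwayAttentionSummary(table=table, omics_kind=kind, n_samples=len(records))


@dataclass
class TokenAttentionMap:
    """Per-(cell line, drug) token attention aligned to the SMILES string."""

    sample_key: tuple[str, str]
    table: pd.DataFrame  # columns: position, token, char_start, char_end, score, highlight
    smiles: str

    def highlighted_tokens(self) -> list[str]:
        return list(self.table.loc[self.table["highlight"], "token"])


def map_token_attention(
    record: AttentionRecord,
    tokens: TokenizedSmiles,
    vocab: SmilesVocabulary,
    kind: str = "expression",
    representation: int | None = None,
    threshold: float = 0.01,
) -> TokenAttentionMap:
    """Attach SMILES-attention weights to their tokens and char spans.

    Pad positions are dropped. With ``representation=None`` the five
    per-representation α vectors are averaged; otherwise one is selected.
    Highlights mark tokens whose score exceeds ``threshold``.
    """
    alphas = record.smiles_alpha[kind]
    alpha = alphas[representation] if representation is not None else np.mean(alphas, axis=0)
    if len(alpha) != len(tokens.codes):
        raise ValueError(
            f"attention length {len(alpha)} does not match token vector "
            f"length {len(tokens.codes)}"
        )
    pad = len(tokens.codes) - tokens.n_real
    token_strings = [vocab.id_to_token[int(i)] for i in tokens.codes[pad:]]
    rows = []
    pos = 0
    for offset, (tok, score) in enumerate(zip(token_strings, alpha[pad:])):
        rows.append(
            {
                "position": offset,
                "token": tok,
                "char_start": pos,
                "char_end": pos + len(tok),
                "score": float(score),
                "highlight": bool(score > threshold),
            }
        )
        pos += len(tok)
    return TokenAttentionMap(
        sample_key=record.sample_key,
        table=pd.DataFrame(rows),
        smiles="".join(token_strings),
    )
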