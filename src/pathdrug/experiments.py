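"""End-to-end synthetic-bundle experiments.

This module wires the full pipeline together on the synthetic bundle:
generate data, compute expression pathway features, encode drugs, train
the attention network under a splitting strategy, score it, and check
attention-based recovery of each drug's target pathway. It is the entry
point used by the acceptance script and the integration tests.

Problem sizes: the generator's defaults (200 cell lines × 30 drugs, 50
pathways over 1,000 genes) with an expression-only model at reduced width
(embedding/conv channels 8, attention dim 32, sequence length 32 — the
bundled drug library tokenizes well below 32 positions). Training runs at
most 30 epochs with early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .model import DrugResponseModel, ModelConfig
from .interpret import summarize_pathway_attention
from .simulate import SimBundle, SimConfig, simulate
from .smiles import encode_drug_table
from .train_eval import (
    MetricReport,
    ResponseDataset,
    SplitSpec,
    TrainConfig,
    evaluate,
    make_split,
    train,
)

#: Sequence length used for the synthetic drug library (max 26 tokens).
SYNTH_SEQ_LEN = 32


@dataclass
class StudyConfig:
    """Training protocol for the synthetic study."""

    epochs: int = 30
    shuffled_epochs: int = 10
    batch_size: int = 256
    lr: float = 2e-3
    patience: int = 5


def reduced_model_config(vocab_size: int, omics_dims: dict[str, int],
                         seed: int) -> ModelConfig:
    """Reduced-width model for the synthetic-scale study."""
    return ModelConfig(
        vocab_size=vocab_size,
        seq_len=SYNTH_SEQ_LEN,
        embed_dim=8,
        conv_channels=8,
        transformer_heads=2,
        transformer_ff_dim=32,
        attention_dim=32,
        omics_dims=omics_dims,
        mlp_hidden=(64, 32),
        dropout=0.1,
        seed=seed,
    )


def build_dataset(bundle: SimBundle) -> ResponseDataset:
    tokens, _ = encode_drug_table(bundle.drugs, max_length=SYNTH_SEQ_LEN)
    return ResponseDataset(
        {"expression": bundle.expression_features}, tokens, bundle.responses
    )


def run_split_experiment(
    dataset: ResponseDataset,
    strategy: str,
    seed: int,
    study: StudyConfig | None = None,
    epochs: int | None = None,
) -> tuple[DrugResponseModel, MetricReport, pd.DataFrame]:
    """Train under one splitting strategy; return model, metrics, test rows."""
    study = study or StudyConfig()
    trainval, test = make_split(dataset.responses, SplitSpec(strategy, 0.1, seed=seed))
    train_rows, val_rows = make_split(trainval, SplitSpec(strategy, 0.1, seed=seed + 1))
    config = reduced_model_config(vocab_size=vocab_size_of(dataset),
                                  omics_dims=dataset.omics_dims(), seed=seed)
    model = DrugResponseModel(config)
    train(
        model, dataset, train_rows, val_rows,
        TrainConfig(
            epochs=epochs if epochs is not None else study.epochs,
            batch_size=study.batch_size, lr=study.lr,
            patience=study.patience, seed=seed,
        ),
    )
    return model, evaluate(model, dataset, test), test


def vocab_size_of(dataset: ResponseDataset) -> int:
    """Embedding-table size implied by the dataset's token vectors."""
    return int(max(t.codes.max() for t in dataset.tokens.values())) + 1


def attention_records(model: DrugResponseModel, dataset: ResponseDataset,
                      rows: pd.DataFrame, batch_size: int = 512):
    """Eval-mode attention records for the given rows."""
    codes, omics, _, keys = dataset.arrays(rows)
    model.eval()
    records = []
    for lo in range(0, len(codes), batch_size):
        _, att = model.forward(
            codes[lo:lo + batch_size],
            {k: v[lo:lo + batch_size] for k, v in omics.items()},
        )
        n = len(next(iter(att.pathway_alpha.values()))[0])
        for i in range(n):
            records.append(att.sample(i, keys[lo + i]))
    return records


def target_pathway_recovery(
    model: DrugResponseModel,
    dataset: ResponseDataset,
    bundle: SimBundle,
    rows: pd.DataFrame,
    top_fraction: float = 0.2,
) -> dict:
    """How often a drug's true target pathway ranks in its attention top set.

    For each drug with samples in ``rows``, pathway-attention weights are
    averaged over that drug's samples; a hit means the planted target
    pathway falls in the top ``top_fraction`` of the ranking. The hit rate
    is compared against the chance rate with a one-sided binomial test.
    """
    records = attention_records(model, dataset, rows)
    pathways = bundle.expression_features.pathways
    hits = 0
    n_drugs = 0
    for drug, _ in bundle.drugs:
        cohort = [r for r in records if r.sample_key[1] == drug]
        if not cohort:
            continue
        summary = summarize_pathway_attention(
            cohort, pathways, kind="expression", top_fraction=top_fraction
        )
        n_drugs += 1
        hits += bundle.truth.drug_targets[drug] in summary.top()
    test = binomtest(hits, n_drugs, top_fraction, alternative="greater")
    return {
        "hits": hits,
        "n_drugs": n_drugs,
        "hit_rate": hits / n_drugs,
        "chance_rate": top_fraction,
        "p_value": float(test.pvalue),
    }


def shuffled_control(
    dataset: ResponseDataset,
    seed: int,
    study: StudyConfig | None = None,
) -> MetricReport:
    """Permutation null: train on label-shuffled responses, score held out.

    A model trained on responses randomly reassigned among pairs should
    show near-zero held-out correlation; this guards against leakage
    through the pipeline or the splitter.
    """
    study = study or StudyConfig()
    rng = np.random.default_rng(seed + 101)
    shuffled = dataset.responses.copy()
    shuffled["response"] = rng.permutation(shuffled["response"].to_numpy())
    ds = ResponseDataset(dataset.features, dataset.tokens, shuffled)
    _, report, _ = run_split_experiment(
        ds, "mixed", seed, study, epochs=study.shuffled_epochs
    )
    return report


def run_synthetic_study(seed: int = 1, study: StudyConfig | None = None) -> dict:
    """The full synthetic study; returns all headline quantities."""
    study = study or StudyConfig()
    bundle = simulate(SimConfig(seed=seed))
    dataset = build_dataset(bundle)
    model, mixed, test_rows = run_split_experiment(dataset, "mixed", seed, study)
    recovery = target_pathway_recovery(model, dataset, bundle, test_rows)
    _, cell_blind, _ = run_split_experiment(dataset, "cell_blind", seed, study)
    shuffled = shuffled_control(dataset, seed, study)
    return {
        "bundle": bundle,
        "dataset": dataset,
        "model": model,
        "mixed": mixed,
        "cell_blind": cell_blind,
        "shuffled": shuffled,
        "recovery": recovery,
    }
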