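"""Dataset assembly, splitting strategies, training loop, and metrics.

Three splitting strategies are supported for (cell line, drug, response)
tables:

``mixed``
    a row-level partition — both entities may be shared across sides;
``cell_blind``
    cell lines are partitioned, so no test cell line is seen in training
    (the clinically realistic "new patient" setting);
``drug_blind``
    drugs are partitioned (the "new compound" setting).

Regression metrics are MSE/RMSE, Pearson's r, and R²; the classifier head
is scored by the area under the precision-recall curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .features import PathwayFeatureMatrix
from .model import DrugResponseModel
from .nn import Adam, Tensor
from .smiles import TokenizedSmiles

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = ("cell_line", "drug", "response")


def validate_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Check a response table: required columns, unique (cell line, drug)."""
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"response table lacks column(s) {missing}")
    if table.empty:
        raise ValueError("response table is empty")
    if table.duplicated(["cell_line", "drug"]).any():
        raise ValueError("duplicate (cell_line, drug) pairs in response table")
    return table


@dataclass
class SplitSpec:
    """How to partition a response table."""

    strategy: str = "mixed"  # mixed | cell_blind | drug_blind
    test_fraction: float = 0.1
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("mixed", "cell_blind", "drug_blind"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def _entity_column(strategy: str) -> str | None:
    return {"cell_blind": "cell_line", "drug_blind": "drug"}.get(strategy)


def make_split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition rows into (train, test) according to the strategy.

    Blind strategies partition by entity first and then expand to rows,
    so the entity sets of the two sides are disjoint by construction.
    """
    validate_responses(table)
    rng = np.random.default_rng(spec.seed)
    col = _entity_column(spec.strategy)
    if col is None:  # mixed: row-level partition
        idx = rng.permutation(len(table))
        n_test = int(len(table) * spec.test_fraction)
        if n_test == 0 or n_test == len(table):
            raise ValueError("test fraction leaves an empty side")
        test = table.iloc[idx[:n_test]]
        train = table.iloc[idx[n_test:]]
        return train, test
    entities = np.array(sorted(table[col].unique()))
    if len(entities) < 2:
        raise ValueError(f"{spec.strategy} split needs >= 2 distinct {col}s")
    rng.shuffle(entities)
    n_test = max(1, int(round(len(entities) * spec.test_fraction)))
    if n_test >= len(entities):
        n_test = len(entities) - 1
    test_entities = set(entities[:n_test])
    mask = table[col].isin(test_entities)
    return table[~mask], table[mask]


def kfold(
    table: pd.DataFrame,
    k: int = 10,
    strategy: str = "mixed",
    seed: int = 0,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """k-fold partition of rows (mixed) or entities (blind strategies)."""
    validate_responses(table)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    col = _entity_column(strategy)
    folds = []
    if col is None:
        idx = rng.permutation(len(table))
        for part in np.array_split(idx, k):
            test = table.iloc[part]
            train = table.iloc[np.setdiff1d(idx, part)]
            folds.append((train, test))
        return folds
    entities = np.array(sorted(table[col].unique()))
    if k > len(entities):
        raise ValueError(f"k={k} exceeds the number of distinct {col}s ({len(entities)})")
    rng.shuffle(entities)
    for part in np.array_split(entities, k):
        mask = table[col].isin(set(part))
        folds.append((table[~mask], table[mask]))
    return folds


class ResponseDataset:
    """Joins pathway features, drug tokens, and responses into arrays."""

    def __init__(
        self,
        features: Mapping[str, PathwayFeatureMatrix],
        tokens: Mapping[str, TokenizedSmiles],
        responses: pd.DataFrame,
    ) -> None:
        self.features = dict(features)
        self.tokens = dict(tokens)
        self.responses = validate_responses(responses).reset_index(drop=True)
        self._feat_rows = {
            kind: {c: fm.values[i] for i, c in enumerate(fm.cell_lines)}
            for kind, fm in self.features.items()
        }
        for _, row in self.responses.iterrows():
            if row["drug"] not in self.tokens:
                raise KeyError(f"no token vector for drug {row['drug']!r}")
            for kind, rows in self._feat_rows.items():
                if row["cell_line"] not in rows:
                    raise KeyError(
                        f"no {kind} features for cell line {row['cell_line']!r}"
                    )

    @property
    def kinds(self) -> list[str]:
        return list(self.features)

    def omics_dims(self) -> dict[str, int]:
        return {k: len(fm.pathways) for k, fm in self.features.items()}

    def arrays(
        self, rows: pd.DataFrame
    ) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray, list[tuple[str, str]]]:
        codes = np.stack([self.tokens[d].codes for d in rows["drug"]])
        omics = {
            kind: np.stack([self._feat_rows[kind][c] for c in rows["cell_line"]])
            for kind in self.features
        }
        y = rows["response"].to_numpy(dtype=float)
        keys = list(zip(rows["cell_line"], rows["drug"]))
        return codes, omics, y, keys


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 512
    lr: float = 1e-3
    patience: int = 20
    seed: int = 0
    verbose: bool = False


def _loss(pred: Tensor, y: np.ndarray, head: str) -> Tensor:
    target = Tensor(y)
    if head == "classifier":
        eps = 1e-7
        p = pred * (1 - 2 * eps) + eps  # clamp away from {0,1}
        return -(target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()
    diff = pred - target
    return (diff * diff).mean()


def _eval_loss(model: DrugResponseModel, dataset: ResponseDataset,
               rows: pd.DataFrame, batch_size: int) -> float:
    y = rows["response"].to_numpy(dtype=float)
    preds = predict_rows(model, dataset, rows, batch_size)
    if model.config.head == "classifier":
        eps = 1e-7
        p = np.clip(preds, eps, 1 - eps)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    return float(((preds - y) ** 2).mean())


def predict_rows(
    model: DrugResponseModel,
    dataset: ResponseDataset,
    rows: pd.DataFrame,
    batch_size: int = 512,
) -> np.ndarray:
    codes, omics, _, _ = dataset.arrays(rows)
    preds = []
    for lo in range(0, len(codes), batch_size):
        hi = lo + batch_size
        preds.append(model.predict(codes[lo:hi], {k: v[lo:hi] for k, v in omics.items()}))
    return np.concatenate(preds)


def train(
    model: DrugResponseModel,
    dataset: ResponseDataset,
    train_rows: pd.DataFrame,
    val_rows: pd.DataFrame,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Minibatch gradient-descent training with early stopping.

    Minimizes MSE (regression head) or binary cross-entropy (classifier)
    with Adam; stops when the validation loss has not improved for
    ``patience`` epochs and restores the best parameters. Returns the
    per-epoch loss history. Fully reproducible given ``config.seed``.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    codes, omics, y, _ = dataset.arrays(train_rows)
    n = len(codes)
    best_val = math.inf
    best_state: dict | None = None
    best_bn: tuple[np.ndarray, np.ndarray] | None = None
    wait = 0
    history = []
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            batch = order[lo:lo + config.batch_size]
            pred, _ = model.forward(
                codes[batch], {k: v[batch] for k, v in omics.items()},
                return_attention=False,
            )
            loss = _loss(pred, y[batch], model.config.head)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}; "
                    "check feature scaling or lower the learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        epoch_loss /= n
        val_loss = _eval_loss(model, dataset, val_rows, config.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss}
        )
        if config.verbose:
            logger.info("epoch %d train %.4f val %.4f", epoch, epoch_loss, val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            best_bn = (model.bn.running_mean.copy(), model.bn.running_var.copy())
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
        model.bn.running_mean, model.bn.running_var = best_bn
    model.eval()
    return pd.DataFrame(history)


@dataclass
class MetricReport:
    """Evaluation metrics; regression and classifier fields as applicable."""

    mse: float | None = None
    rmse: float | None = None
    pcc: float | None = None
    r2: float | None = None
    aucpr: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items() if v is not None}


def average_precision(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (average-precision form)."""
    y_true = np.asarray(y_true, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    n_pos = y_true.sum()
    if n_pos == 0:
        return 0.0
    return float((precision * y).sum() / n_pos)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, head: str = "regression") -> MetricReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("cannot evaluate on zero rows")
    if head == "classifier":
        return MetricReport(aucpr=average_precision(y_true, y_pred), n=y_true.size)
    mse = float(((y_true - y_pred) ** 2).mean())
    report = MetricReport(mse=mse, rmse=math.sqrt(mse), n=y_true.size)
    if y_true.size >= 2 and np.std(y_true) > 0 and np.std(y_pred) > 0:
        report.pcc = float(pearsonr(y_true, y_pred).statistic)
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot > 0:
        report.r2 = 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot
    return report


def evaluate(
    model: DrugResponseModel,
    dataset: ResponseDataset,
    rows: pd.DataFrame,
    batch_size: int = 512,
) -> MetricReport:
    """Score eval-mode predictions on the given rows."""
    if rows.empty:
        raise ValueError("cannot evaluate on zero rows")
    preds = predict_rows(model, dataset, rows, batch_size)
    y = rows["response"].to_numpy(dtype=float)
    return compute_metrics(y, preds, model.config.head)


def aggregate_reports(reports: Sequence[MetricReport]) -> dict[str, dict[str, float]]:
    """Per-fold mean ± sd for each metric present in all reports."""
    out: dict[str, dict[str, float]] = {}
    for name in ("mse", "rmse", "pcc", "r2", "aucpr"):
        vals = [getattr(r, name) for r in reports]
        if all(v is not None for v in vals):
            arr = np.array(vals, dtype=float)
            out[name] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "per_fold": [float(v) for v in arr],
            }
    return out


def zscore_table(
    predictions: pd.DataFrame,
    axis: str,
    value_column: str = "prediction",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Standardize predictions along an axis and call sensitivity classes.

    ``axis`` is ``'per_cell_line'`` (compare drugs within a cell line) or
    ``'per_drug'`` (compare cell lines within a drug). Entries with
    z < −threshold are 'sensitive', z > threshold 'resistant', the rest
    'neutral'. Groups with zero spread get all-'neutral' calls and a
    warning.
    """
    group_col = {"per_cell_line": "cell_line", "per_drug": "drug"}.get(axis)
    if group_col is None:
        raise ValueError("axis must be 'per_cell_line' or 'per_drug'")
    out = predictions.copy()
    out["z"] = np.nan
    out["class"] = "neutral"
    for key, grp in out.groupby(group_col):
        vals = grp[value_column].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"axis group {key!r} has fewer than 2 values")
        sd = vals.std()
        if sd == 0:
            logger.warning("zero spread in group %r; all calls neutral", key)
            out.loc[grp.index, "z"] = 0.0
            continue
        z = (vals - vals.mean()) / sd
        out.loc[grp.index, "z"] = z
        out.loc[grp.index[z < -threshold], "class"] = "sensitive"
        out.loc[grp.index[z > threshold], "class"] = "resistant"
    return out
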