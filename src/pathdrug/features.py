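"""Pathway-difference feature matrices.

For every (cell line, pathway) pair one non-negative value is computed
that contrasts the omics signal over genes within the pathway against all
other universe genes:

* expression — the Mann–Whitney ``|log10 p|`` feature
  (:func:`pathdrug.stats.mann_whitney_diff`);
* mutation / cnv_ratio — the hybrid Pearson-χ²/G statistic on the
  within/outside × normal/altered contingency table.

The resulting cell-lines × pathways matrix is the omics input of the
prediction model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .genesets import GeneSetCollection
from .omics import OmicsMatrix
from .stats import (
    DEFAULT_EXACT_THRESHOLD,
    P_FLOOR,
    chi_square_g,
    cnv_contingency,
    mann_whitney_diff,
    mutation_contingency,
)

logger = logging.getLogger(__name__)


@dataclass
class FeatureConfig:
    """Switches for pathway-feature computation.

    mode
        Mann–Whitney branch selection ('auto', 'exact', 'asymptotic').
    exact_threshold
        min(n, m) at or below which mode='auto' uses the exact method.
    min_set_genes
        Pathways with fewer within-set genes present in the matrix yield a
        0 feature with a warning (a one-gene side makes the rank test
        degenerate).
    rounding
        Copy-number rounding at .5 boundaries ('half_even' or 'half_up').
    """

    mode: str = "auto"
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD
    min_set_genes: int = 2
    rounding: str = "half_even"
    tie_corrected: bool = False
    p_floor: float = P_FLOOR


@dataclass
class PathwayFeatureMatrix:
    """Cell lines × pathways difference values for one omics kind."""

    cell_lines: list[str]
    pathways: list[str]
    values: np.ndarray
    omics_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_lines), len(self.pathways)):
            raise ValueError("values shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("pathway features must be finite")
        if (self.values < 0).any():
            raise ValueError("pathway features must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_lines, columns=self.pathways)

    def row(self, cell_line: str) -> np.ndarray:
        return self.values[self.cell_lines.index(cell_line)]

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="cell_line")

    @classmethod
    def read_csv(cls, path: str | Path, omics_kind: str) -> "PathwayFeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            cell_lines=[str(c) for c in df.index],
            pathways=[str(p) for p in df.columns],
            values=df.to_numpy(dtype=float),
            omics_kind=omics_kind,
        )


def _membership(
    sets: GeneSetCollection, genes: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Boolean genes-present × pathways membership matrix.

    ``genes`` is restricted to the universe first; genes absent from the
    matrix are dropped from both sides of every test.
    """
    in_universe = [g for g in genes if g in set(sets.universe)]
    if not in_universe:
        raise ValueError("no overlap between matrix genes and the gene universe")
    idx = {g: i for i, g in enumerate(in_universe)}
    member = np.zeros((len(in_universe), len(sets)), dtype=bool)
    for k, name in enumerate(sets.names):
        for g in sets.sets[name]:
            i = idx.get(g)
            if i is not None:
                member[i, k] = True
    return member, in_universe


def _expression_features(
    values: np.ndarray, member: np.ndarray, config: FeatureConfig
) -> np.ndarray:
    """Vectorized Mann–Whitney features for all (cell line, pathway) pairs.

    Ranks are computed once per cell line over the pooled universe genes;
    per pathway the within rank-sum then gives U1 directly. Pathways that
    fall in the exact branch are recomputed through the scalar routine so
    both paths share one implementation of the exact null.
    """
    n_cl, n_genes = values.shape
    n_k = member.sum(axis=0).astype(float)  # within-set genes present
    m_k = n_genes - n_k
    out = np.zeros((n_cl, member.shape[1]))
    testable = n_k >= config.min_set_genes
    for name_idx in np.flatnonzero(~testable):
        logger.warning(
            "pathway column %d has fewer than %d genes present; feature set to 0",
            name_idx, config.min_set_genes,
        )
    for i in range(n_cl):
        row = values[i]
        ranks = rankdata(row)
        has_ties = np.unique(row).size < row.size
        r1 = ranks @ member
        u1 = r1 - n_k * (n_k + 1) / 2.0
        u2 = n_k * m_k - u1
        u = np.maximum(u1, u2)
        mu = n_k * m_k / 2.0
        sigma = np.sqrt(n_k * m_k * (n_k + m_k + 1) / 12.0)
        exact_mask = np.zeros_like(testable)
        if config.mode != "asymptotic" and not has_ties:
            small = np.minimum(n_k, m_k) <= config.exact_threshold
            exact_mask = testable & (small if config.mode == "auto" else np.ones_like(small))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sigma > 0, (u - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
        p = np.minimum(2.0 * norm.sf(z), 1.0)
        feat = np.abs(np.log10(np.maximum(p, config.p_floor)))
        feat[~testable] = 0.0
        for k in np.flatnonzero(exact_mask):
            res = mann_whitney_diff(
                row[member[:, k]], row[~member[:, k]],
                mode=config.mode, exact_threshold=config.exact_threshold,
                tie_corrected=config.tie_corrected, p_floor=config.p_floor,
            )
            feat[k] = res.feature
        out[i] = feat
    return out


def compute_pathway_features(
    omics: OmicsMatrix,
    sets: GeneSetCollection,
    config: FeatureConfig | None = None,
) -> PathwayFeatureMatrix:
    """Compute the cell-lines × pathways difference-feature matrix.

    Column order follows the gene-set collection order. Pathways with
    fewer than ``config.min_set_genes`` genes present yield 0.
    """
    config = config or FeatureConfig()
    member, genes_present = _membership(sets, omics.genes)
    gene_idx = [omics.genes.index(g) for g in genes_present]
    values = omics.values[:, gene_idx]

    if omics.kind == "expression":
        feats = _expression_features(values, member, config)
    elif omics.kind in ("mutation", "cnv_ratio"):
        n_cl = values.shape[0]
        feats = np.zeros((n_cl, member.shape[1]))
        n_k = member.sum(axis=0)
        for i in range(n_cl):
            statuses = dict(zip(genes_present, values[i]))
            for k, name in enumerate(sets.names):
                if n_k[k] < config.min_set_genes:
                    if i == 0:
                        logger.warning(
                            "pathway %r has fewer than %d genes present; feature set to 0",
                            name, config.min_set_genes,
                        )
                    continue
                if omics.kind == "mutation":
                    table = mutation_contingency(
                        statuses, sets.sets[name], genes_present, set_name=name
                    )
                else:
                    table = cnv_contingency(
                        statuses, omics.ploidy[omics.cell_lines[i]],
                        sets.sets[name], genes_present,
                        set_name=name, rounding=config.rounding,
                    )
                feats[i, k] = chi_square_g(table)
    else:  # pragma: no cover - OmicsMatrix already validates kind
        raise ValueError(f"unsupported omics kind {omics.kind!r}")

    return PathwayFeatureMatrix(
        cell_lines=list(omics.cell_lines),
        pathways=sets.names,
        values=feats,
        omics_kind=omics.kind,
    )
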