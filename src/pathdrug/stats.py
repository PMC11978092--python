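"""Bespoke statistics behind the pathway-difference features.

Two procedures are implemented:

* :func:`mann_whitney_diff` — a two-sided Mann–Whitney U comparison of an
  omics quantity over genes within a pathway versus all other universe
  genes, converted to a non-negative feature via ``|log10 p|``. The U
  statistic is ``U = max(U1, U2)`` with ``U1 = R1 − n(n+1)/2`` (R1 the sum
  of pooled average ranks on the within side) and ``U2 = nm − U1``. The
  p-value uses the normal approximation
  ``p = 2·SF_N((U − nm/2) / sqrt(nm(n+m+1)/12))`` for large samples, or the
  exact null distribution of U (no-ties case) for small ones.

* :func:`chi_square_g` — a hybrid independence statistic on a 2×2
  within/outside × normal/altered contingency table: Pearson's
  ``Σ(O−E)²/E`` when every expected count exceeds 5, the likelihood-ratio
  ``G = 2·Σ O·ln(O/E)`` otherwise, and exactly 0 when any expected count is
  zero. The statistic itself (not a p-value) is the feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

#: Smallest p-value allowed before the |log10 p| transform, keeping
#: features finite for arbitrarily extreme separations.
P_FLOOR = 1e-300

#: Largest min(n, m) for which mode='auto' uses the exact null distribution.
DEFAULT_EXACT_THRESHOLD = 8


@dataclass(frozen=True)
class UTestResult:
    """Outcome of one within/outside Mann–Whitney comparison."""

    U1: float
    U2: float
    U: float
    method_used: str  # 'asymptotic' or 'exact'
    p: float
    feature: float


from functools import lru_cache


@lru_cache(maxsize=128)
def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Null distribution of U1 for sample sizes (n, m), as counts.

    ``counts[u]`` is the number of the C(n+m, n) equally likely rank
    assignments with U1 = u, built by the classical recursion
    ``f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u)`` (no ties): the largest
    pooled observation is either a within value (beats all m outside
    values) or an outside value.
    """
    umax = n * m
    # rows[i] holds f(i, j, ·) while j sweeps 0..m; at j=0, U1 must be 0.
    rows = [np.zeros(umax + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        rows[i][0] = 1.0
    for j in range(1, m + 1):
        for i in range(1, n + 1):
            new = rows[i].copy()  # f(i, j-1, u)
            new[j:] += rows[i - 1][:-j]  # f(i-1, j, u-j); rows[i-1] is at j already
            rows[i] = new
    counts = rows[n]
    counts.setflags(write=False)
    return counts


def exact_u_sf(u: float, n: int, m: int) -> float:
    """P(U1 >= u) under the exact no-ties null for sizes (n, m)."""
    counts = _exact_u_counts(n, m)
    total = counts.sum()
    lo = int(math.ceil(u))
    if lo <= 0:
        return 1.0
    if lo > n * m:
        return 0.0
    return float(counts[lo:].sum() / total)


def _feature_from_p(p: float, p_floor: float) -> float:
    return abs(math.log10(max(p, p_floor)))


def mann_whitney_diff(
    within: Sequence[float] | np.ndarray,
    outside: Sequence[float] | np.ndarray,
    mode: str = "auto",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    tie_corrected: bool = False,
    p_floor: float = P_FLOOR,
) -> UTestResult:
    """Two-sided Mann–Whitney U comparison, returned as a feature.

    Parameters
    ----------
    within, outside
        Observed values for the genes inside and outside the gene set.
    mode
        ``'asymptotic'``, ``'exact'``, or ``'auto'`` (exact when
        ``min(n, m) <= exact_threshold`` and the pooled sample is tie-free,
        asymptotic otherwise). ``mode='exact'`` with ties falls back to the
        asymptotic branch with a logged warning.
    tie_corrected
        Apply the tie correction to the null standard deviation of U.
        Off by default: the plain ``sqrt(nm(n+m+1)/12)`` form is used.
    p_floor
        Floor applied to p before ``|log10 p|`` so the feature is finite.
    """
    a = np.asarray(within, dtype=float)
    b = np.asarray(outside, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both the within and outside samples must be non-empty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    has_ties = np.unique(pooled).size < pooled.size

    r1 = float(ranks[:n].sum())
    u1 = r1 - n * (n + 1) / 2.0
    u2 = n * m - u1
    u = max(u1, u2)

    use_exact = mode == "exact" or (mode == "auto" and min(n, m) <= exact_threshold)
    if use_exact and has_ties:
        if mode == "exact":
            logger.warning(
                "exact Mann-Whitney requested but pooled sample has ties; "
                "falling back to the asymptotic method"
            )
        use_exact = False

    if use_exact:
        p = 2.0 * exact_u_sf(u, n, m)
        method = "exact"
    else:
        mu = n * m / 2.0
        if tie_corrected:
            N = n + m
            _, t = np.unique(pooled, return_counts=True)
            tie_term = ((t**3 - t).sum()) / (N * (N - 1)) if N > 1 else 0.0
            var = n * m / 12.0 * ((N + 1) - tie_term)
        else:
            var = n * m * (n + m + 1) / 12.0
        sigma = math.sqrt(var)
        z = 0.0 if sigma == 0 else (u - mu) / sigma
        p = 2.0 * float(norm.sf(z))
        method = "asymptotic"

    p = min(p, 1.0)
    p = max(p, 0.0)
    return UTestResult(
        U1=u1, U2=u2, U=u, method_used=method, p=p,
        feature=_feature_from_p(p, p_floor),
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Within/outside × normal/altered gene counts.

    Rows are gene location (within the set, outside the set); columns are
    gene property (normal, altered). All cells are non-negative counts.
    """

    a: int  # within, normal
    b: int  # within, altered
    c: int  # outside, normal
    d: int  # outside, altered

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"contingency cell {name} is negative: {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n_within(self) -> int:
        return self.a + self.b

    @property
    def n_outside(self) -> int:
        return self.c + self.d


def chi_square_g(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Hybrid Pearson-χ² / G statistic for a 2×2 table.

    Expected counts come from the margins. Any zero expected count returns
    0 exactly; all expected counts above 5 selects Pearson's χ²; otherwise
    the likelihood-ratio G-test is used, with ``0·ln(0/E)`` taken as 0.
    """
    if isinstance(table, ContingencyTable2x2):
        obs = table.as_array()
    else:
        obs = np.asarray(table, dtype=float)
        if obs.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
        if (obs < 0).any():
            raise ValueError("contingency cells must be non-negative")
    total = obs.sum()
    if total == 0:
        return 0.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        return 0.0
    if expected.min() > 5.0:
        return float(((obs - expected) ** 2 / expected).sum())
    nz = obs > 0
    return float(2.0 * (obs[nz] * np.log(obs[nz] / expected[nz])).sum())


def _split_statuses(
    values: Mapping[str, float],
    gene_set: Iterable[str],
    universe: Sequence[str],
    set_name: str | None = None,
) -> tuple[list[float], list[float]]:
    """Partition per-gene values into within/outside lists.

    Genes outside the universe are ignored; universe genes missing from
    ``values`` are dropped from both sides.
    """
    members = set(gene_set)
    within = [values[g] for g in universe if g in members and g in values]
    outside = [values[g] for g in universe if g not in members and g in values]
    if not within:
        label = f" {set_name!r}" if set_name else ""
        raise ValueError(f"gene set{label} has no genes in the universe/matrix")
    return within, outside


def mutation_contingency(
    statuses: Mapping[str, float],
    gene_set: Iterable[str],
    universe: Sequence[str],
    set_name: str | None = None,
) -> ContingencyTable2x2:
    """Tally damaging-mutation statuses into the within/outside table.

    A gene is "mutant" when its status code is 1 or 2 and "normal" at 0.
    """
    within, outside = _split_statuses(statuses, gene_set, universe, set_name)
    wi = np.asarray(within)
    ou = np.asarray(outside)
    return ContingencyTable2x2(
        a=int((wi == 0).sum()),
        b=int((wi >= 1).sum()),
        c=int((ou == 0).sum()),
        d=int((ou >= 1).sum()),
    )


def absolute_copy_number(
    ratios: np.ndarray, ploidy: float, rounding: str = "half_even"
) -> np.ndarray:
    """Absolute copy number = round(ploidy × ratio), per gene."""
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    x = np.asarray(ratios, dtype=float) * ploidy
    if rounding == "half_even":
        return np.rint(x)
    if rounding == "half_up":
        return np.floor(x + 0.5)
    raise ValueError(f"unknown rounding {rounding!r}")


def cnv_contingency(
    ratios: Mapping[str, float],
    ploidy: float,
    gene_set: Iterable[str],
    universe: Sequence[str],
    set_name: str | None = None,
    rounding: str = "half_even",
) -> ContingencyTable2x2:
    """Tally copy-number categories into the within/outside table.

    Ratios are converted to absolute copy numbers via
    ``round(ploidy × ratio)``; an absolute copy number of 2 is "normal",
    ≤ 1 ("deleted") or ≥ 3 ("amplified") counts as altered.
    """
    within, outside = _split_statuses(ratios, gene_set, universe, set_name)

    def _counts(vals: list[float]) -> tuple[int, int]:
        absolute = absolute_copy_number(np.asarray(vals), ploidy, rounding)
        normal = int((absolute == 2).sum())
        altered = int(((absolute <= 1) | (absolute >= 3)).sum())
        return normal, altered

    a, b = _counts(within)
    c, d = _counts(outside)
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)
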