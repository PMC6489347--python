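"""Agreement statistics for ordinal category assignments.

The battery applied to every food group × method pair × stratum:

* tie-corrected Spearman rank correlation (Pearson on mid-ranks) with a
  Fisher-z 95% confidence interval and two-sided p-value;
* cross-classification percentages — exact agreement, exact + adjacent,
  and extreme disagreement (the two opposite-corner cells);
* linearly weighted Cohen kappa with its asymptotic standard error under
  the null hypothesis of chance agreement;
* the five pass/fail comparison criteria and the per-group average row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import AgreementSummary, CriteriaVerdict, UndefinedStatisticError

__all__ = [
    "CrossTable",
    "SpearmanResult",
    "KappaResult",
    "CrossClassification",
    "spearman",
    "cross_table",
    "cross_classification",
    "linear_weights",
    "quadratic_weights",
    "weighted_kappa",
    "evaluate_criteria",
    "average_over_groups",
]

# Criteria thresholds (all inclusive, matching the ≥/≤ comparison symbols).
SCC_THRESHOLD = 0.5
EXACT_THRESHOLD = 35.0
ADJACENT_THRESHOLD = 75.0
EXTREME_THRESHOLD = 8.0
KAPPA_THRESHOLD = 0.41


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se0: float
    p: float


@dataclass(frozen=True)
class CrossClassification:
    exact_pct: float
    exact_adjacent_pct: float
    extreme_pct: float


@dataclass
class CrossTable:
    """k×k contingency table of (method-1 level, method-2 level) counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("cross table must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if self.counts.sum() == 0:
            raise ValueError("cross table must contain at least one pair")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _midranks(v: np.ndarray) -> np.ndarray:
    """Mid-ranks (average rank for ties), 1-based."""
    return sps.rankdata(v, method="average")


def spearman(x: Sequence[int], y: Sequence[int]) -> SpearmanResult:
    """Tie-corrected Spearman correlation with Fisher-z CI and p-value.

    rho is the Pearson correlation of mid-ranks.  The 95% CI uses the Fisher
    z transform with standard error 1/sqrt(n-3); the two-sided p comes from
    the z statistic atanh(rho)*sqrt(n-3).

    Raises :class:`UndefinedStatisticError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError(
            "Spearman correlation undefined for a constant vector"
        )
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    se = 1.0 / math.sqrt(n - 3)
    if abs(rho) >= 1.0:
        z = math.inf if rho > 0 else -math.inf
        ci_low, ci_high = rho, rho
        p = 0.0
    else:
        z = math.atanh(rho)
        ci_low = math.tanh(z - 1.959963984540054 * se)
        ci_high = math.tanh(z + 1.959963984540054 * se)
        p = 2.0 * sps.norm.sf(abs(z) / se)
    return SpearmanResult(rho=rho, ci_low=ci_low, ci_high=ci_high, p=float(p), n=n)


def cross_table(x: Sequence[int], y: Sequence[int], k: int) -> CrossTable:
    """Contingency table of co-assigned levels (both vectors in 1..k)."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size == 0:
        raise ValueError("need at least one pair")
    for v, name in ((x, "x"), (y, "y")):
        if v.min() < 1 or v.max() > k:
            raise ValueError(f"{name} contains levels outside 1..{k}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (x - 1, y - 1), 1)
    return CrossTable(counts)


def cross_classification(t: CrossTable) -> CrossClassification:
    """Exact, exact+adjacent and extreme-disagreement percentages.

    Extreme disagreement counts only the two opposite-corner cells, i.e.
    pairs assigned level 1 by one method and level k by the other.
    """
    k, n = t.k, t.n
    i, j = np.indices((k, k))
    d = np.abs(i - j)
    exact = t.counts[d == 0].sum()
    adjacent = t.counts[d <= 1].sum()
    extreme = int(t.counts[0, k - 1]) + int(t.counts[k - 1, 0])
    return CrossClassification(
        exact_pct=float(100.0 * exact / n),
        exact_adjacent_pct=float(100.0 * adjacent / n),
        extreme_pct=float(100.0 * extreme / n),
    )


def linear_weights(k: int) -> np.ndarray:
    """Linear agreement weights w_ij = 1 − |i−j|/(k−1) (Stata's ``w``)."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    i, j = np.indices((k, k))
    return 1.0 - np.abs(i - j) / (k - 1)


def quadratic_weights(k: int) -> np.ndarray:
    """Quadratic agreement weights w_ij = 1 − (i−j)²/(k−1)² (Stata's ``w2``)."""
    if k < 2:
        raise ValueError("need at least 2 levels")
    i, j = np.indices((k, k))
    return 1.0 - ((i - j) / (k - 1)) ** 2


def _check_weights(w: np.ndarray, k: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (k, k):
        raise ValueError(f"weights must be {k}x{k}")
    if not np.allclose(w, w.T):
        raise ValueError("weights must be symmetric")
    if not np.allclose(np.diag(w), 1.0):
        raise ValueError("diagonal weights must equal 1")
    if (w < -1e-12).any() or (w > 1 + 1e-12).any():
        raise ValueError("weights must lie in [0, 1]")
    return w


def weighted_kappa(t: CrossTable, w: np.ndarray | None = None) -> KappaResult:
    """Weighted Cohen kappa with the null-hypothesis asymptotic SE.

    kappa = (po − pe) / (1 − pe) with po = Σ w_ij p_ij and
    pe = Σ w_ij p_i· p_·j.  The standard error under H0: kappa = 0 is the
    Fleiss–Cohen–Everitt form; the reported p is the one-sided normal test
    of kappa / se0.
    """
    if w is None:
        w = linear_weights(t.k)
    w = _check_weights(w, t.k)
    p = t.counts / t.n
    pi = p.sum(axis=1)  # method-1 marginals
    pj = p.sum(axis=0)  # method-2 marginals
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, pj)).sum())
    if abs(1.0 - pe) < 1e-12:
        raise UndefinedStatisticError(
            "weighted kappa undefined: chance agreement equals 1"
        )
    kappa = (po - pe) / (1.0 - pe)
    # H0 variance: [ sum_ij pi_i p_j (w_ij - (wbar_i. + wbar_.j))^2 - pe^2 ]
    # / ( n (1-pe)^2 )
    wbar_i = w @ pj  # row-wise expected weight
    wbar_j = pi @ w  # column-wise expected weight
    term = (w - (wbar_i[:, None] + wbar_j[None, :])) ** 2
    var0 = (float((np.outer(pi, pj) * term).sum()) - pe**2) / (t.n * (1.0 - pe) ** 2)
    se0 = math.sqrt(max(var0, 0.0))
    p_value = float(sps.norm.sf(kappa / se0)) if se0 > 0 else (0.0 if kappa > 0 else 1.0)
    return KappaResult(kappa=float(kappa), se0=se0, p=p_value)


def evaluate_criteria(s: AgreementSummary) -> CriteriaVerdict:
    """Apply the five comparison criteria to a summary row (inclusive bounds)."""
    for fld in ("scc", "exact_pct", "exact_adjacent_pct", "extreme_pct", "kappa_w"):
        if getattr(s, fld) is None:
            raise ValueError(f"summary is missing {fld}; cannot evaluate criteria")
    return CriteriaVerdict(
        scc_ok=bool(s.scc >= SCC_THRESHOLD),
        exact_ok=bool(s.exact_pct >= EXACT_THRESHOLD),
        adjacent_ok=bool(s.exact_adjacent_pct >= ADJACENT_THRESHOLD),
        extreme_ok=bool(s.extreme_pct <= EXTREME_THRESHOLD),
        kappa_ok=bool(s.kappa_w >= KAPPA_THRESHOLD),
    )


def average_over_groups(summaries: Sequence[AgreementSummary]) -> AgreementSummary:
    """Unweighted mean of each statistic across food groups ("Average" row).

    Groups with an undefined statistic are excluded from that statistic's
    mean.  No confidence interval, p-value or standard error is attached to
    the average (the report tables print a dash there).
    """
    rows = list(summaries)
    if not rows:
        raise ValueError("need at least one per-group summary")
    pair = rows[0].method_pair
    stratum = rows[0].stratum
    if any(r.method_pair != pair or r.stratum != stratum for r in rows):
        raise ValueError("summaries must share method pair and stratum")

    def _mean(fld: str) -> float | None:
        vals = [getattr(r, fld) for r in rows if getattr(r, fld) is not None]
        return float(np.mean(vals)) if vals else None

    return AgreementSummary(
        food_group="average",
        method_pair=pair,
        stratum=stratum,
        n=rows[0].n,
        scc=_mean("scc"),
        exact_pct=_mean("exact_pct"),
        exact_adjacent_pct=_mean("exact_adjacent_pct"),
        extreme_pct=_mean("extreme_pct"),
        kappa_w=_mean("kappa_w"),
    )
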