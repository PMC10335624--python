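"""Spearman rank correlation of screening outcomes against simulator scores.

The screening study compared its T:R descriptors with the manufacturer
simulator on three variable pairs:

* pair A — ``mean T:R + SD(T:R)`` against ``mean score + SD(score)``,
* pair B — ``mean T:R + SD(T:R)`` against EVT,
* pair C — FRT against EVT,

where "+" is the literal arithmetic sum of the two columns (it is the
x-axis of the study's scatter plots).  A favourable T:R is *low* while a
favourable score or EVT is *high*, so pairs A and B are monotone
decreasing and pair C increasing; results therefore carry both the
signed coefficient and its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ParameterError

__all__ = [
    "PairedVectorRecord",
    "CorrelationResult",
    "PAIR_NAMES",
    "spearman",
    "study_pairs",
]

#: The three study variable pairs, in presentation order.
PAIR_NAMES = ("tr_sum_vs_score_sum", "tr_sum_vs_evt", "frt_vs_evt")


@dataclass
class PairedVectorRecord:
    """One vector's descriptors from both tools, for correlation."""

    patient_id: str
    vector: str
    mean_tr: float
    sd_tr: float
    frt_pct: float
    mean_score: float
    sd_score: float
    evt_pct: float

    def __post_init__(self) -> None:
        if self.vector not in ("primary", "alternate"):
            raise ParameterError(f"vector must be primary/alternate, got {self.vector!r}")
        for name in ("mean_tr", "sd_tr", "frt_pct", "mean_score", "sd_score", "evt_pct"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")


@dataclass
class CorrelationResult:
    """Spearman coefficient for one variable pair."""

    pair_name: str
    rho: float
    abs_rho: float
    p_value: float
    n: int


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties given their average rank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    pair_name: str = "",
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman's rank correlation with average-rank tie handling.

    The coefficient is the Pearson correlation of the two rank vectors.
    The default p-value uses the two-sided t approximation with ``n - 2``
    degrees of freedom; ``method="permutation"`` gives a seeded exact-style
    permutation p-value instead, useful at small n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ParameterError("Spearman correlation needs n >= 3")

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        ra, rb = _average_ranks(a), _average_ranks(b)
        ra = ra - ra.mean()
        rb = rb - rb.mean()
        denom = np.sqrt((ra**2).sum() * (rb**2).sum())
        if denom == 0:
            raise ParameterError("constant input: rank correlation undefined")
        return float((ra * rb).sum() / denom)

    rho = _rho(x, y)
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * _stats.t.sf(abs(t), df=n - 2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = sum(
            abs(_rho(x, rng.permutation(y))) >= abs(rho) - 1e-12
            for _ in range(n_permutations)
        )
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ParameterError(f"unknown p-value method {method!r}")
    return CorrelationResult(pair_name=pair_name, rho=rho, abs_rho=abs(rho), p_value=p, n=n)


def study_pairs(
    records: Sequence[PairedVectorRecord] | pd.DataFrame,
    method: str = "t",
) -> dict[str, CorrelationResult]:
    """Run the three study correlations on paired per-vector records."""
    if isinstance(records, pd.DataFrame):
        df = records
        required = {"mean_tr", "sd_tr", "frt_pct", "mean_score", "sd_score", "evt_pct"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"records missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame([vars(r) for r in records])
        if df.empty:
            raise ParameterError("no records given")
    if len(df) < 3:
        raise ParameterError("need at least 3 records")
    tr_sum = df["mean_tr"].to_numpy() + df["sd_tr"].to_numpy()
    score_sum = df["mean_score"].to_numpy() + df["sd_score"].to_numpy()
    evt = df["evt_pct"].to_numpy()
    frt = df["frt_pct"].to_numpy()
    return {
        "tr_sum_vs_score_sum": spearman(tr_sum, score_sum, "tr_sum_vs_score_sum", method),
        "tr_sum_vs_evt": spearman(tr_sum, evt, "tr_sum_vs_evt", method),
        "frt_vs_evt": spearman(frt, evt, "frt_vs_evt", method),
    }
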