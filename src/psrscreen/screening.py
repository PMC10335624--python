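"""Per-vector screening descriptors: mean T:R, SD, FRT, EVT, group summaries.

Favorable ratio time (FRT) is the fraction of 10 s segments whose T:R
ratio sits below the eligibility cutoff, as a percentage of the whole
recording; eligible vector time (EVT) is the percentage of simulator
assessments with a passing vector score.  The cutoff defaults to the
manual-screening rule of 1:3, stored as the exact fraction.  Segments
exactly at the cutoff count as over-threshold (conservative for
eligibility).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ParameterError
from .series import TrSeries
from .synth import SimulatorSeries

__all__ = [
    "ScreeningConfig",
    "VectorSummary",
    "EvtSummary",
    "GroupSummary",
    "summarize_vector",
    "compute_evt",
    "group_summary",
    "paired_wilcoxon",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningConfig:
    """Eligibility cutoff and segment length for screening statistics."""

    tr_threshold: Fraction = Fraction(1, 3)
    segment_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < float(self.tr_threshold) < 1.5):
            raise ParameterError("tr_threshold must lie in (0, 1.5)")


@dataclass
class VectorSummary:
    """One vector's screening descriptors (one table row)."""

    mean_tr: float
    sd_tr: float
    n_over: int
    n_below: int
    frt_pct: float
    n_missing: int = 0
    vector_label: str = ""
    patient_id: str = ""

    @property
    def n_segments(self) -> int:
        return self.n_over + self.n_below


@dataclass
class EvtSummary:
    """Eligible vector time for one vector."""

    evt_pct: float
    n_assessments: int
    vector_label: str = ""
    patient_id: str = ""


@dataclass
class GroupSummary:
    """Mean with spread for one vector group (primary/alternate/combined).

    ``halfwidth_95ci`` is the normal-approximation 95% confidence
    halfwidth ``1.96 * SD / sqrt(n)``; ``sd`` is the sample standard
    deviation (n-1 denominator).  Reports state which convention a
    printed "±" uses.
    """

    group: str
    mean: float
    halfwidth_95ci: float
    sd: float
    n: int


def summarize_vector(series: TrSeries, cfg: ScreeningConfig = ScreeningConfig()) -> VectorSummary:
    """Mean, SD, threshold counts and FRT for one vector's T:R series.

    FRT = 100 * (segments with T:R below the cutoff) / (total segments).
    Missing-value (NaN) segments are excluded from every statistic and
    counted separately.
    """
    if len(series) == 0:
        raise ParameterError("cannot summarise an empty series")
    vals = series.values[np.isfinite(series.values)]
    n_missing = len(series) - vals.size
    if n_missing:
        logger.info(
            "%s/%s: excluding %d segments with missing T:R",
            series.patient_id, series.vector_label, n_missing,
        )
    if vals.size == 0:
        raise ParameterError("all segments in the series are missing")
    thr = float(cfg.tr_threshold)
    n_below = int((vals < thr).sum())
    n_over = vals.size - n_below
    return VectorSummary(
        mean_tr=float(vals.mean()),
        sd_tr=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_over=n_over,
        n_below=n_below,
        frt_pct=100.0 * n_below / vals.size,
        n_missing=n_missing,
        vector_label=series.vector_label,
        patient_id=series.patient_id,
    )


def compute_evt(sim: SimulatorSeries) -> EvtSummary:
    """Percentage of assessments with a passing vector score."""
    if len(sim) == 0:
        raise ParameterError("cannot compute EVT of an empty series")
    return EvtSummary(
        evt_pct=100.0 * float(sim.passed.sum()) / len(sim),
        n_assessments=len(sim),
        vector_label=sim.vector_label,
        patient_id=sim.patient_id,
    )


def group_summary(
    values: Sequence[float] | Mapping[str, float],
    groups: Sequence[str] | Mapping[str, str] | None = None,
) -> dict[str, GroupSummary]:
    """Per-group means for primary / alternate vectors plus their union.

    ``values`` may be a mapping ``{vector_id: value}`` with ``groups``
    mapping each vector id to ``"primary"`` or ``"alternate"``, or two
    aligned sequences.  The combined group is always the union of both.
    """
    if isinstance(values, Mapping):
        keys = list(values)
        vals = np.array([values[k] for k in keys], dtype=float)
        if groups is None:
            raise ParameterError("groups mapping required with mapping input")
        grp = np.array([groups[k] for k in keys])
    else:
        vals = np.asarray(values, dtype=float)
        grp = np.asarray(list(groups if groups is not None else []), dtype=object)
        if grp.size != vals.size:
            raise ParameterError("values and groups must align")
    bad = set(grp) - {"primary", "alternate"}
    if bad:
        raise ParameterError(f"unknown groups: {sorted(bad)}")

    out: dict[str, GroupSummary] = {}
    for name, mask in (
        ("primary", grp == "primary"),
        ("alternate", grp == "alternate"),
        ("combined", np.ones(vals.size, dtype=bool)),
    ):
        v = vals[mask]
        if v.size == 0:
            raise ParameterError(f"group {name!r} is empty")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        out[name] = GroupSummary(
            group=name,
            mean=float(v.mean()),
            halfwidth_95ci=1.96 * sd / np.sqrt(v.size),
            sd=sd,
            n=int(v.size),
        )
    return out


def paired_wilcoxon(primary: Sequence[float], alternate: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for a group contrast.

    Offered for descriptive comparisons between paired vector groups; the
    choice of test for such contrasts is a convention, not a reproduction
    target.
    """
    res = _stats.wilcoxon(np.asarray(primary, float), np.asarray(alternate, float))
    return float(res.pvalue)


def summaries_to_frame(
    vector_summaries: Sequence[VectorSummary],
    evt_summaries: Sequence[EvtSummary] | None = None,
    score_stats: Mapping[tuple[str, str], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Tabulate per-vector results in the screening-study column layout.

    Columns: patient, vector, mean T:R, SD, over/below counts, FRT, and —
    when simulator data is present — mean score, score SD and EVT keyed by
    ``(patient_id, vector_label)``.
    """
    rows = []
    evt_by_key = {
        (e.patient_id, e.vector_label): e for e in (evt_summaries or [])
    }
    for s in vector_summaries:
        row = {
            "patient": s.patient_id,
            "vector": s.vector_label,
            "mean_tr": s.mean_tr,
            "sd_tr": s.sd_tr,
            "n_over": s.n_over,
            "n_below": s.n_below,
            "frt_pct": round(s.frt_pct, 2),
        }
        key = (s.patient_id, s.vector_label)
        if score_stats and key in score_stats:
            row["mean_score"], row["sd_score"] = score_stats[key]
        if key in evt_by_key:
            row["evt_pct"] = round(evt_by_key[key].evt_pct, 2)
        rows.append(row)
    return pd.DataFrame(rows)
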