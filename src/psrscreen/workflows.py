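"""End-to-end synthetic screening workflows.

Convenience layers that chain the generator, imaging, regression and
screening stages the way a screening study would run them: build a
seeded corpus of recordings with known T:R ground truth, train the
regressor on some recordings and hold others out, then screen held-out
vectors and correlate against the surrogate simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .correlation import PairedVectorRecord
from .psr import images_for_segments, segment_recording
from .regression import CnnConfig, TrainingReport, TrSeries, build_model, predict_tr, train
from .screening import ScreeningConfig, compute_evt, summarize_vector
from .synth import (
    BeatParams,
    EcgRecording,
    Regime,
    RegimeSchedule,
    SimulatorSeries,
    generate_recording,
    generate_simulator_series,
)

__all__ = [
    "ramp_schedule",
    "SyntheticDataset",
    "build_dataset",
    "train_regressor",
    "block_records",
]


def ramp_schedule(
    ratios: Sequence[float],
    step_s: float = 40.0,
    r_amp: float = 1.0,
    heart_rate: float = 60.0,
    noise_sd: float = 0.0,
    wander_amp: float = 0.0,
) -> RegimeSchedule:
    """Piecewise-constant schedule visiting the given T:R ratios in order.

    Each ratio holds for ``step_s`` seconds; aligning ``step_s`` with a
    multiple of the 10 s segment length keeps every segment's truth
    unambiguous.
    """
    regimes = [
        Regime(
            start_s=i * step_s,
            beat=BeatParams(r_amp=r_amp, t_amp=r * r_amp, heart_rate=heart_rate),
            noise_sd=noise_sd,
            wander_amp=wander_amp,
        )
        for i, r in enumerate(ratios)
    ]
    return RegimeSchedule(regimes)


@dataclass
class SyntheticDataset:
    """Images and ground-truth labels for a corpus of synthetic recordings."""

    images: np.ndarray          # (n_segments, res, res)
    labels: np.ndarray          # ground-truth T:R per segment
    recording_ids: np.ndarray   # which recording each segment came from
    recordings: list[EcgRecording]
    truths: list[dict[str, TrSeries]]

    def split(self, held_out: Sequence[int]) -> tuple["SyntheticDataset", "SyntheticDataset"]:
        """Split by recording (never by segment) to avoid leakage."""
        held = np.isin(self.recording_ids, list(held_out))
        def _take(mask):
            return SyntheticDataset(
                self.images[mask], self.labels[mask], self.recording_ids[mask],
                self.recordings, self.truths,
            )
        return _take(~held), _take(held)


def build_dataset(
    schedules_per_recording: Sequence[dict[str, RegimeSchedule]],
    duration_s: float,
    fs: float = 500.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate recordings and convert every segment to a PSR image."""
    images, labels, rec_ids, recs, truths = [], [], [], [], []
    for i, schedules in enumerate(schedules_per_recording):
        rec, truth = generate_recording(
            schedules, duration_s, fs=fs, seed=seed + i, patient_id=f"syn{i:02d}"
        )
        recs.append(rec)
        truths.append(truth)
        segs = segment_recording(rec)
        for label, seg_list in segs.items():
            images.append(images_for_segments(seg_list))
            labels.append(truth[label].values[: len(seg_list)])
            rec_ids.append(np.full(len(seg_list), i))
    return SyntheticDataset(
        np.concatenate(images),
        np.concatenate(labels),
        np.concatenate(rec_ids),
        recs,
        truths,
    )


def train_regressor(
    dataset: SyntheticDataset,
    cfg: CnnConfig,
    held_out: Sequence[int] = (),
):
    """Train on all recordings except ``held_out``; validate on those.

    Returns ``(model, report, train_split, test_split)``.
    """
    train_ds, test_ds = dataset.split(held_out)
    model = build_model(cfg)
    report = train(
        model, train_ds.images, train_ds.labels, cfg,
        val_images=test_ds.images if len(test_ds.labels) else None,
        val_labels=test_ds.labels if len(test_ds.labels) else None,
    )
    return model, report, train_ds, test_ds


def block_records(
    predicted: TrSeries,
    sim: SimulatorSeries,
    block_s: float = 300.0,
    segment_s: float = 10.0,
    cfg: ScreeningConfig = ScreeningConfig(),
) -> list[PairedVectorRecord]:
    """Screen one vector in consecutive time blocks for correlation work.

    Splits a per-segment T:R series and its simulator assessment series
    into aligned blocks and emits one paired record per block (FRT and
    descriptive T:R statistics from the series; mean score, score SD and
    EVT from the simulator), giving the n >= 3 paired observations a rank
    correlation needs even when only one recording is available.
    """
    seg_per_block = int(round(block_s / segment_s))
    int_per_block = int(round(block_s / sim.interval_s))
    n_blocks = min(len(predicted) // seg_per_block, len(sim) // int_per_block)
    records = []
    for b in range(n_blocks):
        sub = TrSeries(
            predicted.values[b * seg_per_block:(b + 1) * seg_per_block],
            source=predicted.source,
            vector_label=predicted.vector_label,
            patient_id=predicted.patient_id,
        )
        vs = summarize_vector(sub, cfg)
        sim_sub = SimulatorSeries(
            scores=sim.scores[b * int_per_block:(b + 1) * int_per_block],
            passed=sim.passed[b * int_per_block:(b + 1) * int_per_block],
            interval_s=sim.interval_s,
            vector_label=sim.vector_label,
            patient_id=sim.patient_id,
        )
        evt = compute_evt(sim_sub)
        records.append(PairedVectorRecord(
            patient_id=f"{predicted.patient_id}:block{b:02d}",
            vector=predicted.vector_label or "primary",
            mean_tr=vs.mean_tr,
            sd_tr=vs.sd_tr,
            frt_pct=vs.frt_pct,
            mean_score=float(sim_sub.scores.mean()),
            sd_score=float(sim_sub.scores.std(ddof=1)) if len(sim_sub) > 1 else 0.0,
            evt_pct=evt.evt_pct,
        ))
    return records
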