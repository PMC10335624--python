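"""Per-segment T:R estimation: peak-detection oracle and CNN regressor.

Two independent routes to the same quantity:

* :func:`oracle_tr` works in the signal domain — detect R peaks, measure
  the largest T deflection in a physiological window after each R, and
  take the ratio of medians.  On clean signals this recovers the true
  ratio to within quantisation error, which makes it both a label source
  for training and a validation baseline.
* The convolutional regressor consumes 32x32 phase-space images and is
  trained with a squared-error loss to emit the ratio directly, mirroring
  the screening tool's design: feature-extraction blocks, a flattening
  step, then fully connected layers ending in a single regression output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ParameterError, QualityError
from .nn import Adam, ConvNet
from .psr import EcgSegment, PsrImage
from .series import TrSeries

__all__ = [
    "TrSeries",
    "CnnConfig",
    "TrainingReport",
    "oracle_tr",
    "oracle_series",
    "build_model",
    "train",
    "predict_tr",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Predictions are clipped to this ceiling: T can exceed R pathologically,
#: but an unbounded regression output is rejected for stability.
TR_CEILING = 1.5


# ---------------------------------------------------------------------------
# Signal-domain oracle
# ---------------------------------------------------------------------------

def oracle_tr(
    seg: EcgSegment,
    r_height_frac: float = 0.7,
    refractory_s: float = 0.25,
    t_window_s: tuple[float, float] = (0.15, 0.45),
    strict: bool = True,
) -> float:
    """Estimate a segment's T:R ratio by direct peak measurement.

    R peaks are detected with an adaptive amplitude threshold
    (``r_height_frac`` of the segment maximum — above the largest
    plausible T wave) and a refractory period; the T amplitude is the
    largest absolute deflection in a 150-450 ms window after each R.
    Returns ``median(T) / median(R)`` over the detected beats.

    With ``strict=False`` a segment with fewer than two detectable beats
    yields ``NaN`` instead of raising :class:`QualityError`.
    """
    # baseline: lower quartile rather than the median — P/QRS/T activity
    # can occupy over half the beat, which biases the median upward,
    # while the small Q/S deflections keep the lower quartile on the
    # isoelectric cluster
    x = seg.samples - np.percentile(seg.samples, 25)
    peak_height = r_height_frac * x.max() if x.max() > 0 else np.inf
    peaks, _ = find_peaks(x, height=peak_height, distance=max(1, int(refractory_s * seg.fs)))
    if len(peaks) < 2:
        if strict:
            raise QualityError(
                f"segment {seg.segment_index}: found {len(peaks)} R peaks, need >= 2"
            )
        return float("nan")
    lo = int(round(t_window_s[0] * seg.fs))
    hi = int(round(t_window_s[1] * seg.fs))
    t_amps, r_amps = [], []
    for p in peaks:
        a, b = p + lo, min(p + hi, x.size)
        if a >= b:
            continue
        t_amps.append(np.abs(x[a:b]).max())
        r_amps.append(x[p])
    if not t_amps:
        if strict:
            raise QualityError("no complete T windows in segment")
        return float("nan")
    return float(np.median(t_amps) / np.median(r_amps))


def oracle_series(
    segments: Sequence[EcgSegment], **kwargs
) -> TrSeries:
    """Apply :func:`oracle_tr` to a list of segments, NaN on failures."""
    vals = [oracle_tr(s, strict=False, **kwargs) for s in segments]
    first = segments[0] if segments else None
    return TrSeries(
        np.array(vals),
        source="oracle",
        vector_label=first.vector_label if first else "",
        patient_id=first.patient_id if first else "",
    )


# ---------------------------------------------------------------------------
# Convolutional regressor
# ---------------------------------------------------------------------------

@dataclass
class CnnConfig:
    """Architecture and training hyperparameters of the T:R regressor.

    Defaults are compact enough for CPU-only training in minutes: two
    feature blocks (3x3 convolution, ReLU, 2x2 max pool; 8 then 16
    filters), a flatten, then dense layers 64 -> 16 -> 1 with a
    non-negative (softplus) output.  Loss is squared error.
    """

    n_feature_blocks: int = 2
    filters: tuple[int, ...] = (8, 16)
    dense: tuple[int, ...] = (64, 16)
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    resolution: int = 32

    def __post_init__(self) -> None:
        self.filters = tuple(self.filters)
        self.dense = tuple(self.dense)
        if self.n_feature_blocks < 1:
            raise ParameterError("need at least one feature block")
        if len(self.filters) != self.n_feature_blocks:
            raise ParameterError("one filter count per feature block required")
        if len(self.dense) < 1:
            raise ParameterError("need at least one dense layer")
        if any(f < 1 for f in self.filters) or any(d < 1 for d in self.dense):
            raise ParameterError("all layer sizes must be positive")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ParameterError("invalid training hyperparameters")


@dataclass
class TrainingReport:
    """Per-epoch training loss and validation MAE."""

    epoch_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    n_train: int = 0
    n_val: int = 0

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, loss in enumerate(self.epoch_loss):
                rec = {"epoch": i + 1, "train_mse": loss}
                if i < len(self.val_mae):
                    rec["val_mae"] = self.val_mae[i]
                fh.write(json.dumps(rec) + "\n")

    @property
    def final_val_mae(self) -> float | None:
        return self.val_mae[-1] if self.val_mae else None


def build_model(cfg: CnnConfig) -> ConvNet:
    """Instantiate the regressor with seeded initial weights."""
    model = ConvNet(
        resolution=cfg.resolution,
        filters=cfg.filters,
        dense=cfg.dense,
        seed=cfg.seed,
    )
    logger.info("built ConvNet with %d parameters", model.n_params)
    return model


def _as_image_array(images, resolution: int) -> np.ndarray:
    if isinstance(images, np.ndarray):
        arr = images
    else:
        arr = np.stack([im.pixels if isinstance(im, PsrImage) else np.asarray(im)
                        for im in images]) if len(images) else np.empty((0, resolution, resolution))
    if arr.ndim != 3 or arr.shape[1:] != (resolution, resolution):
        raise ParameterError(
            f"expected (n, {resolution}, {resolution}) images, got {arr.shape}"
        )
    return np.asarray(arr, dtype=float)


def train(
    model: ConvNet,
    images,
    labels: TrSeries | np.ndarray,
    cfg: CnnConfig,
    val_images=None,
    val_labels: TrSeries | np.ndarray | None = None,
) -> TrainingReport:
    """Fit the regressor by mini-batch gradient descent on squared error.

    Training labels should come from the generator's ground truth or from
    the signal-domain oracle.  The report carries per-epoch training loss
    and, when a validation split is given, per-epoch validation MAE.
    """
    x = _as_image_array(images, cfg.resolution)
    y = labels.values if isinstance(labels, TrSeries) else np.asarray(labels, dtype=float)
    if x.shape[0] != y.size:
        raise ParameterError(f"{x.shape[0]} images but {y.size} labels")
    if x.shape[0] == 0:
        raise ParameterError("need at least one training pair")
    keep = np.isfinite(y)
    if not keep.all():
        logger.info("dropping %d training pairs with missing labels", (~keep).sum())
        x, y = x[keep], y[keep]

    xv = yv = None
    if val_images is not None:
        xv = _as_image_array(val_images, cfg.resolution)
        yv = val_labels.values if isinstance(val_labels, TrSeries) else np.asarray(val_labels, dtype=float)

    report = TrainingReport(n_train=x.shape[0], n_val=0 if xv is None else xv.shape[0])
    if cfg.epochs == 0:
        return report

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model, lr=cfg.learning_rate)
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = model.forward(x[idx])
            err = pred - y[idx]
            losses.append(float(np.mean(err**2)))
            model.backward(2.0 * err / idx.size)
            opt.step()
        report.epoch_loss.append(float(np.mean(losses)))
        if xv is not None:
            mae = float(np.mean(np.abs(np.clip(model.predict(xv), 0, TR_CEILING) - yv)))
            report.val_mae.append(mae)
    return report


def predict_tr(
    model: ConvNet,
    images,
    vector_label: str = "",
    patient_id: str = "",
) -> TrSeries:
    """Predict one T:R value per image, clipped to ``[0, 1.5]``."""
    x = _as_image_array(images, model.resolution)
    vals = np.clip(model.predict(x), 0.0, TR_CEILING)
    return TrSeries(vals, source="model", vector_label=vector_label, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: ConvNet, cfg: CnnConfig, path: str | Path) -> None:
    """Write config plus weights to a single ``.npz`` checkpoint."""
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, config=json.dumps(asdict(cfg)), **weights)


def load_model(path: str | Path) -> tuple[ConvNet, CnnConfig]:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as npz:
        cfg_d = json.loads(str(npz["config"]))
        cfg_d["filters"] = tuple(cfg_d["filters"])
        cfg_d["dense"] = tuple(cfg_d["dense"])
        cfg = CnnConfig(**cfg_d)
        model = build_model(cfg)
        model.set_weights([npz[f"w{i}"] for i in range(len(model.get_weights()))])
    return model, cfg
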