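"""Phase-space-reconstruction imaging of 10 s ECG segments.

A 1-D signal is delay-embedded by plotting each sample against a copy of
itself lagged by a fixed delay; removing the time axis turns repetitive
morphology into a closed attractor (a sine wave, for instance, becomes a
circle when the lag is a quarter period).  Each 10 s segment of each
sensing vector is embedded and rasterised onto a 32x32 grid whose pixel
intensities are normalised visit counts — a compact, amplitude-invariant
image of the beat morphology that the convolutional regressor consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .synth import EcgRecording

__all__ = [
    "EcgSegment",
    "PsrImage",
    "DEFAULT_LAG_S",
    "DEFAULT_RESOLUTION",
    "segment_recording",
    "delay_embed",
    "rasterize_psr",
    "psr_features",
    "segment_to_image",
    "images_for_segments",
    "save_png",
    "save_txt",
    "write_image_batch",
]

#: Default embedding delay (s): 10 samples at the 500 Hz study rate —
#: small against the QRS width so the fast limb of the attractor stays open.
DEFAULT_LAG_S = 0.02

#: Raster resolution of the compressed image.
DEFAULT_RESOLUTION = 32

#: Robust normalisation percentiles for the raster bounds.
_NORM_PCT = (1.0, 99.0)


@dataclass
class EcgSegment:
    """One fixed-length window of one sensing vector."""

    samples: np.ndarray
    fs: float
    vector_label: str = ""
    segment_index: int = 0
    duration_s: float = 10.0
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.duration_s * self.fs))
        if self.samples.size != expected:
            raise ParameterError(
                f"segment has {self.samples.size} samples, expected "
                f"{expected} for {self.duration_s:g}s at {self.fs:g} Hz"
            )


@dataclass
class PsrImage:
    """Rasterised delay embedding: 32x32 grid of normalised visit counts.

    ``pixels[row, col]`` covers increasing current-sample value along
    columns and increasing delayed-sample value along rows (row 0 = lowest
    amplitude).  Intensities lie in [0, 1]; ``norm_bounds`` records the mV
    bounds used to scale both axes.
    """

    pixels: np.ndarray
    lag_s: float
    norm_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ParameterError("pixels must be a square 2-D grid")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ParameterError("pixel intensities must lie in [0, 1]")

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]


def segment_recording(
    rec: EcgRecording, segment_s: float = 10.0
) -> dict[str, list[EcgSegment]]:
    """Split every channel into contiguous, non-overlapping segments.

    Windows are half-open ``[k*segment_s, (k+1)*segment_s)``; a trailing
    partial segment is discarded.  A recording shorter than one segment
    yields empty lists with a warning rather than an error.
    """
    if segment_s <= 0:
        raise ParameterError("segment_s must be > 0")
    seg_len = int(round(segment_s * rec.fs))
    n_seg = rec.n_samples // seg_len
    if n_seg == 0:
        warnings.warn(
            f"recording of {rec.duration_s:.1f}s is shorter than one "
            f"{segment_s:g}s segment", stacklevel=2,
        )
    out: dict[str, list[EcgSegment]] = {}
    for label in rec.vector_labels:
        x = rec.channel(label)
        out[label] = [
            EcgSegment(
                x[k * seg_len:(k + 1) * seg_len],
                fs=rec.fs,
                vector_label=label,
                segment_index=k,
                duration_s=segment_s,
                patient_id=rec.patient_id,
            )
            for k in range(n_seg)
        ]
    return out


def delay_embed(samples: np.ndarray, lag_samples: int) -> np.ndarray:
    """Two-dimensional delay embedding of a signal.

    Returns an ``(n - lag, 2)`` array of points; point ``i`` is
    ``(samples[i + lag], samples[i])`` — x is the current sample, y the
    delayed copy.
    """
    samples = np.asarray(samples, dtype=float)
    if lag_samples < 1:
        raise ParameterError("lag_samples must be >= 1")
    if lag_samples >= samples.size:
        raise ParameterError(
            f"lag of {lag_samples} samples >= signal length {samples.size}"
        )
    return np.column_stack([samples[lag_samples:], samples[:-lag_samples]])


def rasterize_psr(
    points: np.ndarray,
    resolution: int = DEFAULT_RESOLUTION,
    norm_pct: tuple[float, float] = _NORM_PCT,
    lag_s: float = float("nan"),
) -> PsrImage:
    """Bin embedded points onto a square grid of visit counts.

    Axis bounds are a robust per-segment percentile range of the point
    amplitudes (then clamped), so single-sample spikes cannot swamp the
    scale and the image is invariant to overall signal gain.  Intensities
    are visit counts divided by the maximum visit count.  A constant
    signal (zero amplitude range) lights the single centre pixel.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] == 0:
        raise ParameterError("points must be a non-empty (n, 2) array")
    lo, hi = np.percentile(points, norm_pct)
    counts = np.zeros((resolution, resolution))
    if hi <= lo:
        c = resolution // 2
        counts[c, c] = float(points.shape[0])
    else:
        # snap to 1e-9 of a pixel before flooring so that bin assignment
        # is invariant to overall signal gain despite fp rounding
        scaled = np.round((points - lo) / (hi - lo) * resolution, 9)
        idx = np.clip(np.floor(scaled).astype(int), 0, resolution - 1)
        np.add.at(counts, (idx[:, 1], idx[:, 0]), 1.0)  # (row=y, col=x)
    return PsrImage(counts / counts.max(), lag_s=lag_s, norm_bounds=(float(lo), float(hi)))


def psr_features(img: PsrImage) -> dict:
    """Classical attractor summaries: box count, area, row/column sums."""
    occupied = img.pixels > 0
    res = img.resolution
    return {
        "box_count": int(occupied.sum()),
        "occupied_area_fraction": float(occupied.sum() / res**2),
        "row_sums": img.pixels.sum(axis=1),
        "col_sums": img.pixels.sum(axis=0),
    }


def segment_to_image(
    seg: EcgSegment,
    lag_s: float = DEFAULT_LAG_S,
    resolution: int = DEFAULT_RESOLUTION,
) -> PsrImage:
    """Embed and rasterise one segment in a single call."""
    lag = max(1, int(round(lag_s * seg.fs)))
    pts = delay_embed(seg.samples, lag)
    return rasterize_psr(pts, resolution=resolution, lag_s=lag / seg.fs)


def images_for_segments(
    segments: Sequence[EcgSegment],
    lag_s: float = DEFAULT_LAG_S,
    resolution: int = DEFAULT_RESOLUTION,
) -> np.ndarray:
    """Stack segment images into an ``(n, res, res)`` float array."""
    return np.stack(
        [segment_to_image(s, lag_s, resolution).pixels for s in segments]
    ) if segments else np.empty((0, resolution, resolution))


def save_png(img: PsrImage, path: str | Path) -> None:
    """Export as an 8-bit grayscale PNG (row 0 drawn at the top)."""
    from PIL import Image

    arr = np.round(img.pixels[::-1] * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_txt(img: PsrImage, path: str | Path) -> None:
    """Export the raw intensity grid as whitespace-delimited text."""
    np.savetxt(path, img.pixels, fmt="%.6f")


def write_image_batch(
    segments: Sequence[EcgSegment],
    out_dir: str | Path,
    fmt: str = "png",
    lag_s: float = DEFAULT_LAG_S,
    resolution: int = DEFAULT_RESOLUTION,
) -> list[Path]:
    """Write one image file per segment, named ``{patient}_{vector}_{index}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = {"png": save_png, "txt": save_txt}.get(fmt)
    if writer is None:
        raise ParameterError(f"unknown image format {fmt!r}")
    paths = []
    for seg in segments:
        img = segment_to_image(seg, lag_s, resolution)
        name = f"{seg.patient_id or 'rec'}_{seg.vector_label or 'ch'}_{seg.segment_index:05d}.{fmt}"
        p = out_dir / name
        writer(img, p)
        paths.append(p)
    return paths
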