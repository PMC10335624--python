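"""Synthetic two-channel Holter generator with known per-segment T:R truth.

The subcutaneous ICD senses a surface-like ECG in which the ratio of the
T-wave peak to the R-wave peak (the T:R ratio) decides whether a sensing
vector is screenable.  This module synthesises long two-channel recordings
whose T:R ratio is known exactly segment by segment, so the imaging,
regression and screening stages can all be validated against ground truth.

The beat model is a sum of Gaussian bumps (P, Q, R, S, T); amplitudes are
therefore analytically controllable and ``t_amp / r_amp`` of the active
regime *is* the segment's true T:R ratio.  Time-varying behaviour —
posture or rate driven drift of the T wave — is expressed as a piecewise
schedule of beat regimes, each with its own additive white noise level and
sinusoidal baseline wander.  Noise is added only after the ground-truth
labels are fixed.

A surrogate "simulator" is also provided: a monotone-decreasing map from
interval-mean T:R to a dimensionless vector score with a pass threshold,
standing in for the manufacturer's screening simulator so that the
correlation analysis has a controllable gold standard.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import FormatError, ParameterError
from .series import TrSeries

__all__ = [
    "BeatParams",
    "Regime",
    "RegimeSchedule",
    "EcgRecording",
    "SimulatorSeries",
    "generate_beat",
    "generate_recording",
    "generate_simulator_series",
    "default_score_map",
    "DEFAULT_PASS_THRESHOLD",
    "write_recording",
    "read_recording",
]

#: Segment length used for ground-truth labelling (s).
SEGMENT_S = 10.0

#: Wave order within one beat; centres must respect P < QRS < T.
_WAVES = ("p", "q", "r", "s", "t")


@dataclass(frozen=True)
class BeatParams:
    """Amplitudes, widths and timing of one sum-of-Gaussians cardiac cycle.

    Offsets are wave centres in seconds from beat onset; widths are the
    Gaussian standard deviations in seconds.  Defaults describe a 1 s beat
    (60 beats/min) with a QRS complex (small Q and S deflections flanking
    the R spike) and remain valid for rates up to ~90 beats/min.
    ``t_amp / r_amp`` equals the intended noise-free T:R ratio.
    """

    r_amp: float = 1.0
    t_amp: float = 0.25
    heart_rate: float = 60.0
    p_amp: float = 0.10
    q_amp: float = -0.05
    s_amp: float = -0.08
    offsets: Mapping[str, float] = field(
        default_factory=lambda: {"p": 0.16, "q": 0.225, "r": 0.26, "s": 0.295, "t": 0.50}
    )
    widths: Mapping[str, float] = field(
        default_factory=lambda: {"p": 0.025, "q": 0.008, "r": 0.012, "s": 0.008, "t": 0.050}
    )

    def __post_init__(self) -> None:
        if self.r_amp <= 0:
            raise ParameterError("r_amp must be > 0")
        if self.t_amp < 0:
            raise ParameterError("t_amp must be >= 0")
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be > 0")
        for w in _WAVES:
            if w not in self.offsets or w not in self.widths:
                raise ParameterError(f"missing offset/width for wave {w!r}")
            if self.widths[w] <= 0:
                raise ParameterError(f"width of wave {w!r} must be > 0")
        if not (self.offsets["p"] < self.offsets["r"] < self.offsets["t"]):
            raise ParameterError("wave centres must be ordered P < QRS < T")
        beat_s = 60.0 / self.heart_rate
        tail = self.offsets["t"] + 3.0 * self.widths["t"]
        if tail > beat_s:
            raise ParameterError(
                f"T wave (ends ~{tail:.3f}s) does not fit in a "
                f"{beat_s:.3f}s beat; shorten offsets or slow the rate"
            )

    @property
    def tr_ratio(self) -> float:
        """Intended noise-free T:R ratio of beats with these parameters."""
        return self.t_amp / self.r_amp


def generate_beat(params: BeatParams, fs: float) -> np.ndarray:
    """Render one cardiac cycle (mV) at sampling rate ``fs``.

    The array spans one beat interval, ``60 / heart_rate`` seconds.  The
    global maximum equals ``r_amp`` and the T-window maximum equals
    ``t_amp``, both within sampling quantisation error.
    """
    if fs <= 0:
        raise ParameterError("fs must be > 0")
    beat_s = 60.0 / params.heart_rate
    n = int(round(beat_s * fs))
    t = np.arange(n) / fs
    amps = {
        "p": params.p_amp,
        "q": params.q_amp,
        "r": params.r_amp,
        "s": params.s_amp,
        "t": params.t_amp,
    }
    y = np.zeros(n)
    for w in _WAVES:
        y += amps[w] * np.exp(-0.5 * ((t - params.offsets[w]) / params.widths[w]) ** 2)
    return y


@dataclass(frozen=True)
class Regime:
    """One piece of a schedule: beat morphology plus artefact levels."""

    start_s: float
    beat: BeatParams
    noise_sd: float = 0.0          # additive white noise SD (mV)
    wander_amp: float = 0.0        # baseline wander amplitude (mV)
    wander_freq: float = 0.33      # baseline wander frequency (Hz), ~respiration


@dataclass
class RegimeSchedule:
    """Piecewise-constant beat regimes covering a recording.

    Start times must be strictly increasing and the first must be 0 so
    every instant of the recording has exactly one active regime.
    """

    regimes: Sequence[Regime]

    def __post_init__(self) -> None:
        if len(self.regimes) == 0:
            raise ParameterError("schedule must contain at least one regime")
        starts = [r.start_s for r in self.regimes]
        if starts[0] != 0:
            raise ParameterError("first regime must start at t=0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ParameterError("regime start times must be strictly increasing")

    def active_at(self, t_s: float) -> Regime:
        """Regime governing time ``t_s``."""
        current = self.regimes[0]
        for r in self.regimes:
            if r.start_s <= t_s:
                current = r
            else:
                break
        return current

    @classmethod
    def constant(cls, beat: BeatParams, noise_sd: float = 0.0,
                 wander_amp: float = 0.0, wander_freq: float = 0.33) -> "RegimeSchedule":
        return cls([Regime(0.0, beat, noise_sd, wander_amp, wander_freq)])


@dataclass
class EcgRecording:
    """Multi-channel sampled voltage traces, one channel per sensing vector.

    ``channels`` has shape ``(n_vectors, n_samples)`` in mV; the study
    Holter recorded the primary and alternate vectors simultaneously, so
    two channels is the default and the expected case.
    """

    channels: np.ndarray
    fs: float = 500.0
    vector_labels: tuple[str, ...] = ("primary", "alternate")
    patient_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        self.vector_labels = tuple(self.vector_labels)
        if len(self.vector_labels) != self.channels.shape[0]:
            raise FormatError(
                f"{self.channels.shape[0]} channels but "
                f"{len(self.vector_labels)} vector labels"
            )
        if len(set(self.vector_labels)) != len(self.vector_labels):
            raise ParameterError("vector labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.vector_labels.index(label)
        except ValueError:
            raise ParameterError(f"no channel labelled {label!r}") from None
        return self.channels[i]


def _render_clean_channel(schedule: RegimeSchedule, n_samples: int, fs: float) -> np.ndarray:
    """Concatenate beats, switching regime at each beat onset."""
    out = np.zeros(n_samples)
    pos = 0
    while pos < n_samples:
        regime = schedule.active_at(pos / fs)
        beat = generate_beat(regime.beat, fs)
        take = min(len(beat), n_samples - pos)
        out[pos:pos + take] = beat[:take]
        pos += len(beat)
    return out


def _ground_truth(schedule: RegimeSchedule, duration_s: float) -> np.ndarray:
    n_seg = int(np.floor(duration_s / SEGMENT_S))
    # Label each segment by the regime active at its midpoint, so a regime
    # switch landing inside a segment charges the segment to whichever
    # regime covers most of it when switches align with segment boundaries.
    mids = (np.arange(n_seg) + 0.5) * SEGMENT_S
    return np.array([schedule.active_at(t).beat.tr_ratio for t in mids])


def generate_recording(
    schedules: RegimeSchedule | Mapping[str, RegimeSchedule],
    duration_s: float,
    fs: float = 500.0,
    seed: int = 0,
    patient_id: str = "synthetic",
) -> tuple[EcgRecording, dict[str, TrSeries]]:
    """Simulate a two-channel Holter recording plus per-segment truth.

    Parameters
    ----------
    schedules
        Either one :class:`RegimeSchedule` applied to both vectors, or a
        mapping ``{vector_label: schedule}``.
    duration_s, fs
        Recording length (s) and sampling rate (Hz; study hardware: 500).
    seed
        Master seed; per-channel noise streams are spawned from it, so
        channels are independent but the whole recording is reproducible
        bit for bit.

    Returns
    -------
    (recording, truth)
        ``truth[label]`` is a ground-truth :class:`TrSeries` with one
        value per whole 10 s segment (trailing partial segment dropped),
        fixed *before* noise and baseline wander are added.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be > 0")
    if isinstance(schedules, RegimeSchedule):
        schedules = {"primary": schedules, "alternate": schedules}
    if len(schedules) == 0:
        raise ParameterError("no channel schedules given")

    labels = tuple(schedules)
    n_samples = int(round(duration_s * fs))
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(labels))

    channels = np.empty((len(labels), n_samples))
    truth: dict[str, TrSeries] = {}
    for i, label in enumerate(labels):
        sched = schedules[label]
        sig = _render_clean_channel(sched, n_samples, fs)
        truth[label] = TrSeries(
            _ground_truth(sched, duration_s),
            source="ground_truth",
            vector_label=label,
            patient_id=patient_id,
        )
        rng = np.random.default_rng(streams[i])
        phase = rng.uniform(0, 2 * np.pi)
        # artefact levels follow the active regime, piecewise over time
        bounds = [int(np.ceil(r.start_s * fs)) for r in sched.regimes] + [n_samples]
        for r, (a, b) in zip(sched.regimes, zip(bounds, bounds[1:])):
            if b <= a:
                continue
            if r.noise_sd > 0:
                sig[a:b] += r.noise_sd * rng.standard_normal(b - a)
            if r.wander_amp > 0:
                t_slice = np.arange(a, b) / fs
                sig[a:b] += r.wander_amp * np.sin(
                    2 * np.pi * r.wander_freq * t_slice + phase
                )
        channels[i] = sig

    rec = EcgRecording(channels, fs=fs, vector_labels=labels, patient_id=patient_id)
    return rec, truth


# ---------------------------------------------------------------------------
# Surrogate screening simulator
# ---------------------------------------------------------------------------

def default_score_map(mean_tr: np.ndarray) -> np.ndarray:
    """Monotone-decreasing map from interval-mean T:R to a vector score.

    ``1000 * (1 - x)`` clipped at zero: a perfectly favourable interval
    (T:R 0) scores 1000, and the score falls linearly as the T wave grows.
    """
    return np.clip(1000.0 * (1.0 - np.asarray(mean_tr, dtype=float)), 0.0, None)


#: Pass threshold aligned with the screening T:R cutoff of 1/3 under the
#: default score map: an interval passes iff its mean T:R < 1/3.
DEFAULT_PASS_THRESHOLD = 1000.0 * (1.0 - 1.0 / 3.0)


@dataclass
class SimulatorSeries:
    """Per-interval surrogate vector scores with pass/fail assessments."""

    scores: np.ndarray
    passed: np.ndarray
    interval_s: float = 60.0
    vector_label: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.passed = np.asarray(self.passed, dtype=bool)
        if self.scores.shape != self.passed.shape:
            raise ParameterError("scores and passed must have equal length")
        if np.any(self.scores < 0):
            raise ParameterError("vector scores must be non-negative")

    def __len__(self) -> int:
        return self.scores.size


def generate_simulator_series(
    truth: TrSeries,
    interval_s: float = 60.0,
    mapping: Callable[[np.ndarray], np.ndarray] = default_score_map,
    score_noise_sd: float = 0.0,
    pass_threshold: float = DEFAULT_PASS_THRESHOLD,
    seed: int = 0,
) -> SimulatorSeries:
    """Score a ground-truth T:R series the way the screening simulator would.

    The recording is assessed at ``interval_s`` intervals (the study
    simulator used 1 min); each interval's score is the monotone map of
    its mean T:R plus optional Gaussian noise, clipped at zero, and the
    interval passes iff score >= ``pass_threshold``.  With zero noise the
    scores are a strictly decreasing function of interval-mean T:R, so the
    Spearman correlation against truth is exactly -1.
    """
    if len(truth) == 0:
        raise ParameterError("truth series is empty")
    per = interval_s / SEGMENT_S
    if interval_s < SEGMENT_S or abs(per - round(per)) > 1e-9:
        raise ParameterError(
            f"interval_s must be a multiple of the {SEGMENT_S:.0f}s segment length"
        )
    per = int(round(per))
    n_int = len(truth) // per
    if n_int == 0:
        raise ParameterError("truth series shorter than one assessment interval")
    means = truth.values[: n_int * per].reshape(n_int, per).mean(axis=1)
    scores = np.asarray(mapping(means), dtype=float)
    if score_noise_sd > 0:
        rng = np.random.default_rng(seed)
        scores = scores + score_noise_sd * rng.standard_normal(n_int)
    scores = np.clip(scores, 0.0, None)
    return SimulatorSeries(
        scores=scores,
        passed=scores >= pass_threshold,
        interval_s=interval_s,
        vector_label=truth.vector_label,
        patient_id=truth.patient_id,
    )


# ---------------------------------------------------------------------------
# Recording I/O: CSV dialect and a minimal WFDB-style .hea/.dat dialect
# ---------------------------------------------------------------------------

#: Full-scale quantisation used on write (16-bit signed).
_QMAX = 32767


def _quantise(channels: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale to int16; returns (ints, gain) with mV = ints / gain."""
    peak = float(np.max(np.abs(channels))) if channels.size else 0.0
    if peak == 0.0:
        return channels.astype(np.int16), 1.0
    gain = _QMAX / peak
    return np.round(channels * gain).astype(np.int16), gain


def write_recording(rec: EcgRecording, path: str | os.PathLike) -> None:
    """Write a recording as CSV (``.csv``) or WFDB-style (``.hea``).

    Both dialects quantise samples to 16-bit integers, matching common
    Holter exports; a round trip therefore reproduces samples to within
    one quantisation step.
    """
    path = Path(path)
    if path.suffix == ".csv":
        _write_csv(rec, path)
    elif path.suffix == ".hea":
        _write_wfdb(rec, path)
    else:
        raise FormatError(f"unsupported recording extension {path.suffix!r}")


def read_recording(path: str | os.PathLike) -> EcgRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if path.suffix == ".csv":
        return _read_csv(path)
    if path.suffix == ".hea":
        return _read_wfdb(path)
    raise FormatError(f"unsupported recording extension {path.suffix!r}")


def _write_csv(rec: EcgRecording, path: Path) -> None:
    ints, gain = _quantise(rec.channels)
    mv = ints / gain
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write(f"# vectors={','.join(rec.vector_labels)}\n")
        fh.write(f"# patient={rec.patient_id}\n")
        np.savetxt(fh, mv.T, fmt="%.7g", delimiter=",")


def _read_csv(path: Path) -> EcgRecording:
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            m = re.match(r"#\s*(\w+)\s*=\s*(.*)", line)
            if not m:
                raise FormatError(f"malformed header line: {line.strip()!r}")
            header[m.group(1)] = m.group(2).strip()
    for key in ("fs", "vectors"):
        if key not in header:
            raise FormatError(f"missing required header field {key!r}")
    labels = tuple(v.strip() for v in header["vectors"].split(","))
    data = np.loadtxt(path, delimiter=",", skiprows=n_header, ndmin=2)
    if data.shape[1] != len(labels):
        raise FormatError(
            f"{data.shape[1]} sample columns but {len(labels)} declared vectors"
        )
    return EcgRecording(
        data.T,
        fs=float(header["fs"]),
        vector_labels=labels,
        patient_id=header.get("patient", ""),
    )


def _write_wfdb(rec: EcgRecording, path: Path) -> None:
    ints, gain = _quantise(rec.channels)
    base = path.with_suffix("")
    dat = base.with_suffix(".dat")
    n_ch, n_s = ints.shape
    with open(path, "w") as fh:
        fh.write(f"{base.name} {n_ch} {rec.fs:g} {n_s}\n")
        for label in rec.vector_labels:
            fh.write(f"{dat.name} 16 {gain:.9g} 0 {label}\n")
        fh.write(f"# patient={rec.patient_id}\n")
    ints.T.astype("<i2").tofile(dat)  # interleaved sample frames


def _read_wfdb(path: Path) -> EcgRecording:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    try:
        _, n_ch, fs, n_s = lines[0].split()
        n_ch, fs, n_s = int(n_ch), float(fs), int(n_s)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed record line in {path.name}") from exc
    sig_lines = [l for l in lines[1:] if not l.startswith("#")]
    if len(sig_lines) != n_ch:
        raise FormatError(
            f"{len(sig_lines)} signal lines but {n_ch} channels declared"
        )
    labels, gains, dat_name = [], [], None
    for l in sig_lines:
        parts = l.split()
        if len(parts) < 5 or parts[1] != "16":
            raise FormatError(f"malformed signal line: {l!r}")
        dat_name = parts[0]
        gains.append(float(parts[2]))
        labels.append(parts[4])
    patient = ""
    for l in lines[1:]:
        m = re.match(r"#\s*patient=(.*)", l)
        if m:
            patient = m.group(1).strip()
    raw = np.fromfile(path.parent / dat_name, dtype="<i2")
    if raw.size != n_ch * n_s:
        raise FormatError(
            f"{dat_name}: expected {n_ch * n_s} samples, found {raw.size}"
        )
    ints = raw.reshape(n_s, n_ch).T
    mv = ints / np.asarray(gains)[:, None]
    return EcgRecording(mv, fs=fs, vector_labels=tuple(labels), patient_id=patient)
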