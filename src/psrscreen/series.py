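"""Per-segment T:R ratio series.

A :class:`TrSeries` is the common currency between the signal generator,
the peak-detection oracle and the convolutional regressor: one T:R value
per 10 s segment of one sensing vector, tagged with where the values came
from so downstream summaries can state their provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Allowed provenance tags for a series.
SOURCES = ("ground_truth", "oracle", "model")


@dataclass
class TrSeries:
    """Per-segment T:R estimates for one sensing vector.

    Parameters
    ----------
    values
        One dimensionless T:R ratio per 10 s segment.  Values are finite
        and non-negative; ``NaN`` marks a segment the estimator could not
        measure (missing-value sentinel).
    source
        Provenance of the values: ``"ground_truth"`` (from the generator),
        ``"oracle"`` (signal-domain peak detection) or ``"model"``
        (convolutional regressor).
    vector_label
        Sensing-vector name, typically ``"primary"`` or ``"alternate"``.
    patient_id
        Opaque recording identifier.
    """

    values: np.ndarray
    source: str
    vector_label: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("TrSeries values must be one-dimensional")
        if self.source not in SOURCES:
            raise ParameterError(
                f"source must be one of {SOURCES}, got {self.source!r}"
            )
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ParameterError("T:R ratios must be non-negative")
        if np.any(np.isinf(self.values)):
            raise ParameterError("T:R ratios must be finite or NaN")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())
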