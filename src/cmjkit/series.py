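"""Uniformly sampled time series — the common currency of every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class SampledSeries:
    """A uniformly sampled scalar time series with an explicit rate.

    Parameters
    ----------
    values : array-like
        Sample values. Stored as a float64 numpy array.
    rate : float
        Sampling rate in Hz. Must be positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    name : str, optional
        Channel label, e.g. ``"hip_px"`` or ``"force_N"``.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SampledSeries holds a 1-D channel")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds."""
        return max(len(self) - 1, 0) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    def with_values(self, values: np.ndarray, name: str | None = None) -> "SampledSeries":
        """Copy of this series with new values on the same time base."""
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name)

    def slice(self, start: int, end: int) -> "SampledSeries":
        """Sub-series on samples ``[start, end)``, preserving absolute time."""
        start = max(start, 0)
        end = min(end, len(self))
        return SampledSeries(self.values[start:end], self.rate,
                             t0=self.t0 + start / self.rate, name=self.name)
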