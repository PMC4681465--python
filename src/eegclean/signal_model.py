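"""Core signal containers and regressor construction.

Everything downstream (adaptive filters, wavelet baseline, evaluation)
speaks :class:`TimeSeries`: a uniformly sampled, finite, real-valued
signal with an explicit sampling rate.  Adaptive noise cancellation
regresses the contaminated EEG on the reference artifact channel and a
delayed copy of it; :func:`build_regressors` builds that two-column
input matrix.

Standardization uses the population convention (divide by N).  Filters
train on standardized signals internally so that Gaussian widths and
novelty thresholds are scale-free; :func:`destandardize` restores the
original units exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "RegressorMatrix",
    "StandardizationParams",
    "standardize",
    "destandardize",
    "build_regressors",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        Signal values (e.g. microvolts).  Coerced to a float64 array;
        must be non-empty and finite.
    sampling_rate_hz
        Sampling rate in Hz, strictly positive.
    label
        Free-text channel label, e.g. ``"EEG"``, ``"EOG"`` or ``"ECG"``.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sampling_rate_hz", float(self.sampling_rate_hz))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        """New series with the same rate but different samples."""
        return TimeSeries(samples, self.sampling_rate_hz,
                          self.label if label is None else label)


@dataclass(frozen=True)
class StandardizationParams:
    """Affine parameters ``x = standardized * scale + mean``."""

    mean: float
    scale: float
    method: str = "zscore"

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class RegressorMatrix:
    """Per-sample input vectors ``[r(k), r(k - d)]`` from a reference channel.

    Row ``k`` pairs the current reference sample with its ``delay_d``-sample
    delayed copy; samples before the start of the recording are zero.
    """

    rows: np.ndarray
    delay_d: int
    n_inputs: int = field(default=2)

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.ndim != 2 or rows.shape[1] != self.n_inputs:
            raise ValueError(f"rows must be (n, {self.n_inputs})")
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return int(self.rows.shape[0])


def standardize(series: TimeSeries, method: str = "zscore") -> tuple[TimeSeries, StandardizationParams]:
    """Shift/scale a series to a canonical range.

    ``method="zscore"`` maps to zero mean, unit population standard
    deviation; ``method="maxabs"`` maps to zero mean, max absolute value 1
    (useful ahead of trigonometric functional-link expansion, which wants
    inputs in roughly [-1, 1]).  A constant series gets ``scale=1`` so the
    transform stays invertible.
    """
    x = series.samples
    mean = float(np.mean(x))
    centered = x - mean
    if method == "zscore":
        scale = float(np.sqrt(np.mean(centered**2)))
    elif method == "maxabs":
        scale = float(np.max(np.abs(centered)))
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    if scale == 0.0:
        scale = 1.0
    params = StandardizationParams(mean=mean, scale=scale, method=method)
    return series.with_samples(centered / scale), params


def destandardize(series: TimeSeries, params: StandardizationParams) -> TimeSeries:
    """Invert :func:`standardize`: ``x = z * scale + mean``."""
    return series.with_samples(series.samples * params.scale + params.mean)


def standardize_array(x: np.ndarray, method: str = "zscore") -> tuple[np.ndarray, StandardizationParams]:
    """Array-level counterpart of :func:`standardize` (internal plumbing)."""
    mean = float(np.mean(x))
    centered = np.asarray(x, dtype=np.float64) - mean
    if method == "zscore":
        scale = float(np.sqrt(np.mean(centered**2)))
    elif method == "maxabs":
        scale = float(np.max(np.abs(centered)))
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    if scale == 0.0:
        scale = 1.0
    return centered / scale, StandardizationParams(mean=mean, scale=scale, method=method)


def apply_params(x: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return (np.asarray(x, dtype=np.float64) - params.mean) / params.scale


def invert_params(z: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return np.asarray(z, dtype=np.float64) * params.scale + params.mean


def build_regressors(reference: TimeSeries, delay_d: int = 1) -> RegressorMatrix:
    """Build the two-input regressor matrix ``[r(k), r(k - d)]``.

    The delayed column is zero-padded for ``k < d`` so the matrix keeps one
    row per sample and the cleaned output stays sample-aligned with the
    input recording.
    """
    if delay_d < 0:
        raise ValueError("delay_d must be non-negative")
    r = reference.samples
    delayed = np.zeros_like(r)
    if delay_d < r.size:
        if delay_d == 0:
            delayed[:] = r
        else:
            delayed[delay_d:] = r[:-delay_d]
    rows = np.column_stack([r, delayed])
    return RegressorMatrix(rows=rows, delay_d=int(delay_d))
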