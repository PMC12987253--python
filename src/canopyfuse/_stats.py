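"""Shared statistical conventions.

Every module that reports percentiles, standard deviations, or
histogram-shape features goes through these helpers so the conventions
(linear-interpolation percentiles, sample standard deviation, 50-bin
histograms with lower-bin tie-breaking) are defined exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Number of equal-width histogram bins used for all distribution-shape features.
N_HISTOGRAM_BINS = 50


def percentile(values: np.ndarray, q) -> np.ndarray:
    """Percentile with linear interpolation between order statistics."""
    return np.quantile(np.asarray(values, dtype=float), np.asarray(q) / 100.0)


def sample_std(values: np.ndarray) -> float:
    """Sample standard deviation (ddof=1); 0.0 for a single value."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1))


@dataclass(frozen=True)
class HistogramFeatures:
    """Shape descriptors of a fixed-bin histogram.

    peak_location
        Center of the modal bin (ties broken toward the lower-valued bin).
    peak_frequency
        Modal bin count divided by the number of samples.
    distribution_width
        Number of bins whose count is at least half the modal count,
        times the bin width (a full-width-at-half-maximum analogue).
    """

    peak_location: float
    peak_frequency: float
    distribution_width: float


def histogram_features(values: np.ndarray, n_bins: int = N_HISTOGRAM_BINS) -> HistogramFeatures:
    """Histogram-shape features over ``n_bins`` equal-width bins spanning min..max.

    A degenerate sample (all values equal) is treated as a single point
    mass: peak_frequency 1 and zero distribution width.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("histogram_features requires at least one value")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return HistogramFeatures(peak_location=lo, peak_frequency=1.0, distribution_width=0.0)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    modal = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    bin_width = (hi - lo) / n_bins
    half_max = counts[modal] / 2.0
    width_bins = int(np.count_nonzero(counts >= half_max))
    return HistogramFeatures(
        peak_location=float((edges[modal] + edges[modal + 1]) / 2.0),
        peak_frequency=float(counts[modal] / values.size),
        distribution_width=float(width_bins * bin_width),
    )
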