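"""Pair correlation functions between intensity-carpet columns.

The pair correlation function between pixels p and p+n at lag τ is the
normalized temporal cross-covariance of the two column traces,

    pCF(τ; p, p+n) = <F(t, p) F(t+τ, p+n)> / (<F(t, p)> <F(t, p+n)>) − 1,

with the brackets denoting the temporal average over the record and the
lag quantized to integer multiples of the line period.  n = 0 gives the
ordinary FCS autocorrelation of one column.  Averages are taken over the
overlapping T − k line pairs only (no zero padding); normalization uses
the full-record means of the two columns.

Two lag-sampling schemes are provided: a multi-tau quasi-logarithmic
correlator (16 linear lags in the first octave, then 8 per octave with
the traces block-averaged by 2 per octave — the standard hardware
correlator layout) and an exact linear-lag correlator used for oracle
comparisons and short records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from stedpcf.carpet_io import LineScanCarpet

logger = logging.getLogger(__name__)

MULTITAU_POINTS_PER_LEVEL = 16


@dataclass(frozen=True)
class CorrelationCurve:
    """Correlation amplitudes on a grid of positive lag times.

    ``pixel_pair`` records (p, q) of the source and target columns (equal
    for an autocorrelation, None for an average over columns);
    ``n_samples_per_lag`` the number of line pairs that entered each lag
    (in units of the block-averaged sampling at that lag's octave).
    """

    lags: np.ndarray
    values: np.ndarray
    pixel_pair: Optional[tuple] = None
    n_samples_per_lag: Optional[np.ndarray] = None

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape or lags.ndim != 1:
            raise ValueError("lags and values must be 1D arrays of equal length")
        if len(lags) and (np.diff(lags) <= 0).any():
            raise ValueError("lags must be strictly increasing")
        if len(lags) and lags[0] <= 0:
            raise ValueError("lags must be positive")
        if not np.isfinite(values).all():
            raise ValueError("correlation values contain non-finite entries")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class PCFCarpet:
    """Stack of pair correlation curves for all column pairs at fixed offset.

    ``values`` has shape (n_lags, n_columns); column j holds the curve
    whose *source* pixel is ``column_pixels[j]``.  ``distance_n`` is the
    signed pixel offset: positive correlates p → p+|n| (forward, the
    direction the line is drawn), negative p → p−|n| (backward).
    """

    values: np.ndarray
    lags: np.ndarray
    distance_n: int
    column_pixels: np.ndarray

    @property
    def direction(self) -> str:
        return "forward" if self.distance_n >= 0 else "backward"

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def curve(self, pixel: int) -> CorrelationCurve:
        """Curve whose source column is ``pixel``."""
        idx = np.nonzero(self.column_pixels == pixel)[0]
        if idx.size == 0:
            raise KeyError(f"pixel {pixel} has no curve in this carpet")
        j = int(idx[0])
        return CorrelationCurve(
            lags=self.lags,
            values=self.values[:, j],
            pixel_pair=(pixel, pixel + self.distance_n),
        )


def _check_column(trace: np.ndarray, p: int) -> float:
    mean = float(trace.mean())
    if mean == 0.0:
        raise ValueError(
            f"column {p} has zero mean: pair correlation normalization undefined"
        )
    return mean


def _multitau_correlate(x: np.ndarray, y: np.ndarray, dt: float,
                        m: int = MULTITAU_POINTS_PER_LEVEL):
    """Multi-tau cross-correlation <x(t) y(t+k)> on a quasi-log lag grid."""
    norm = x.mean() * y.mean()
    lags, values, nsamp = [], [], []
    xl = x.astype(float)
    yl = y.astype(float)
    resolution = 1
    level = 0
    while True:
        L = xl.size
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            if k >= L:
                break
            lags.append(k * resolution * dt)
            values.append(
                float(np.dot(xl[: L - k], yl[k:])) / (L - k) / norm - 1.0
            )
            nsamp.append(L - k)
        if L // 2 <= m + 1:
            break
        half = (L // 2) * 2
        xl = xl[:half].reshape(-1, 2).mean(axis=1)
        yl = yl[:half].reshape(-1, 2).mean(axis=1)
        resolution *= 2
        level += 1
    return (np.array(lags), np.array(values), np.array(nsamp))


def _linear_correlate(x: np.ndarray, y: np.ndarray, dt: float, max_lag: int):
    """Exact linear-lag correlator: one dot product per integer lag."""
    norm = x.mean() * y.mean()
    T = x.size
    max_lag = min(max_lag, T - 1)
    ks = np.arange(1, max_lag + 1)
    values = np.empty(ks.size)
    xf = x.astype(float)
    yf = y.astype(float)
    for i, k in enumerate(ks):
        values[i] = np.dot(xf[: T - k], yf[k:]) / (T - k) / norm - 1.0
    return ks * dt, values, T - ks


def pcf_pair(carpet: LineScanCarpet, p: int, n: int,
             lag_scheme: str = "multitau",
             max_lag: Optional[int] = None) -> CorrelationCurve:
    """Pair correlation between columns p and p+n of a carpet.

    ``n`` is the signed pixel offset; n = 0 yields the autocorrelation of
    column p.  ``lag_scheme`` is ``"multitau"`` (quasi-logarithmic) or
    ``"linear"`` (every integer lag up to ``max_lag``, default T // 4).
    """
    q = p + n
    for idx in (p, q):
        if not (0 <= idx < carpet.n_pixels):
            raise IndexError(
                f"column {idx} out of range for {carpet.n_pixels}-pixel carpet"
            )
    x = carpet.counts[:, p]
    y = carpet.counts[:, q]
    _check_column(x, p)
    _check_column(y, q)
    dt = carpet.line_period
    if lag_scheme == "multitau":
        lags, values, nsamp = _multitau_correlate(x, y, dt)
    elif lag_scheme == "linear":
        if max_lag is None:
            max_lag = carpet.n_lines // 4
        lags, values, nsamp = _linear_correlate(x, y, dt, max_lag)
    else:
        raise ValueError(f"unknown lag_scheme {lag_scheme!r}")
    return CorrelationCurve(
        lags=lags, values=values, pixel_pair=(p, q), n_samples_per_lag=nsamp
    )


def pcf_carpet(carpet: LineScanCarpet, n: int,
               lag_scheme: str = "multitau",
               max_lag: Optional[int] = None) -> PCFCarpet:
    """Pair correlation carpet: pcf_pair stacked over every valid column.

    Forward (n ≥ 0) correlates p → p+n for p = 0 .. n_pixels−n−1;
    backward (n < 0) correlates p → p−|n| for p = |n| .. n_pixels−1.
    """
    if abs(n) >= carpet.n_pixels:
        raise ValueError(
            f"offset {n} too large for {carpet.n_pixels}-pixel carpet"
        )
    if n >= 0:
        pixels = np.arange(0, carpet.n_pixels - n)
    else:
        pixels = np.arange(-n, carpet.n_pixels)
    curves = []
    for p in pixels:
        try:
            curves.append(pcf_pair(carpet, int(p), n, lag_scheme, max_lag))
        except ValueError as exc:
            raise ValueError(f"pcf failed at source column {p}: {exc}") from exc
    values = np.column_stack([c.values for c in curves])
    return PCFCarpet(
        values=values, lags=curves[0].lags, distance_n=int(n),
        column_pixels=pixels,
    )


def average_pcf(pcf: PCFCarpet, columns: Optional[Sequence[int]] = None
                ) -> CorrelationCurve:
    """Unweighted mean of the selected source-pixel curves at each lag.

    ``columns`` lists source pixels (default: all columns of the carpet);
    spatial averaging trades the per-pixel map for lower noise.
    """
    if columns is None:
        idx = np.arange(pcf.n_columns)
    else:
        columns = np.asarray(list(columns), dtype=int)
        if columns.size == 0:
            raise ValueError("empty column subset")
        idx = []
        for c in columns:
            where = np.nonzero(pcf.column_pixels == c)[0]
            if where.size == 0:
                raise IndexError(f"source pixel {c} not present in this carpet")
            idx.append(int(where[0]))
        idx = np.asarray(idx)
    return CorrelationCurve(
        lags=pcf.lags,
        values=pcf.values[:, idx].mean(axis=1),
        pixel_pair=None,
    )


def detrend(carpet: LineScanCarpet, segment_length: int = 1000,
            seed: int = 0) -> LineScanCarpet:
    """Flatten slow intensity drifts by adding uncorrelated filler counts.

    Each column is cut into segments of ``segment_length`` lines and the
    segment means are computed.  Every line of a segment whose mean falls
    below the column's maximum segment mean receives independent Poisson
    counts of mean (m_max − m_segment), equalizing the mean profile to the
    maximum.  The filler is uncorrelated, so it dilutes correlation
    amplitudes slightly but removes the spurious long-lag correlation a
    drifting mean would create.  Counts are only ever added.
    """
    if segment_length < 2:
        raise ValueError(f"segment_length must be >= 2, got {segment_length}")
    if segment_length > carpet.n_lines:
        raise ValueError(
            f"segment_length {segment_length} exceeds carpet length "
            f"{carpet.n_lines}"
        )
    rng = np.random.default_rng(seed)
    counts = carpet.counts.astype(float).copy()
    n = carpet.n_lines
    edges = list(range(0, n, segment_length))
    edges.append(n)
    # drop a trailing fragment shorter than half a segment into the
    # previous segment so its mean stays well estimated
    if len(edges) > 2 and edges[-1] - edges[-2] < segment_length // 2:
        edges.pop(-2)
    for col in range(carpet.n_pixels):
        seg_means = np.array([
            counts[a:b, col].mean() for a, b in zip(edges[:-1], edges[1:])
        ])
        m_max = seg_means.max()
        for (a, b), m in zip(zip(edges[:-1], edges[1:]), seg_means):
            deficit = m_max - m
            if deficit > 0:
                counts[a:b, col] += rng.poisson(deficit, b - a)
    return LineScanCarpet(
        counts=counts,
        line_period=carpet.line_period,
        pixel_size=carpet.pixel_size,
        origin_label=carpet.origin_label,
        acquisition_id=carpet.acquisition_id + "+detrend",
        mode=carpet.mode,
    )
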