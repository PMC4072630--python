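"""End-to-end carpet analysis: interface localization, directional pair
correlation carpets, maxima detection/classification, and two-pool
diffusion summaries.

A pair correlation curve takes one of three shapes: *sigmoidal* (maximum
at the first sampled lag — the two pixels are within the optical
resolution), *bell* (interior maximum at the modal transit time τ_m —
the pixels are resolved), or *zero* (no correlation above noise — a
barrier blocks diffusion between them).  The pipeline classifies every
column pair, converts interior maxima to local diffusion coefficients
via D = d²/(4 τ_m), and pools them into fast and slow components.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal

from stedpcf.carpet_io import LineScanCarpet
from stedpcf.correlate import (
    CorrelationCurve,
    PCFCarpet,
    average_pcf,
    detrend as detrend_carpet,
    pcf_carpet,
)
from stedpcf.models import EnvelopeSummary, estimate_D_from_tau_max, locate_envelope

logger = logging.getLogger(__name__)


def resolution_ratio(w_confocal: float, w_sted: float) -> float:
    """Fold improvement of STED over confocal resolution (e.g. 275/110 = 2.5)."""
    if w_confocal <= 0 or w_sted <= 0:
        raise ValueError("PSF sizes must be positive")
    return w_confocal / w_sted


@dataclass(frozen=True)
class ColumnClassification:
    """Shape classification of one column's pair correlation curve."""

    pixel: int
    shape: str                      # "sigmoidal" | "bell" | "zero"
    tau_m_list: tuple = ()          # interior maxima lags, seconds
    amplitudes: tuple = ()          # curve values at those maxima
    D_estimates: tuple = ()         # µm²/s via d²/(4 τ_m), when d is known

    def __post_init__(self):
        if self.shape not in ("sigmoidal", "bell", "zero"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "zero" and self.tau_m_list:
            raise ValueError("zero-class curves cannot carry maxima")
        if self.shape == "bell" and not self.tau_m_list:
            raise ValueError("bell-class curves need at least one maximum")


@dataclass(frozen=True)
class PoolEstimate:
    """Pooled transit-time statistics for one mobility component."""

    tau_m_mean: float
    tau_m_sd: float
    D_mean: float
    D_sd: float
    n_maxima: int
    max_extent_below_nm: Optional[float] = None   # farthest detection below x0
    max_extent_above_nm: Optional[float] = None   # farthest detection above x0


@dataclass
class TwoPoolSummary:
    fast: Optional[PoolEstimate]
    slow: Optional[PoolEstimate]
    n_pools: int
    d_nm: float


def exclusion_mask(x0: float, halfwidth_px: int, n_pixels: int) -> np.ndarray:
    """Boolean mask (True = excluded) covering ``halfwidth_px`` pixels on
    both sides of the interface midpoint ``round(x0)``, clipped to the line.

    The region nearest the envelope is dominated by nuclear-pore
    interactions and is left out of the free/bound pool analysis.
    """
    if not (0 <= x0 <= n_pixels - 1):
        raise ValueError(f"x0 = {x0} outside the {n_pixels}-pixel line")
    if halfwidth_px < 0:
        raise ValueError("halfwidth_px must be >= 0")
    center = int(round(x0))
    mask = np.zeros(n_pixels, dtype=bool)
    lo = max(0, center - halfwidth_px)
    hi = min(n_pixels, center + halfwidth_px + 1)
    mask[lo:hi] = True
    return mask


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: values.size]


def _refine_peak(lags: np.ndarray, values: np.ndarray, i: int) -> float:
    """Sub-bin peak position by a parabola in log-lag around bin i."""
    if i == 0 or i == lags.size - 1:
        return float(lags[i])
    x = np.log(lags[i - 1 : i + 2])
    y = values[i - 1 : i + 2]
    denom = (y[0] - 2.0 * y[1] + y[2])
    if denom >= 0:
        return float(lags[i])
    shift = 0.5 * (y[0] - y[2]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    xc = x[1] + shift * (x[2] - x[1] if shift > 0 else x[1] - x[0])
    return float(np.exp(xc))


def detect_maxima(curve: CorrelationCurve, smooth_window: int = 5,
                  z_threshold: float = 3.0, max_search_lag_s: float = 0.02,
                  d_nm: Optional[float] = None, pixel: int = -1,
                  max_maxima: int = 2) -> ColumnClassification:
    """Classify a pair correlation curve and extract its transit maxima.

    The curve is analyzed within ``max_search_lag_s`` (transit maxima of
    interest sit in the 0.1–10 ms range; the long-lag bins of a multi-tau
    curve are sample-starved and carry no transit information) and
    smoothed by a centered moving average over ``smooth_window`` lag
    bins.  The per-bin noise scale σ is estimated robustly from the
    high-frequency residual (curve minus its smooth), so no signal-free
    region needs to be designated.  Smoothed maxima with amplitude
    > z·σ/√window count as significant.  Classes: *zero* if nothing is
    significant, *sigmoidal* if the global maximum sits at the first
    sampled lag, *bell* otherwise, reporting up to ``max_maxima``
    highest interior maxima (fast and slow pools) with parabola-refined
    lags.
    """
    values = np.asarray(curve.values, dtype=float)
    lags = np.asarray(curve.lags, dtype=float)
    window = lags <= max_search_lag_s
    if window.sum() >= smooth_window + 2:
        values = values[window]
        lags = lags[window]
    if values.size < smooth_window + 2:
        raise ValueError(
            f"curve has {values.size} points, shorter than the smoothing "
            f"window {smooth_window}"
        )
    smooth = _smooth(values, smooth_window)
    resid = values - smooth
    # noise scale per bin, estimated robustly per group of 8 bins: on a
    # quasi-logarithmic grid the sample count halves per octave, so the
    # bin noise grows roughly as sqrt(lag) and a single global scale
    # either drowns early peaks or admits late junk
    sigma_bin = np.empty_like(values)
    for a in range(0, values.size, 8):
        chunk = resid[a: a + 8]
        sigma_bin[a: a + 8] = 1.4826 * np.median(np.abs(chunk - np.median(chunk)))
    threshold = z_threshold * sigma_bin / math.sqrt(smooth_window)
    # a candidate maximum must both exceed its local noise floor and rise
    # by at least the noise scale above its surroundings (prominence),
    # which rejects shallow bumps riding on the shoulder of a real peak
    peaks, _ = signal.find_peaks(smooth, prominence=float(np.median(threshold)))
    peaks = peaks[smooth[peaks] > threshold[peaks]]
    global_max = int(np.argmax(smooth))
    if smooth[global_max] <= threshold[global_max]:
        return ColumnClassification(pixel=pixel, shape="zero")
    if global_max == 0 or peaks.size == 0:
        return ColumnClassification(pixel=pixel, shape="sigmoidal")
    order = np.argsort(smooth[peaks])[::-1][:max_maxima]
    chosen = np.sort(peaks[order])
    tau_m = tuple(_refine_peak(lags, smooth, int(i)) for i in chosen)
    amps = tuple(float(values[i]) for i in chosen)
    Ds = tuple(estimate_D_from_tau_max(t, d_nm) for t in tau_m) if d_nm else ()
    return ColumnClassification(
        pixel=pixel, shape="bell", tau_m_list=tau_m, amplitudes=amps,
        D_estimates=Ds,
    )


def _two_means_1d(log_taus: np.ndarray, max_iter: int = 100):
    """Deterministic 1D two-means on log transit times."""
    c = np.array([log_taus.min(), log_taus.max()])
    labels = np.zeros(log_taus.size, dtype=int)
    for _ in range(max_iter):
        new_labels = (np.abs(log_taus - c[1]) < np.abs(log_taus - c[0])).astype(int)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in (0, 1):
            if (labels == j).any():
                c[j] = log_taus[labels == j].mean()
    return labels, c


def _pool_estimate(taus, pixels, d_nm, x0_px, pixel_size_nm):
    taus = np.asarray(taus)
    below = above = None
    if x0_px is not None and pixels:
        px = np.asarray(pixels, dtype=float)
        dist = (px - x0_px) * pixel_size_nm
        if (dist < 0).any():
            below = float(-dist[dist < 0].min())
        if (dist > 0).any():
            above = float(dist[dist > 0].max())
    tau_mean = float(taus.mean())
    tau_sd = float(taus.std(ddof=1)) if taus.size > 1 else 0.0
    # D is evaluated at the pooled mean transit time (the per-column
    # reciprocals 1/tau would bias the pool upward by Jensen's inequality)
    D_mean = estimate_D_from_tau_max(tau_mean, d_nm)
    return PoolEstimate(
        tau_m_mean=tau_mean,
        tau_m_sd=tau_sd,
        D_mean=D_mean,
        D_sd=D_mean * tau_sd / tau_mean,
        n_maxima=int(taus.size),
        max_extent_below_nm=below,
        max_extent_above_nm=above,
    )


def two_pool_summary(classifications: Sequence[ColumnClassification],
                     d_nm: float, x0_px: Optional[float] = None,
                     pixel_size_nm: float = 50.0,
                     min_separation_ratio: float = 2.0) -> TwoPoolSummary:
    """Cluster per-column transit maxima into fast and slow mobility pools.

    All interior maxima of bell-classified columns are split by a 1D
    two-means on log τ_m; two pools are declared only when the cluster
    centers differ by at least ``min_separation_ratio`` (the free and
    complex-bound pools differ ~4-fold in vivo), otherwise a single pool
    is reported as *fast*.  When the interface position ``x0_px`` is
    known, the farthest slow-pool detection on either side of it is
    reported in nm.
    """
    entries = [
        (t, c.pixel)
        for c in classifications if c.shape == "bell"
        for t in c.tau_m_list
    ]
    n_bell = sum(1 for c in classifications if c.shape == "bell")
    if n_bell < 3:
        raise ValueError(
            f"need at least 3 bell-classified columns, got {n_bell}"
        )
    taus = np.array([e[0] for e in entries])
    pixels = [e[1] for e in entries]
    log_taus = np.log(taus)
    labels, centers = _two_means_1d(log_taus)
    ratio = float(np.exp(abs(centers[1] - centers[0])))
    # a pool must be populated by several columns — a lone stray maximum
    # (noise) is not a mobility component
    min_members = max(3, round(0.1 * taus.size))
    both_populated = ((labels == 0).sum() >= min_members
                      and (labels == 1).sum() >= min_members)
    if both_populated and ratio >= min_separation_ratio:
        fast_label = int(centers.argmin())
        fast_idx = labels == fast_label
        slow_idx = ~fast_idx
        fast = _pool_estimate(taus[fast_idx],
                              [p for p, k in zip(pixels, fast_idx) if k],
                              d_nm, x0_px, pixel_size_nm)
        slow = _pool_estimate(taus[slow_idx],
                              [p for p, k in zip(pixels, slow_idx) if k],
                              d_nm, x0_px, pixel_size_nm)
        return TwoPoolSummary(fast=fast, slow=slow, n_pools=2, d_nm=d_nm)
    fast = _pool_estimate(taus, pixels, d_nm, x0_px, pixel_size_nm)
    return TwoPoolSummary(fast=fast, slow=None, n_pools=1, d_nm=d_nm)


@dataclass
class AnalysisSettings:
    """Configuration of the end-to-end carpet analysis."""

    distance_n: int = 4
    lag_scheme: str = "multitau"
    detrend: bool = False
    segment_length: int = 1000
    locate_interface: bool = True
    x0_px: Optional[float] = None   # known interface position; skips localization
    bin_factor: int = 20
    exclusion_halfwidth: int = 4
    smooth_window: int = 5
    z_threshold: float = 3.0
    pool_separation_ratio: float = 2.0
    d_nm: Optional[float] = None    # default |n| * pixel size
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything the analysis produced, JSON-serializable.

    Every reported diffusion coefficient traces back to a transit maximum
    τ_m and the pair distance d recorded next to it.
    """

    settings: AnalysisSettings
    envelope: Optional[EnvelopeSummary]
    excluded_pixels: list
    classifications_forward: List[ColumnClassification]
    classifications_backward: List[ColumnClassification]
    pools_forward: Optional[TwoPoolSummary]
    pools_backward: Optional[TwoPoolSummary]
    d_nm: float
    config_hash: str
    seed: int
    software_version: str
    pcf_forward: Optional[PCFCarpet] = None
    pcf_backward: Optional[PCFCarpet] = None

    def to_dict(self) -> dict:
        def pool(p):
            return None if p is None else {
                "fast": None if p.fast is None else asdict(p.fast),
                "slow": None if p.slow is None else asdict(p.slow),
                "n_pools": p.n_pools,
                "d_nm": p.d_nm,
            }
        return {
            "settings": self.settings.to_dict(),
            "envelope": None if self.envelope is None else asdict(self.envelope),
            "excluded_pixels": list(map(int, self.excluded_pixels)),
            "classifications_forward": [asdict(c) for c in self.classifications_forward],
            "classifications_backward": [asdict(c) for c in self.classifications_backward],
            "pools_forward": pool(self.pools_forward),
            "pools_backward": pool(self.pools_backward),
            "d_nm": self.d_nm,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "software_version": self.software_version,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def run_analysis(carpet: LineScanCarpet,
                 settings: Optional[AnalysisSettings] = None) -> AnalysisReport:
    """Run the full carpet analysis.

    Stages, in order: optional detrend → interface localization →
    exclusion zone around the interface → pair correlation carpets at
    ±``distance_n`` (both scan directions, never merged — the forward/
    backward asymmetry carries the transport directionality) → per-column
    maxima classification → fast/slow pool summaries.  Deterministic for
    fixed carpet and settings (the detrend filler is seeded).
    """
    import stedpcf

    settings = settings or AnalysisSettings()
    d_nm = settings.d_nm
    if d_nm is None:
        d_nm = abs(settings.distance_n) * carpet.pixel_size * 1e9
    work = carpet
    if settings.detrend:
        try:
            work = detrend_carpet(carpet, settings.segment_length, settings.seed)
        except ValueError as exc:
            raise RuntimeError(f"detrend stage failed: {exc}") from exc

    envelope = None
    x0 = settings.x0_px
    if x0 is None and settings.locate_interface:
        try:
            envelope = locate_envelope(work, settings.bin_factor)
            x0 = envelope.x0_mean
        except (RuntimeError, ValueError) as exc:
            logger.warning("interface localization failed (%s); continuing "
                           "without exclusion zone", exc)
    if x0 is not None:
        mask = exclusion_mask(x0, settings.exclusion_halfwidth, carpet.n_pixels)
    else:
        mask = np.zeros(carpet.n_pixels, dtype=bool)

    n = abs(settings.distance_n)
    results = {}
    for sign, key in ((+1, "forward"), (-1, "backward")):
        try:
            pcf = pcf_carpet(work, sign * n, settings.lag_scheme)
        except ValueError as exc:
            raise RuntimeError(f"pcf stage ({key}) failed: {exc}") from exc
        classifications = []
        for j, p in enumerate(pcf.column_pixels):
            q = p + pcf.distance_n
            if mask[p] or mask[q]:
                continue
            curve = CorrelationCurve(lags=pcf.lags, values=pcf.values[:, j],
                                     pixel_pair=(int(p), int(q)))
            classifications.append(detect_maxima(
                curve, settings.smooth_window, settings.z_threshold,
                d_nm=d_nm, pixel=int(p),
            ))
        try:
            pools = two_pool_summary(
                classifications, d_nm,
                x0_px=x0,
                pixel_size_nm=carpet.pixel_size * 1e9,
                min_separation_ratio=settings.pool_separation_ratio,
            )
        except ValueError as exc:
            logger.info("no pool summary for %s direction: %s", key, exc)
            pools = None
        results[key] = (pcf, classifications, pools)

    return AnalysisReport(
        settings=settings,
        envelope=envelope,
        excluded_pixels=list(np.nonzero(mask)[0]),
        classifications_forward=results["forward"][1],
        classifications_backward=results["backward"][1],
        pools_forward=results["forward"][2],
        pools_backward=results["backward"][2],
        d_nm=float(d_nm),
        config_hash=settings.config_hash(),
        seed=settings.seed,
        software_version=stedpcf.__version__,
        pcf_forward=results["forward"][0],
        pcf_backward=results["backward"][0],
    )
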