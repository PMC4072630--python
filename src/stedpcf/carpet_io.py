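"""Reading, writing and reshaping line-scan intensity carpets.

An intensity carpet is the 2D photon-count record of a repeated line scan:
row ``i`` holds the counts of the ``i``-th sweep of the line (time axis),
column ``p`` the counts collected at pixel ``p`` along the line (space
axis).  Carpets travel as single-plane grayscale TIFF or plain CSV plus a
JSON metadata sidecar carrying the physical units, so the pixel data stay
unit-free.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Defaults applied when no sidecar is present: 50 nm pixels scanned at
#: 8 kHz (0.125 ms per line), the acquisition geometry this package targets.
DEFAULT_PIXEL_SIZE_NM = 50.0
DEFAULT_LINE_PERIOD_MS = 0.125

SIDECAR_SUFFIX = ".meta.json"


@dataclass(frozen=True)
class LineScanCarpet:
    """Photon-count matrix of a repeated line scan plus acquisition metadata.

    Parameters
    ----------
    counts
        Non-negative array of shape ``(n_lines, n_pixels)``; row 0 is the
        earliest line, column 0 the first pixel of the scan line.
    line_period
        Seconds per line (time between successive rows).
    pixel_size
        Meters per pixel along the scan line.
    origin_label
        Free text recording the orientation of the line (e.g. which end
        is the nucleus).
    acquisition_id
        Free-text identifier of the acquisition.
    """

    counts: np.ndarray
    line_period: float
    pixel_size: float
    origin_label: str = ""
    acquisition_id: str = ""
    mode: str = "synthetic"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2D, got shape {counts.shape}")
        # a single-row carpet is a legal degenerate case (e.g. the result
        # of binning every line together); correlation requires >= 2 rows
        # and fails loudly downstream
        if counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ValueError(
                f"carpet needs at least 1 line and 2 pixels, got {counts.shape}"
            )
        if not np.isfinite(counts).all():
            raise ValueError("counts contain non-finite entries")
        if (counts < 0).any():
            raise ValueError("counts contain negative entries")
        if not self.line_period > 0:
            raise ValueError(f"line_period must be > 0, got {self.line_period}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "counts", counts)

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.n_lines * self.line_period

    @property
    def times(self) -> np.ndarray:
        """Start time of each line in seconds."""
        return np.arange(self.n_lines) * self.line_period

    @property
    def pixel_positions(self) -> np.ndarray:
        """Position of each pixel along the line in meters."""
        return np.arange(self.n_pixels) * self.pixel_size

    def metadata(self) -> "CarpetMetadata":
        return CarpetMetadata(
            pixel_size_nm=self.pixel_size * 1e9,
            line_period_ms=self.line_period * 1e3,
            n_lines=self.n_lines,
            n_pixels=self.n_pixels,
            mode=self.mode,
        )


@dataclass(frozen=True)
class CarpetMetadata:
    """Physical metadata of a carpet, round-tripped through the JSON sidecar."""

    pixel_size_nm: float
    line_period_ms: float
    n_lines: int
    n_pixels: int
    mode: str = "synthetic"

    _MODES = ("confocal", "sted", "synthetic")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if not (self.pixel_size_nm > 0 and self.line_period_ms > 0):
            raise ValueError("pixel_size_nm and line_period_ms must be positive")

    def to_dict(self) -> dict:
        return {
            "pixel_size_nm": self.pixel_size_nm,
            "line_period_ms": self.line_period_ms,
            "n_lines": int(self.n_lines),
            "n_pixels": int(self.n_pixels),
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CarpetMetadata":
        return cls(
            pixel_size_nm=float(d["pixel_size_nm"]),
            line_period_ms=float(d["line_period_ms"]),
            n_lines=int(d["n_lines"]),
            n_pixels=int(d["n_pixels"]),
            mode=str(d.get("mode", "synthetic")),
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + SIDECAR_SUFFIX)


def read_carpet(path, sidecar=None) -> LineScanCarpet:
    """Read an intensity carpet from TIFF or CSV with an optional JSON sidecar.

    If ``sidecar`` is None, ``<name>.meta.json`` next to ``path`` is used
    when present; otherwise the documented defaults (50 nm pixel, 0.125 ms
    line) are applied and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        counts = np.asarray(tifffile.imread(path))
    else:
        counts = np.loadtxt(path, delimiter=",", ndmin=2)
    if counts.ndim != 2:
        raise ValueError(f"{path} does not contain a single 2D plane")
    if (counts < 0).any():
        raise ValueError(f"{path} contains negative count values")

    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    mode = "synthetic"
    if sidecar.exists():
        meta = CarpetMetadata.from_dict(json.loads(sidecar.read_text()))
        if (meta.n_lines, meta.n_pixels) != counts.shape:
            raise ValueError(
                f"sidecar {sidecar} declares shape "
                f"({meta.n_lines}, {meta.n_pixels}) but data is {counts.shape}"
            )
        pixel_size = meta.pixel_size_nm * 1e-9
        line_period = meta.line_period_ms * 1e-3
        mode = meta.mode
    else:
        pixel_size = DEFAULT_PIXEL_SIZE_NM * 1e-9
        line_period = DEFAULT_LINE_PERIOD_MS * 1e-3
        logger.warning(
            "no metadata sidecar for %s; assuming %.0f nm pixels, %.3f ms/line",
            path, DEFAULT_PIXEL_SIZE_NM, DEFAULT_LINE_PERIOD_MS,
        )
    return LineScanCarpet(
        counts=counts,
        line_period=line_period,
        pixel_size=pixel_size,
        acquisition_id=path.stem,
        mode=mode,
    )


def write_carpet(carpet: LineScanCarpet, path) -> None:
    """Write a carpet to TIFF or CSV (chosen by extension) plus a JSON sidecar.

    Integral counts are stored as 32-bit unsigned integers, otherwise as
    32-bit float (64-bit in CSV).  ``read_carpet`` inverts the write
    bit-exactly for integer carpets.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"target directory {path.parent} does not exist")
    counts = carpet.counts
    integral = np.all(np.mod(counts, 1) == 0) and counts.max(initial=0) < 2**32
    if path.suffix.lower() in (".tif", ".tiff"):
        data = counts.astype(np.uint32 if integral else np.float32)
        tifffile.imwrite(path, data)
    else:
        fmt = "%d" if integral else "%.17g"
        np.savetxt(path, counts, delimiter=",", fmt=fmt)
    _sidecar_path(path).write_text(
        json.dumps(carpet.metadata().to_dict(), indent=1)
    )


def bin_lines(carpet: LineScanCarpet, factor: int) -> LineScanCarpet:
    """Average every ``factor`` consecutive lines into one.

    The output has ``floor(n_lines / factor)`` rows, each the arithmetic
    mean of ``factor`` input rows, and a line period ``factor`` times
    longer.  Trailing lines that do not fill a complete group are dropped.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor > carpet.n_lines:
        raise ValueError(
            f"factor {factor} exceeds the number of lines {carpet.n_lines}"
        )
    n_out = carpet.n_lines // factor
    if factor == 1:
        return carpet
    dropped = carpet.n_lines - n_out * factor
    if dropped:
        logger.info("bin_lines: dropping %d trailing lines", dropped)
    used = carpet.counts[: n_out * factor].astype(float)
    binned = used.reshape(n_out, factor, carpet.n_pixels).mean(axis=1)
    return replace(carpet, counts=binned, line_period=carpet.line_period * factor)


def column_trace(carpet: LineScanCarpet, p: int) -> np.ndarray:
    """Return the time series of counts at pixel ``p`` (one sample per line)."""
    if not (0 <= p < carpet.n_pixels):
        raise IndexError(
            f"pixel index {p} out of range for {carpet.n_pixels}-pixel carpet"
        )
    return carpet.counts[:, p]
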