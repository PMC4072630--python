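"""Brownian-dynamics photon-count simulator of confocal/STED line scans.

Point particles diffuse in a 3D box while a Gaussian excitation/detection
volume is raster-scanned along a 64-pixel (configurable) line.  Each pixel
dwell yields a Poisson photon count whose mean is the sum of per-particle
emissions

    brightness * exp(-2 (dx² + dy²) / w_xy²  -  2 dz² / w_z²),

the 1/e² convention, so the simulator's ``w_xy`` is identical to the
``w_xy`` of the analytic correlation models.  Optional features emulate
the realities of in-cell acquisitions: a semi-permeable barrier plane
(nuclear envelope), a slow-diffusion zone around it (transport-complex
binding), per-particle photobleaching, and uniform background counts.

Geometry: the box is periodic in y and z; in x it is periodic for
barrier-free runs and bounded by reflecting walls when a barrier is
present (so that "left of the barrier" is well defined).  Margins of a
few PSF radii around the scanned line keep boundary images negligible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from stedpcf._kernels import X_PERIODIC, X_REFLECT, scan_chunk
from stedpcf.carpet_io import LineScanCarpet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Species:
    """One diffusing species.

    D is the diffusion coefficient in µm²/s, ``fraction`` the share of the
    particle pool, and ``brightness`` the expected counts per pixel dwell
    emitted by one particle sitting at the PSF center.
    """

    D: float
    fraction: float = 1.0
    brightness: float = 2.0

    def __post_init__(self):
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if not (0 <= self.fraction <= 1):
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.brightness < 0:
            raise ValueError(f"brightness must be >= 0, got {self.brightness}")


@dataclass(frozen=True)
class PSFModel:
    """3D Gaussian observation volume.

    ``w_xy`` is the 1/e² radial radius in nm; the axial 1/e² radius is
    ``S * w_xy``.  Typical values: 275 nm / S = 5 for confocal, 110 nm /
    S = 10 for CW-STED (the depletion beam shrinks only the radial
    extent).
    """

    w_xy: float
    S: float

    def __post_init__(self):
        if self.w_xy <= 0:
            raise ValueError(f"w_xy must be > 0, got {self.w_xy}")
        if self.S < 1:
            raise ValueError(f"S must be >= 1, got {self.S}")

    @property
    def w_z(self) -> float:
        """Axial 1/e² radius in nm."""
        return self.S * self.w_xy

    @property
    def effective_volume_um3(self) -> float:
        """FCS effective volume π^{3/2} w_xy² w_z in µm³."""
        w = self.w_xy * 1e-3
        return math.pi ** 1.5 * w * w * (self.w_z * 1e-3)


@dataclass(frozen=True)
class BarrierSpec:
    """Semi-permeable plane perpendicular to the scan line.

    ``permeability`` is the probability that an attempted crossing of the
    plane succeeds in one time step; 0 is an impermeable wall, 1 no
    barrier at all.  Optionally, inside ``slow_zone_halfwidth`` nm of the
    plane every particle diffuses with ``slow_zone_D`` instead of its own
    D, emulating transient binding to transport machinery near the
    envelope.
    """

    position_x: float            # nm along the scan line
    permeability: float = 0.0
    slow_zone_halfwidth: float = 0.0
    slow_zone_D: float = 0.0

    def __post_init__(self):
        if not (0 <= self.permeability <= 1):
            raise ValueError(
                f"permeability must be in [0, 1], got {self.permeability}"
            )
        if self.slow_zone_halfwidth < 0 or self.slow_zone_D < 0:
            raise ValueError("slow zone parameters must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic line-scan experiment."""

    species: Sequence[Species]
    psf: PSFModel
    n_pixels: int = 64
    pixel_size: float = 50.0        # nm
    line_period: float = 0.125      # ms
    n_lines: int = 200_000
    n_particles: int = 100
    box_y: Optional[float] = None   # nm, periodic extent; default 10 w_xy
    box_z: Optional[float] = None   # nm, periodic extent; default 3.5 w_z
    x_margin: Optional[float] = None  # nm each side of the line; default 3 w_xy
    background: float = 0.0         # expected counts per dwell
    bleach_rate: float = 0.0        # 1/s probability of irreversible loss
    barrier: Optional[BarrierSpec] = None
    poisson_noise: bool = True
    initial_positions: Optional[tuple] = None  # (n,3) nm; None -> uniform
    seed: int = 0

    def __post_init__(self):
        if not self.species:
            raise ValueError("at least one species required")
        total = sum(s.fraction for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions must sum to 1, got {total}")
        for name in ("n_pixels", "pixel_size", "line_period", "n_lines"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_particles < 0 or self.background < 0 or self.bleach_rate < 0:
            raise ValueError("n_particles, background, bleach_rate must be >= 0")
        if self.n_particles == 0 and self.background == 0:
            logger.warning("zero particles and zero background: all-zero carpet")

    # -- derived geometry (all in µm) ------------------------------------
    @property
    def dwell(self) -> float:
        """Pixel dwell time in seconds."""
        return self.line_period * 1e-3 / self.n_pixels

    @property
    def scan_length_um(self) -> float:
        return (self.n_pixels - 1) * self.pixel_size * 1e-3

    def box_geometry(self):
        """Return (x_lo, x_hi, x_mode, y_half, z_half) in µm."""
        w = self.psf.w_xy * 1e-3
        wz = self.psf.w_z * 1e-3
        margin = (self.x_margin * 1e-3) if self.x_margin is not None else 3.0 * w
        x_lo = -margin
        x_hi = self.scan_length_um + margin
        x_mode = X_REFLECT if self.barrier is not None else X_PERIODIC
        # the periodic transverse box must be wide relative to the PSF so
        # that its discrete diffusion modes resolve the continuum decay of
        # the correlation; 10 w_xy in y keeps the distortion of fitted D
        # below ~5%
        by = (self.box_y * 1e-3) if self.box_y is not None else 10.0 * w
        bz = (self.box_z * 1e-3) if self.box_z is not None else 3.5 * wz
        return x_lo, x_hi, x_mode, by / 2.0, bz / 2.0

    @property
    def box_volume_um3(self) -> float:
        x_lo, x_hi, _, y_half, z_half = self.box_geometry()
        return (x_hi - x_lo) * 2 * y_half * 2 * z_half

    @property
    def mean_particles_in_focus(self) -> float:
        """Expected particle number in the FCS effective volume."""
        return self.n_particles / self.box_volume_um3 * self.psf.effective_volume_um3

    def to_json(self) -> str:
        d = {
            "species": [vars(s) for s in self.species],
            "psf": vars(self.psf),
            "barrier": vars(self.barrier) if self.barrier else None,
        }
        for k in ("n_pixels", "pixel_size", "line_period", "n_lines",
                  "n_particles", "box_y", "box_z", "x_margin", "background",
                  "bleach_rate", "poisson_noise", "seed"):
            d[k] = getattr(self, k)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        species = tuple(Species(**s) for s in d.pop("species"))
        psf = PSFModel(**d.pop("psf"))
        barrier = d.pop("barrier", None)
        if barrier is not None:
            barrier = BarrierSpec(**barrier)
        return cls(species=species, psf=psf, barrier=barrier, **d)


def particles_for_focal_number(config_volume_um3: float, psf: PSFModel,
                               n_focus: float) -> int:
    """Particle count that puts on average ``n_focus`` particles in the
    effective volume of ``psf`` for a box of the given volume."""
    return max(1, round(n_focus / psf.effective_volume_um3 * config_volume_um3))


def _init_particles(config: SimulationConfig, rng: np.random.Generator):
    """Draw initial positions (uniform in the box) and per-particle D and
    brightness according to the species fractions."""
    n = config.n_particles
    x_lo, x_hi, _, y_half, z_half = config.box_geometry()
    if config.initial_positions is not None:
        pos = np.asarray(config.initial_positions, dtype=float) * 1e-3
        if pos.shape != (n, 3):
            raise ValueError(
                f"initial_positions must have shape ({n}, 3), got {pos.shape}"
            )
        x, y, z = pos[:, 0].copy(), pos[:, 1].copy(), pos[:, 2].copy()
    else:
        x = rng.uniform(x_lo, x_hi, n)
        y = rng.uniform(-y_half, y_half, n)
        z = rng.uniform(-z_half, z_half, n)
    fractions = np.array([s.fraction for s in config.species])
    counts = rng.multinomial(n, fractions)
    D = np.empty(n)
    brightness = np.empty(n)
    start = 0
    for sp, c in zip(config.species, counts):
        D[start:start + c] = sp.D
        brightness[start:start + c] = sp.brightness
        start += c
    return x, y, z, D, brightness


def simulate_carpet(config: SimulationConfig, return_trajectories: bool = False,
                    traj_stride: int = 0):
    """Simulate one line-scan acquisition.

    Returns a :class:`LineScanCarpet`; with ``return_trajectories=True``
    additionally returns an array of unwrapped particle positions
    ``(n_stores, n_particles, 3)`` sampled every ``traj_stride`` dwells
    (for mean-square-displacement checks).  The same config (including
    seed) always produces the identical carpet.
    """
    rng = np.random.default_rng(config.seed)
    x, y, z, D, brightness = _init_particles(config, rng)
    x_lo, x_hi, x_mode, y_half, z_half = config.box_geometry()
    pixel_x = np.arange(config.n_pixels) * config.pixel_size * 1e-3
    bleach_p = 1.0 - math.exp(-config.bleach_rate * config.dwell)
    barrier = config.barrier
    has_barrier = barrier is not None
    n_steps = config.n_lines * config.n_pixels
    if return_trajectories and traj_stride < 1:
        traj_stride = config.n_pixels  # one sample per line
    n_stores = (n_steps // traj_stride) if traj_stride > 0 else 0
    traj = np.zeros((n_stores, config.n_particles, 3))

    counts = np.zeros((config.n_lines, config.n_pixels))
    alive = np.ones(config.n_particles, dtype=bool)
    ux, uy, uz = x.copy(), y.copy(), z.copy()
    sigma0 = np.sqrt(2.0 * D * config.dwell)
    sigma_zone = (
        math.sqrt(2.0 * barrier.slow_zone_D * config.dwell) if has_barrier else 0.0
    )
    # chunked execution: displacement normals are pre-generated per chunk
    # with the vectorized numpy generator, Poisson/uniform draws come from
    # a per-chunk 32-bit seed inside the kernel
    n_part = max(config.n_particles, 1)
    chunk_lines = max(1, min(config.n_lines,
                             1_000_000 // (n_part * config.n_pixels) + 1))
    step, store = 0, 0
    line0 = 0
    while line0 < config.n_lines:
        nl = min(chunk_lines, config.n_lines - line0)
        normals = rng.standard_normal((nl * config.n_pixels,
                                       config.n_particles, 3))
        chunk_seed = int(rng.integers(0, 2**31 - 1))
        step, store = scan_chunk(
            chunk_seed, line0, nl, counts, pixel_x,
            x, y, z, ux, uy, uz, alive,
            D == 0.0, sigma0, sigma_zone, brightness, normals,
            config.psf.w_xy * 1e-3, config.psf.w_z * 1e-3,
            x_lo, x_hi, x_mode, y_half, z_half,
            config.background, bleach_p,
            has_barrier,
            (barrier.position_x * 1e-3) if has_barrier else 0.0,
            barrier.permeability if has_barrier else 1.0,
            (barrier.slow_zone_halfwidth * 1e-3) if has_barrier else 0.0,
            config.poisson_noise,
            traj_stride if n_stores else 0,
            step, store, traj,
        )
        line0 += nl
    mode = "sted" if config.psf.w_xy < 200 else "confocal"
    carpet = LineScanCarpet(
        counts=counts,
        line_period=config.line_period * 1e-3,
        pixel_size=config.pixel_size * 1e-9,
        acquisition_id=f"sim-seed{config.seed}",
        mode=mode,
    )
    if return_trajectories:
        return carpet, traj
    return carpet


def simulate_spot_image(psf: PSFModel, emitter_positions: Sequence, pixel_size: float,
                        image_size: int, brightness: float = 1000.0,
                        poisson_noise: bool = False, seed: int = 0) -> np.ndarray:
    """Image point emitters through the radial Gaussian PSF.

    ``emitter_positions`` are (x, y) pairs in nm; ``pixel_size`` in nm;
    the output is an ``image_size`` × ``image_size`` intensity image.
    Used to exercise FWHM-based resolution analysis of bead/particle
    images.
    """
    if image_size <= 0:
        raise ValueError(f"image_size must be positive, got {image_size}")
    positions = np.atleast_2d(np.asarray(emitter_positions, dtype=float))
    if positions.size == 0:
        raise ValueError("emitter list is empty")
    extent = image_size * pixel_size
    if (positions < 0).any() or (positions > extent).any():
        raise ValueError("emitter positions outside image bounds")
    coords = (np.arange(image_size) + 0.5) * pixel_size
    xx, yy = np.meshgrid(coords, coords)  # xx varies along columns
    image = np.zeros((image_size, image_size))
    for ex, ey in positions:
        r2 = (xx - ex) ** 2 + (yy - ey) ** 2
        image += brightness * np.exp(-2.0 * r2 / psf.w_xy ** 2)
    if poisson_noise:
        image = np.random.default_rng(seed).poisson(image).astype(float)
    return image


def apply_bleaching_trend(carpet: LineScanCarpet, total_loss_fraction: float,
                          seed: int = 0) -> LineScanCarpet:
    """Impose an exponential photobleaching trend on a carpet.

    The expected intensity decays exponentially in time, reaching
    ``1 - total_loss_fraction`` of the initial value at the final line.
    Counts are re-sampled by binomial thinning, which turns Poisson counts
    of mean µ exactly into Poisson counts of the decayed mean.  Exists so
    the detrend filter can be tested against a bleach-free twin of the
    same carpet.
    """
    if not (0 <= total_loss_fraction < 1):
        raise ValueError(
            f"total_loss_fraction must be in [0, 1), got {total_loss_fraction}"
        )
    if total_loss_fraction == 0:
        return carpet
    rng = np.random.default_rng(seed)
    n = carpet.n_lines
    # decay(t) = exp(-k t) with decay at the last line = 1 - loss
    k = -math.log(1.0 - total_loss_fraction)
    decay = np.exp(-k * np.arange(n) / (n - 1))
    counts = carpet.counts
    if np.all(np.mod(counts, 1) == 0):
        thinned = rng.binomial(counts.astype(np.int64), decay[:, None])
    else:
        thinned = rng.poisson(counts * decay[:, None])
    return LineScanCarpet(
        counts=thinned.astype(float),
        line_period=carpet.line_period,
        pixel_size=carpet.pixel_size,
        origin_label=carpet.origin_label,
        acquisition_id=carpet.acquisition_id + "+bleach",
        mode=carpet.mode,
    )
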