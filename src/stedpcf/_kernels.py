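"""Numba kernel for the Brownian-dynamics line-scan simulator.

The kernel advances every particle once per pixel dwell and evaluates the
photon emission law at each dwell, so that motion occurring *within* a
line is correlated correctly (at D = 20 µm²/s a particle moves ~70 nm per
line period, larger than a pixel).

The simulation is processed in chunks of lines: the unit-variance
Gaussian displacement factors are pre-generated per chunk with numpy's
vectorized generator (much faster than drawing scalars in the loop),
while the mean-dependent Poisson counts and the bleaching/barrier
uniforms are drawn inside the kernel from a per-chunk seed.  All seeds
derive from the single config seed, so the output is bit-reproducible.

Emission is cut off beyond 3 radial PSF radii from the beam axis
(relative weight exp(-18) ≈ 1.5e-8), which skips the exponential for the
majority of box particles at any given dwell.
"""

import numpy as np
from numba import njit

# x-boundary handling codes
X_REFLECT = 0
X_PERIODIC = 1


@njit(cache=True, fastmath=True)
def scan_chunk(
    seed,             # per-chunk seed for Poisson/uniform draws
    line0,            # first line of this chunk
    chunk_lines,
    counts,           # (n_lines, n_pixels) output, written in place
    pixel_x,          # (n_pixels,) beam center positions, µm
    x, y, z,          # (n_particles,) positions, µm; mutated in place
    ux, uy, uz,       # unwrapped accumulators for trajectories
    alive,            # (n_particles,) bool; mutated in place
    D_is_zero,        # (n_particles,) bool; immobile particles skip motion
    sigma0,           # (n_particles,) per-dwell step size, µm
    sigma_zone,       # step size inside the slow zone, µm
    brightness,       # (n_particles,) expected counts/dwell at PSF center
    normals,          # (chunk_lines * n_pixels, n_particles, 3) N(0,1) draws
    w_xy, w_z,        # µm, 1/e² PSF radii
    x_lo, x_hi,       # x box bounds, µm
    x_mode,           # X_REFLECT or X_PERIODIC
    y_half, z_half,   # half-extents of the periodic y/z box, µm
    background,       # expected background counts/dwell
    bleach_p,         # per-dwell bleaching probability
    has_barrier,
    barrier_x,        # µm
    permeability,     # crossing acceptance probability
    zone_halfwidth,   # µm; 0 disables the slow zone
    poisson_noise,    # False -> write expectation values
    traj_stride,      # 0 disables trajectory recording
    step0,            # global dwell counter at chunk start
    store0,           # trajectory rows already written
    traj,             # (n_stores, n_particles, 3) output
):
    np.random.seed(seed)
    n_pixels = pixel_x.size
    n_particles = x.size
    cut = 3.0 * w_xy
    inv_wxy2 = 1.0 / (w_xy * w_xy)
    inv_wz2 = 1.0 / (w_z * w_z)
    x_span = x_hi - x_lo
    has_zone = zone_halfwidth > 0.0
    record = traj_stride > 0
    step = step0
    store = store0
    row = 0
    for line in range(line0, line0 + chunk_lines):
        for p in range(n_pixels):
            bx = pixel_x[p]
            mean = background
            for i in range(n_particles):
                if not alive[i]:
                    continue
                # emission from the pre-move position
                dx = x[i] - bx
                if -cut < dx < cut:
                    arg = 2.0 * ((dx * dx + y[i] * y[i]) * inv_wxy2
                                 + z[i] * z[i] * inv_wz2)
                    if arg < 36.0:
                        mean += brightness[i] * np.exp(-arg)
                # advance this particle by one dwell
                if bleach_p > 0.0 and np.random.random() < bleach_p:
                    alive[i] = False
                    continue
                if D_is_zero[i]:
                    continue
                sigma = sigma0[i]
                if has_zone and abs(x[i] - barrier_x) <= zone_halfwidth:
                    sigma = sigma_zone
                sx = sigma * normals[row, i, 0]
                sy = sigma * normals[row, i, 1]
                sz = sigma * normals[row, i, 2]
                xn = x[i] + sx
                if has_barrier:
                    crossed = (x[i] - barrier_x) * (xn - barrier_x) < 0.0
                    if crossed and np.random.random() >= permeability:
                        xn = 2.0 * barrier_x - xn  # elastic reflection
                        sx = xn - x[i]
                # x boundary
                if x_mode == X_PERIODIC:
                    if xn >= x_hi:
                        xn -= x_span
                    elif xn < x_lo:
                        xn += x_span
                else:
                    if xn > x_hi:
                        xn = 2.0 * x_hi - xn
                    elif xn < x_lo:
                        xn = 2.0 * x_lo - xn
                x[i] = xn
                yn = y[i] + sy
                if yn >= y_half:
                    yn -= 2.0 * y_half
                elif yn < -y_half:
                    yn += 2.0 * y_half
                y[i] = yn
                zn = z[i] + sz
                if zn >= z_half:
                    zn -= 2.0 * z_half
                elif zn < -z_half:
                    zn += 2.0 * z_half
                z[i] = zn
                if record:
                    ux[i] += sx
                    uy[i] += sy
                    uz[i] += sz
            if poisson_noise:
                counts[line, p] = np.random.poisson(mean)
            else:
                counts[line, p] = mean
            step += 1
            row += 1
            if record and step % traj_stride == 0 and store < traj.shape[0]:
                for i in range(n_particles):
                    traj[store, i, 0] = ux[i]
                    traj[store, i, 1] = uy[i]
                    traj[store, i, 2] = uz[i]
                store += 1
    return step, store
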