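# stedpcf

Pair correlation analysis of confocal/STED line-scan intensity carpets:
sub-diffraction mapping of protein mobility along a scanned line.

## What it does, and for whom

Repeatedly scanning a focused laser along one line at kHz rates yields an
*intensity carpet* `F(t, p)` — photon counts per pixel `p` and line `t`.
Cross-correlating two columns `n` pixels apart,

```
pCF(τ; p, p+n) = ⟨F(t,p) F(t+τ,p+n)⟩ / (⟨F(t,p)⟩⟨F(t,p+n)⟩) − 1
```

(the pair correlation function, pCF(n)) measures the time molecules take
to travel between the two positions. Its shape reads out local transport:
**sigmoidal** when the pixel pair falls within one resolution element,
**bell-shaped** with a maximum at the modal transit time τ_m when the
pair is resolved, **zero** when a barrier blocks exchange. With a STED
(stimulated emission depletion) microscope the effective point spread
function shrinks from ~275 nm to ~110 nm, so distances of 3–4 pixels
(150–200 nm) become resolvable and the carpet turns into a diffusion map
below the diffraction limit — including barriers and slow, bound pools
near the nuclear envelope that confocal acquisition cannot see.

The package is for microscopists and quantitative cell biologists doing
line-scan fluctuation spectroscopy: it reads/writes carpets (TIFF/CSV +
JSON sidecar), computes multi-tau pair correlations with photobleaching
detrending, fits the standard FCS diffusion models, localizes the
nucleus/cytoplasm interface, classifies per-column curve shapes,
estimates local diffusion coefficients from transit maxima
(`D = d²/(4 τ_m)`), and ships a Brownian-dynamics photon-count simulator
that generates every test input.

Core relations (3D diffusion through a Gaussian volume, radial 1/e²
radius `w_xy`, axial ratio `S`, occupancy `N`, pair displacement `d`):

```
G(τ)        = (1/N) (1 + τ/τ_D)^(-1) (1 + τ/(S²τ_D))^(-1/2),   τ_D = w_xy²/(4D)
G_x(τ; d)   = G(τ) · exp(−(d/w_xy)² / (1 + τ/τ_D))
τ_m (exact) : positive root of 3u² + (2S²+4−2a)u + (2S²+1−2aS²) = 0,
              a = (d/w_xy)², u = τ/τ_D
τ_m (w≪d)   ≈ d²/(4D)   ⇒   D = d²/(4τ_m)
```

## Worked example

Simulate a STED-like acquisition of freely diffusing bright particles
(D = 8.5 µm²/s, w_xy = 110 nm, 50 000 lines of 64 pixels at 0.125
ms/line), then analyze it:

```python
from dataclasses import replace
from stedpcf import (SimulationConfig, Species, PSFModel, simulate_carpet,
                     pcf_carpet, average_pcf, fit_correlation)
from stedpcf.simulate import particles_for_focal_number
from stedpcf.pipeline import detect_maxima

psf = PSFModel(w_xy=110.0, S=10.0)           # STED-like observation volume
cfg = SimulationConfig(
    species=(Species(D=8.5, brightness=2.0),),
    psf=psf, n_pixels=64, n_lines=50_000, n_particles=1,
    background=0.02, seed=7,
)
cfg = replace(cfg, n_particles=particles_for_focal_number(
    cfg.box_volume_um3, psf, 1.2))            # ~1.2 particles in focus
carpet = simulate_carpet(cfg)

acf = average_pcf(pcf_carpet(carpet, 0))      # pCF(0) = autocorrelation
fit = fit_correlation(acf, "acf_3d", free=("D", "N"),
                      fixed={"w_xy": 110.0, "S": 10.0}, max_lag_s=1.0)
print(f"pCF(0) fit:  D = {fit.params['D']:.1f} um^2/s,  N = {fit.params['N']:.2f}")

pcf3 = average_pcf(pcf_carpet(carpet, 3))     # 150 nm pair distance
shape = detect_maxima(pcf3, smooth_window=3, d_nm=150.0)
print(f"pCF(3):      {shape.shape}, tau_m = {shape.tau_m_list[0]*1e3:.2f} ms, "
      f"apparent D = {shape.D_estimates[0]:.1f} um^2/s")
```

Output:

```
pCF(0) fit:  D = 9.1 um^2/s,  N = 1.23
pCF(3):      bell, tau_m = 0.34 ms, apparent D = 16.7 um^2/s
```

The autocorrelation fit recovers the generating coefficient (9.1 vs 8.5
µm²/s, within the ~5% systematic + statistical scatter of a 50 000-line
record) and the occupancy (1.23 vs 1.2). The 150 nm pair correlation is
*bell-shaped* — the displacement is resolved by the 110 nm PSF — with a
transit maximum at 0.34 ms. The "apparent D" from d²/(4τ_m) exceeds the
true value by the known geometric factor 1/(1−(w/d)²) ≈ 2.2 at this
w/d; it is a position-comparable mobility index, not a corrected
coefficient (see `docs/methods.md`). With a 275 nm confocal PSF the same
curve is sigmoidal and carries no transit maximum.

The same workflow is scriptable from a shell:

```
sted-pcf simulate --config sim.json --out carpet.tif
sted-pcf pcf --carpet carpet.tif --distance 4 --direction both --out run1
sted-pcf ne-locate --carpet carpet.tif --bin 20
sted-pcf report --carpet carpet.tif --out report.json
```

## Layout

```
src/stedpcf/carpet_io.py   carpets: TIFF/CSV + JSON sidecar I/O, binning
src/stedpcf/simulate.py    Brownian-dynamics photon-count simulator
src/stedpcf/correlate.py   multi-tau / linear pCF estimators, detrend
src/stedpcf/models.py      analytic models, transit maxima, fits
src/stedpcf/pipeline.py    classification, pools, end-to-end reports
src/stedpcf/cli.py         `sted-pcf` command line
docs/methods.md            models, estimator choices, simulator design
```
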