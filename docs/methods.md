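# Methods

## The measurement and the model

A line-scan fluorescence fluctuation experiment repeatedly sweeps a
focused excitation/detection volume along a fixed line (here 64 pixels of
50 nm at 8 kHz, i.e. 0.125 ms per line) and records photon counts per
pixel dwell.  The record forms an *intensity carpet* `F(t, p)`: rows are
successive lines (time), columns are pixel positions (space).  The pair
correlation function between two columns separated by `n` pixels,

    pCF(τ; p, p+n) = ⟨F(t, p) F(t+τ, p+n)⟩ / (⟨F(t, p)⟩⟨F(t, p+n)⟩) − 1,

measures how long molecules take to travel between the two positions.
Its shape classifies the local transport: **sigmoidal** (maximum at the
shortest sampled lag) when the two pixels fall within one optical
resolution element; **bell-shaped** with a maximum at the modal transit
time τ_m when they are resolved; **zero** when a barrier blocks exchange.
Shrinking the point spread function (PSF) with stimulated emission
depletion (STED) therefore converts short pixel distances from the
sigmoidal to the bell regime and turns the carpet into a sub-diffraction
map of local mobility.

For free 3D diffusion through a Gaussian volume of radial 1/e² radius
w_xy and axial/radial ratio S, the autocorrelation (the n = 0 case) is

    G(τ) = (1/N) (1 + τ/τ_D)^(−1) (1 + τ/(S² τ_D))^(−1/2),   τ_D = w_xy²/(4D),

with N the mean occupancy of the effective volume V_eff = π^{3/2} w_xy² w_z.
The cross-correlation between two such volumes displaced radially by d
(the displaced-volume form of the FCS literature) is

    G_x(τ; d) = G(τ) · exp(−(d/w_xy)² / (1 + τ/τ_D)).

Setting a = (d/w_xy)² and u = τ/τ_D, dG_x/du = 0 reduces to

    3u² + (2S² + 4 − 2a) u + (2S² + 1 − 2aS²) = 0,

whose positive root gives τ_m in closed form (`tau_max_exact`); an
interior maximum exists iff a > 1 + 1/(2S²).  For large S the root
collapses to τ_m = (d² − w_xy²)/(4D) (`tau_max_2d`), and for w_xy ≪ d to
τ_m ≈ d²/(4D), inverted as the *local diffusion estimate*

    D = d² / (4 τ_m)        (`estimate_D_from_tau_max`).

The closed-form root is guarded by a grid-search maximization test over a
D × d × w_xy sweep.  Note that neglecting w_xy biases the estimate up by
exactly 1/(1 − (w_xy/d)²) — +43% at w_xy = 110 nm, d = 200 nm — so D from
this relation is an *apparent, local* coefficient, comparable across
positions measured with the same geometry (a property test pins the exact
factor).

## Correlator

`pcf_pair` implements the normalized-covariance estimator with symmetric
normalization by the two full-record column means, averaging lag products
over the overlapping T − k line pairs (no zero padding, no further bias
correction).  Lags are quantized to the line period.  Two lag schemes:

- **multi-tau** (default): 16 linear lags in the first octave, then 8
  per octave with the traces block-averaged by 2 per octave — the
  standard hardware-correlator layout.  Block averaging trades a small
  triangular smoothing of the curve (window ≤ 1/8 of the lag) for shot
  noise suppression at long lags.
- **linear**: every integer lag up to a cap, one exact dot product per
  lag; used for oracle comparisons against an independently coded
  O(T²) direct sum with exactly-rounded (`math.fsum`) accumulation.

Zero-mean columns raise an error rather than propagating NaN, so a dead
detector column fails loudly during carpet assembly.

`detrend` removes slow drifts (photobleaching, cell movement) by the
additive approach: each column is cut into segments (default 1000 lines =
0.125 s), and every line of a segment receives independent Poisson filler
counts of mean (m_max − m_segment), equalizing all segment means to the
column maximum.  Counts are only ever added — the filler is uncorrelated
and dilutes correlation amplitudes slightly but cannot create structure.
On a stationary carpet the method adds only the max-order-statistic of
the segment-mean noise (≈ σ_seg √(2 ln m), a ~2% intensity overhead at
typical settings).

## Simulator

`simulate_carpet` is a Brownian-dynamics photon-count generator and the
source of every test fixture.  Point particles diffuse in a 3D box;
each pixel dwell (dwell = line period / n_pixels) the beam sits at one
pixel and every live particle contributes Poisson-mean
`brightness · exp(−2(dx² + dy²)/w_xy² − 2dz²/w_z²)` — the 1/e²
convention, so the simulator's w_xy *is* the w_xy of the analytic models.
Design choices:

- **Per-dwell updates.** Particles advance by N(0, 2DΔt) per axis once
  per dwell, not per line, so intra-line motion is correlated correctly
  (at D = 20 µm²/s a particle moves ~70 nm per line period).
- **Box geometry.** Periodic in y and z; in x periodic for barrier-free
  runs and reflecting when a barrier is present.  Defaults: x margin
  3 w_xy beyond the scan line, y extent 10 w_xy, z extent 3.5 w_z.  The
  transverse extents were chosen against an exact mode-sum calculation
  of the finite-box correlation function: a periodic box supports only
  discrete diffusion modes, and too small a box distorts the correlation
  decay (a 6 w_xy y-box biases fitted D by ≈ +15%).  The defaults keep
  the predicted fit bias at ~2–4%, and the measured end-to-end accuracy
  of generator + correlator + fit is ~5% — an order of magnitude inside
  the ±15% recovery bands used in the acceptance tests.
- **Barrier.** A semi-permeable plane: attempted crossings succeed with
  probability `permeability`, otherwise reflect elastically.  An optional
  slow zone around the plane replaces D by `slow_zone_D` inside it.
  Because step sizes depend on position, the zone behaves as a *trap*:
  at steady state particles accumulate there by the mobility ratio
  (≈ D_free/D_zone), exactly as transient binding to transport machinery
  would enrich cargo near the envelope.  This enrichment is intended and
  produces the intensity contrast around the envelope in the synthetic
  scenes.
- **Bleaching** is per-particle (irreversible stochastic death at rate
  `bleach_rate`) inside the simulator; `apply_bleaching_trend` instead
  imposes a deterministic exponential mean decay on an existing carpet by
  binomial thinning (thinning Poisson(µ) counts with probability p gives
  exactly Poisson(pµ)), so the detrend filter can be tested against a
  bleach-free twin of the *same* realization.
- **Determinism.** One config seed drives particle initialization, the
  pre-generated Gaussian displacement streams, and the per-chunk count
  noise; the same config is bit-reproducible.

What the generator does *not* emulate: anomalous diffusion, explicit
binding kinetics (the slow pool is a mobility zone, not a reaction),
detector afterpulsing or dead time, scanner retrace time, and STED
depletion photophysics (STED enters only as a smaller effective PSF).
Passing tests therefore demonstrate correctness of the estimators and
fits under ideal Brownian statistics, not robustness to every artifact of
real acquisitions.

## Maxima detection and pools

`detect_maxima` works on one correlation curve: restrict to lags ≤ 20 ms
(transit maxima of interest sit at 0.1–10 ms; longer multi-tau lags are
sample-starved), smooth with a centered 5-bin moving average, estimate
the per-bin noise robustly from the high-frequency residual (median
absolute deviation per group of 8 bins — on a quasi-log grid the sample
count halves per octave, so noise grows with lag), and accept maxima
exceeding z = 3 times the local noise with at least that prominence.
Maxima lags are refined by a parabola in log-lag.  Classification
follows the taxonomy above; up to two interior maxima (fast and slow
pool) are reported.

`two_pool_summary` pools all interior maxima of bell-classified columns
and splits them by a deterministic 1D two-means on log τ_m.  Two pools
are declared only when the cluster centers differ ≥ 2-fold *and* each
cluster holds at least 3 maxima (10% of the total if larger) — a lone
stray maximum is noise, not a mobility component.  Pool D is evaluated
at the pooled mean transit time (per-column reciprocals 1/τ would bias
the pool upward by Jensen's inequality); its spread is propagated from
the τ_m spread.  When the envelope position is known, the farthest
slow-pool detection on each side is reported in nm; note it is recorded
at the *source* pixel of the pair, so it can overshoot a confinement
zone by up to the pair span plus ~1 PSF radius.

## Envelope localization

The nucleus/cytoplasm interface is localized by fitting each binned line
profile (default: average of 20 lines) to the sigmoid step
I(x) = A + B/(1 + exp(−(x − x0)/w)); the per-line distributions of x0 and
w are summarized by a maximum-likelihood Gaussian fit (mean ± sd).  The
reported width is the *logistic scale* w in pixels (the 25–75% rise
spans ≈ 2.2 w).  At least 50% of the binned lines must yield a converged
fit with x0 inside the line, otherwise an error names the fraction.  The
±4-pixel exclusion zone around round(x0) removes the region where
nuclear-pore interactions dominate before pool analysis.

## Numerical choices and degenerate inputs

Correlation-model fits use lmfit (Levenberg–Marquardt, relative
tolerance 1e-10, bounded positive parameters); deterministic initial
guesses come from the first-lag amplitude (N) and the half-decay lag
(τ_D → D or w_xy).  Fit windows default to lags ≤ 1 s.  Non-convergence
is a flagged result, not an exception, so carpet-wide batch fits
proceed.  Per-line sigmoid and Gaussian-spot fits use
scipy.optimize.curve_fit for speed (thousands of small fits).  Gaussian
FWHM is reported as 2√(2 ln 2)·σ; multi-peaked spot profiles are
rejected.  Degenerate inputs (all-zero curves, zero-mean columns,
empty emitter lists, loss fractions ≥ 1) raise ValueError with the
offending quantity named.

## Test problem sizes

Full-scale fixtures use the documented acquisition geometry — 2·10^5
lines × 64 pixels at 0.125 ms/line — for the parameter-recovery checks
(confocal: w_xy = 275 nm, S = 5, D = 8.5 µm²/s, N ≈ 1.5; STED:
w_xy = 110 nm, S = 10, D = 20 µm²/s, N ≈ 1.2).  The shape-taxonomy and
detrend checks use a 1.5·10^5-line STED carpet at D = 8.5 µm²/s, where a
3–4 pixel displacement sits well inside the bell regime.  The
nuclear-envelope scene (48 pixels, 10^5 lines) combines a semi-permeable
plane (permeability 0.05), a 600 nm trapping zone at D = 4.3 µm²/s, and
a free pool at D = 17 µm²/s with bright particles (8 counts/dwell at
focus), giving per-column maxima detection adequate SNR.  Oracle
comparisons run on 10^4-line carpets.  These sizes keep the whole suite
at roughly a quarter hour on one CPU while preserving the statistics the
assertions need.

## Known limitations

- The D = d²/(4τ_m) estimate carries the 1/(1 − (w/d)²) geometric bias
  discussed above; reported pool coefficients are apparent values.
- The multi-tau curve is triangularly smoothed at long lags; fits fix no
  baseline term, so records much shorter than ~10⁴ diffusion times will
  show finite-record bias.
- The simulator's periodic box leaves a ~2–4% systematic in recovered
  parameters (mode-sum analysis above); shrinking it further is a pure
  cost/accuracy trade.
- Equalize-to-maximum detrending adds uncorrelated counts and therefore
  slightly lowers correlation amplitudes (N is biased up marginally
  after detrending); transit times are unaffected within the tested 10%.
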