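"""Analytic correlation models and least-squares fits.

Notation follows standard fluorescence correlation spectroscopy.  For 3D
isotropic diffusion through a Gaussian observation volume of radial 1/e²
radius w_xy and axial/radial ratio S, the autocorrelation is

    G(τ) = (1/N) (1 + τ/τ_D)^(-1) (1 + τ/(S² τ_D))^(-1/2),
    τ_D = w_xy² / (4 D),

with N the mean particle number in the effective volume.  The
cross-correlation between two identical volumes displaced radially by d
(the Eigen/Rigler/Brinkmeier displaced-volume form) multiplies G by a
transit factor,

    G_x(τ; d) = G(τ) · exp( −(d/w_xy)² / (1 + τ/τ_D) ).

For d > w_xy the cross-correlation is bell-shaped: its maximum lag τ_m is
the modal transit time between the two points.  Setting a = (d/w_xy)² and
u = τ/τ_D, dG_x/du = 0 reduces to the quadratic

    3u² + (2S² + 4 − 2a) u + (2S² + 1 − 2aS²) = 0,

whose positive root gives τ_m exactly.  For large S (STED, or 2D
membrane diffusion) this collapses to τ_m = (d² − w_xy²)/(4D), and in
the super-resolution regime w_xy ≪ d further to τ_m ≈ d²/(4D) — which
inverts to the local diffusion-coefficient estimate D = d²/(4 τ_m) used
throughout the carpet analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import lmfit
from scipy import optimize, signal, stats

from stedpcf.carpet_io import LineScanCarpet, bin_lines

logger = logging.getLogger(__name__)

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusionModelParams:
    """Parameters of the 3D diffusion autocorrelation model.

    N dimensionless, D in µm²/s, w_xy in nm, S dimensionless.
    """

    N: float
    D: float
    w_xy: float
    S: float

    def __post_init__(self):
        for name in ("N", "D", "w_xy", "S"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def tau_D(self) -> float:
        """Radial diffusion time w_xy²/(4D) in seconds."""
        w_um = self.w_xy * 1e-3
        return w_um * w_um / (4.0 * self.D)


@dataclass(frozen=True)
class PairModelParams(DiffusionModelParams):
    """Diffusion parameters plus the radial displacement d (nm) between
    the two observation volumes; d = 0 reduces to the autocorrelation."""

    d: float = 0.0

    def __post_init__(self):
        super().__post_init__()
        if self.d < 0:
            raise ValueError("d must be >= 0")


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the sigmoid intensity step I(x) = A + B / (1 + exp(−(x − x0)/w)).

    ``x_width`` is the logistic scale parameter w in pixels (the 25–75%
    rise occupies ≈ 2.2 w).  ``stderr`` maps parameter names to 1σ
    uncertainties when available.
    """

    A: float
    B: float
    x0: float
    x_width: float
    stderr: Optional[dict] = None
    converged: bool = True


@dataclass(frozen=True)
class EnvelopeSummary:
    """Per-cell summary of the interface position and width distributions.

    Mean ± sd of the sigmoid midpoint x0 and width (both in pixels) over
    the per-line fits, from a Gaussian fit of their distributions.
    """

    x0_mean: float
    x0_sd: float
    width_mean: float
    width_sd: float
    n_lines_fit: int
    n_converged: int


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares model fit.

    ``params`` holds every model parameter (fixed ones unchanged),
    ``stderr`` 1σ uncertainties for the free parameters only, ``fixed``
    the fixed-parameter names.  Non-convergence is flagged, not raised,
    so carpet-wide batch fits can proceed.
    """

    params: dict
    stderr: dict
    fixed: tuple
    residual_norm: float
    converged: bool
    n_points: int = 0

    def __getitem__(self, key: str) -> float:
        return self.params[key]


# ---------------------------------------------------------------------------
# analytic models
# ---------------------------------------------------------------------------

def _g3d(tau, N, D, w_xy, S):
    w_um = w_xy * 1e-3
    tau_D = w_um * w_um / (4.0 * D)
    u = tau / tau_D
    return (1.0 / N) / (1.0 + u) / np.sqrt(1.0 + u / (S * S))


def _gpair(tau, N, D, w_xy, S, d):
    a = (d / w_xy) ** 2
    w_um = w_xy * 1e-3
    tau_D = w_um * w_um / (4.0 * D)
    u = tau / tau_D
    return _g3d(tau, N, D, w_xy, S) * np.exp(-a / (1.0 + u))


def acf_3d(tau, params: DiffusionModelParams):
    """3D isotropic-diffusion autocorrelation amplitude at lag ``tau`` (s).

    Monotonically decreasing in τ; G(0) = 1/N.
    """
    tau = np.asarray(tau, dtype=float)
    if (tau < 0).any():
        raise ValueError("tau must be >= 0")
    return _g3d(tau, params.N, params.D, params.w_xy, params.S)


def pair_ccf(tau, params: PairModelParams):
    """Displaced-volume cross-correlation amplitude at lag ``tau`` (s).

    Reduces exactly to :func:`acf_3d` at d = 0; for d sufficiently larger
    than w_xy the curve is bell-shaped with an interior maximum.
    """
    tau = np.asarray(tau, dtype=float)
    if (tau < 0).any():
        raise ValueError("tau must be >= 0")
    return _gpair(tau, params.N, params.D, params.w_xy, params.S, params.d)


def has_interior_maximum(params: PairModelParams) -> bool:
    """True when the cross-correlation peaks at τ > 0, i.e. when the two
    points are optically distinguishable: (d/w_xy)² > 1 + 1/(2S²)."""
    a = (params.d / params.w_xy) ** 2
    return a > 1.0 + 0.5 / (params.S * params.S)


def tau_max_exact(params: PairModelParams) -> float:
    """Exact lag of the cross-correlation maximum, in seconds.

    Positive root of the quadratic stationarity condition (module
    docstring).  Raises ValueError when no interior maximum exists
    (d = 0 or the displacement is not resolved by the PSF).
    """
    if params.d == 0:
        raise ValueError("d = 0: the autocorrelation has no interior maximum")
    if not has_interior_maximum(params):
        raise ValueError(
            f"d = {params.d} nm is within the optical resolution "
            f"(w_xy = {params.w_xy} nm, S = {params.S}): no interior maximum"
        )
    a = (params.d / params.w_xy) ** 2
    S2 = params.S * params.S
    A = 3.0
    B = 2.0 * S2 + 4.0 - 2.0 * a
    C = 2.0 * S2 + 1.0 - 2.0 * a * S2
    u = (-B + math.sqrt(B * B - 4.0 * A * C)) / (2.0 * A)
    return u * params.tau_D


def tau_max_2d(params: PairModelParams) -> float:
    """Large-S (quasi-2D) limit of the maximum lag: τ_m = (d² − w_xy²)/(4D)."""
    if params.d == 0:
        raise ValueError("d = 0: no interior maximum")
    if params.d <= params.w_xy:
        raise ValueError(
            f"d = {params.d} nm must exceed w_xy = {params.w_xy} nm for an "
            "interior maximum in the large-S limit"
        )
    d_um = params.d * 1e-3
    w_um = params.w_xy * 1e-3
    return (d_um * d_um - w_um * w_um) / (4.0 * params.D)


def estimate_D_from_tau_max(tau_m: float, d: float) -> float:
    """Local diffusion coefficient from the transit-time maximum.

    In the super-resolution regime w_xy ≪ d the maximum lag reduces to
    τ_m ≈ d²/(4D), inverted here as D = d²/(4 τ_m).  ``tau_m`` in
    seconds, ``d`` in nm, result in µm²/s.
    """
    if tau_m <= 0 or d <= 0:
        raise ValueError("tau_m and d must be strictly positive")
    d_um = d * 1e-3
    return d_um * d_um / (4.0 * tau_m)


# ---------------------------------------------------------------------------
# correlation-curve fitting
# ---------------------------------------------------------------------------

_MODEL_FUNCS = {"acf_3d": _g3d, "pair_ccf": _gpair}
_MODEL_PARAMS = {
    "acf_3d": ("N", "D", "w_xy", "S"),
    "pair_ccf": ("N", "D", "w_xy", "S", "d"),
}


def _initial_guesses(lags, values, fixed, model):
    """Deterministic starting values: N from the first-lag amplitude,
    τ_D (hence D or w_xy) from the half-decay lag."""
    guesses = {}
    g0 = max(values[0], 1e-6)
    guesses["N"] = 1.0 / g0
    below = np.nonzero(values <= 0.5 * g0)[0]
    tau_half = lags[below[0]] if below.size else lags[len(lags) // 2]
    if "D" not in fixed:
        w = fixed.get("w_xy", 275.0)
        guesses["D"] = max((w * 1e-3) ** 2 / (4.0 * tau_half), 1e-3)
    if "w_xy" not in fixed:
        D = fixed.get("D", 10.0)
        guesses["w_xy"] = max(math.sqrt(4.0 * D * tau_half) * 1e3, 10.0)
    guesses.setdefault("S", 5.0)
    guesses.setdefault("D", 10.0)
    guesses.setdefault("w_xy", 275.0)
    if model == "pair_ccf":
        guesses.setdefault("d", 200.0)
    return guesses


def fit_correlation(curve, model: str = "acf_3d",
                    free: Sequence[str] = ("D", "N"),
                    fixed: Optional[Mapping[str, float]] = None,
                    initial: Optional[Mapping[str, float]] = None,
                    weights: Optional[np.ndarray] = None,
                    max_lag_s: Optional[float] = None) -> FitResult:
    """Weighted least-squares fit of a correlation curve to an analytic model.

    The three standard usages are (i) w_xy, S fixed — fit D and N;
    (ii) D, S fixed — fit w_xy and N (optical-resolution determination);
    (iii) pair model with d and S fixed — fit w_xy (and N).

    ``max_lag_s`` restricts the fit window; unit weights by default.
    Non-convergence returns a flagged partial result rather than raising.
    """
    if model not in _MODEL_FUNCS:
        raise ValueError(f"unknown model {model!r}")
    names = _MODEL_PARAMS[model]
    fixed = dict(fixed or {})
    free = tuple(free)
    missing = set(names) - set(free) - set(fixed)
    if missing:
        raise ValueError(f"parameters neither free nor fixed: {sorted(missing)}")
    lags = np.asarray(curve.lags, dtype=float)
    values = np.asarray(curve.values, dtype=float)
    mask = np.ones(lags.size, dtype=bool)
    if max_lag_s is not None:
        mask &= lags <= max_lag_s
    lags, values = lags[mask], values[mask]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[mask]
    if lags.size < 2 * len(free):
        raise ValueError(
            f"curve has {lags.size} points; need at least {2 * len(free)} "
            f"for {len(free)} free parameters"
        )
    if np.allclose(values, 0.0):
        raise ValueError("degenerate curve: all correlation values are zero")

    guesses = _initial_guesses(lags, values, fixed, model)
    if initial:
        guesses.update(initial)
    params = lmfit.Parameters()
    for name in names:
        if name in fixed:
            params.add(name, value=float(fixed[name]), vary=False)
        else:
            params.add(name, value=float(guesses[name]), min=1e-12)

    func = _MODEL_FUNCS[model]

    def residual(p):
        r = func(lags, *(p[name].value for name in names)) - values
        return r * weights if weights is not None else r

    try:
        out = lmfit.minimize(residual, params, method="leastsq",
                             xtol=1e-10, ftol=1e-10, max_nfev=500 * len(free))
        converged = bool(out.success)
        result_params = out.params
        residual_norm = float(np.sqrt(np.sum(np.asarray(out.residual) ** 2)))
    except Exception as exc:  # keep batch fits alive
        logger.warning("fit did not converge: %s", exc)
        converged = False
        result_params = params
        residual_norm = float(np.sqrt(np.sum(residual(params) ** 2)))
    estimates = {name: float(result_params[name].value) for name in names}
    stderr = {
        name: float(result_params[name].stderr)
        for name in names
        if name not in fixed and result_params[name].stderr is not None
    }
    return FitResult(
        params=estimates, stderr=stderr, fixed=tuple(sorted(fixed)),
        residual_norm=residual_norm, converged=converged, n_points=lags.size,
    )


# ---------------------------------------------------------------------------
# interface localization and imaging resolution
# ---------------------------------------------------------------------------

def _sigmoid(x, A, B, x0, w):
    return A + B / (1.0 + np.exp(-(x - x0) / w))


def fit_sigmoid_profile(profile, x: Optional[np.ndarray] = None) -> SigmoidParams:
    """Fit an intensity-vs-pixel profile to the sigmoid step model.

    Returns sub-pixel estimates of the step midpoint x0 and logistic
    width.  A monotone-decreasing profile yields B < 0 with x0 still the
    midpoint (no mirroring is applied; the sign of B carries the step
    direction).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 6:
        raise ValueError(f"profile too short ({profile.size} < 6 points)")
    if x is None:
        x = np.arange(profile.size, dtype=float)
    grad = np.gradient(profile)
    x0_guess = float(x[np.argmax(np.abs(grad))])
    A_guess = float(profile[0])
    B_guess = float(profile[-1] - profile[0])
    if B_guess == 0.0:
        B_guess = float(np.ptp(profile)) or 1.0
    p0 = (A_guess, B_guess, x0_guess, 1.5)
    try:
        popt, pcov = optimize.curve_fit(
            _sigmoid, x, profile, p0=p0, maxfev=2000
        )
        perr = np.sqrt(np.diag(pcov))
        converged = np.isfinite(perr).all()
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise RuntimeError(f"sigmoid fit did not converge: {exc}") from exc
    A, B, x0, w = popt
    # logistic width is sign-symmetric; report it positive
    return SigmoidParams(
        A=float(A), B=float(B), x0=float(x0), x_width=float(abs(w)),
        stderr=dict(zip(("A", "B", "x0", "x_width"), map(float, perr))),
        converged=bool(converged),
    )


def locate_envelope(carpet: LineScanCarpet, bin_factor: int = 20
                    ) -> EnvelopeSummary:
    """Locate the nuclear-envelope interface from a carpet spanning it.

    Lines are binned by ``bin_factor`` (averaging suppresses shot noise),
    each binned line's intensity profile is fitted to the sigmoid step,
    and the resulting distributions of midpoint x0 and width are
    summarized by a Gaussian (maximum-likelihood mean ± sd).  Fits must
    converge with a midpoint inside the line on at least 50% of the
    binned lines.
    """
    binned = bin_lines(carpet, bin_factor)
    x = np.arange(carpet.n_pixels, dtype=float)
    x0s, widths = [], []
    n_total = binned.n_lines
    for i in range(n_total):
        try:
            fit = fit_sigmoid_profile(binned.counts[i], x)
        except RuntimeError:
            continue
        if fit.converged and 0.0 <= fit.x0 <= carpet.n_pixels and fit.x_width > 0:
            x0s.append(fit.x0)
            widths.append(fit.x_width)
    frac = len(x0s) / n_total
    if frac < 0.5:
        raise RuntimeError(
            f"interface fit converged on only {100 * frac:.0f}% of "
            f"{n_total} binned lines (need >= 50%)"
        )
    x0_mu, x0_sd = stats.norm.fit(x0s)
    w_mu, w_sd = stats.norm.fit(widths)
    return EnvelopeSummary(
        x0_mean=float(x0_mu), x0_sd=float(x0_sd),
        width_mean=float(w_mu), width_sd=float(w_sd),
        n_lines_fit=n_total, n_converged=len(x0s),
    )


def _gaussian_peak(x, offset, amp, mu, sigma):
    return offset + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def gaussian_fwhm(profile, positions: Optional[np.ndarray] = None) -> float:
    """Spatial resolution from a single-spot intensity profile.

    Fits a Gaussian with offset and returns its full width at half
    maximum, 2√(2 ln 2)·σ, in the units of ``positions`` (pixel index by
    default).  Multi-peaked profiles are rejected.
    """
    profile = np.asarray(profile, dtype=float)
    if positions is None:
        positions = np.arange(profile.size, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if profile.size < 5:
        raise ValueError("profile too short for a Gaussian fit")
    # reject multi-peaked input: significant local maxima after light smoothing
    smooth = np.convolve(profile, np.ones(3) / 3.0, mode="same")
    floor = smooth.min()
    peaks, _ = signal.find_peaks(smooth, height=floor + 0.3 * (smooth.max() - floor),
                                 prominence=0.2 * (smooth.max() - floor))
    if peaks.size > 1:
        raise ValueError(f"profile has {peaks.size} peaks; expected a single spot")
    i_max = int(np.argmax(profile))
    p0 = (
        float(profile.min()),
        float(profile.max() - profile.min()),
        float(positions[i_max]),
        float((positions[-1] - positions[0]) / 6.0),
    )
    popt, _ = optimize.curve_fit(_gaussian_peak, positions, profile, p0=p0,
                                 maxfev=2000)
    return float(FWHM_PER_SIGMA * abs(popt[3]))
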