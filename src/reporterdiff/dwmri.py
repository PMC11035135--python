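"""Apparent-diffusion-coefficient estimation from multi-b-value MRI series.

Water diffusivity is read out from the mono-exponential decay of the
diffusion-weighted signal, ``S(b) = S0 * exp(-b * D)``, with the
diffusion weighting ``b`` in ms/µm² and the apparent diffusion
coefficient (ADC) ``D`` in µm²/ms, so that ``b * D`` is dimensionless.
The module covers the full measurement chain of a reporter-gene
diffusion contrast experiment: ROI-mean signal decays, scalar ADC fits,
voxel-wise ADC maps with validity tracking, median-filtered 8-bit
pseudo-color rendering, and the reporter contrast statistic
``ΔD/D₀ = 100 * (D - D0) / D0`` comparing reporter-expressing cells to
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "DiffusionSeries",
    "SignalDecay",
    "ADCEstimate",
    "DiffusionMap",
    "RenderedMap",
    "effective_bvalue",
    "roi_mean_signal",
    "fit_adc",
    "fit_adc_map",
    "render_diffusion_map",
    "percent_delta_diffusivity",
    "aggregate_percent_delta",
    "rician_expected_magnitude",
    "correct_rician_floor",
    "um2_per_ms_to_mm2_per_s",
    "mm2_per_s_to_um2_per_ms",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DiffusionSeries:
    """Stack of magnitude images indexed by effective b-value.

    Parameters
    ----------
    stack
        Array of shape ``(*spatial, n_b)``; the trailing axis enumerates
        b-values. Spatial rank may be 2 or 3.
    bvalues
        Effective b-values in ms/µm², one per stack frame.
    voxel_mm
        Voxel edge lengths in mm (metadata only).
    meta
        Acquisition metadata (echo/repetition time, gradient timing,
        averages, FOV ...). Carried through unchanged.
    """

    stack: np.ndarray
    bvalues: np.ndarray
    voxel_mm: tuple[float, ...] = (0.4, 0.4)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.bvalues.ndim != 1 or self.bvalues.size < 2:
            raise ValueError("need at least 2 b-values")
        if np.unique(self.bvalues).size != self.bvalues.size:
            raise ValueError("b-values must be distinct")
        if self.stack.shape[-1] != self.bvalues.size:
            raise ValueError(
                f"stack has {self.stack.shape[-1]} frames but "
                f"{self.bvalues.size} b-values"
            )
        if not np.all(np.isfinite(self.stack)):
            raise ValueError("stack contains non-finite intensities")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.stack.shape[:-1]


@dataclass
class SignalDecay:
    """Paired (b-value, mean signal) vectors for one ROI."""

    bvalues: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.bvalues.shape != self.signals.shape or self.bvalues.size < 2:
            raise ValueError("decay needs >=2 matched (b, S) pairs")


@dataclass
class ADCEstimate:
    """Result of a mono-exponential ADC fit."""

    D: float                 # µm²/ms
    ln_intercept: float      # ln(a.u.)
    r_squared: float
    n_points: int
    stderr: float            # standard error of the slope magnitude

    @property
    def S0(self) -> float:
        return float(np.exp(self.ln_intercept))


@dataclass
class DiffusionMap:
    """Per-voxel apparent diffusivity with a validity mask."""

    D: np.ndarray            # µm²/ms, NaN where invalid
    valid: np.ndarray        # bool, True where the fit succeeded
    bvalues: np.ndarray
    roi_id: str = ""

    def __post_init__(self) -> None:
        if self.D.shape != self.valid.shape:
            raise ValueError("D and validity mask shapes differ")


@dataclass
class RenderedMap:
    """8-bit rendering of a diffusion map."""

    image: np.ndarray        # uint8
    lower: float             # µm²/ms mapped to 0
    upper: float             # µm²/ms mapped to 255
    kernel: int


# ---------------------------------------------------------------------------
# unit helpers
# ---------------------------------------------------------------------------

def um2_per_ms_to_mm2_per_s(d: float) -> float:
    """1 µm²/ms = 1e-3 mm²/s (exact)."""
    return d * 1e-3


def mm2_per_s_to_um2_per_ms(d: float) -> float:
    return d * 1e3


def effective_bvalue(gamma: float, G: float, delta: float, Delta: float) -> float:
    """Stejskal-Tanner diffusion weighting for a pulsed-gradient pair.

    ``b = γ² G² δ² (Δ - δ/3)``, the standard expression for rectangular
    gradient lobes of amplitude ``G`` and duration ``δ`` separated by
    ``Δ``; for a stimulated-echo sequence ``Δ`` is the diffusion time.

    Parameters
    ----------
    gamma
        Gyromagnetic ratio, rad s⁻¹ T⁻¹ (¹H: 2.675e8).
    G
        Gradient amplitude, T/m. ``G = 0`` gives ``b = 0``.
    delta, Delta
        Gradient duration and separation, ms.

    Returns
    -------
    float
        b in ms/µm² (1 ms/µm² = 1e9 s/m²).
    """
    if gamma <= 0 or delta <= 0 or Delta <= 0 or G < 0:
        raise ValueError("gamma, delta, Delta must be positive and G >= 0")
    if Delta <= delta / 3:
        raise ValueError("requires Delta > delta/3")
    delta_s = delta * 1e-3
    Delta_s = Delta * 1e-3
    b_si = gamma**2 * G**2 * delta_s**2 * (Delta_s - delta_s / 3)  # s/m²
    return b_si / 1e9


# ---------------------------------------------------------------------------
# Rician noise-floor correction
# ---------------------------------------------------------------------------
#
# Magnitude MRI data follow a Rician distribution: at low signal-to-noise
# the expected magnitude does not decay to zero but to the noise floor
# σ√(π/2), which flattens the tail of a diffusion decay and biases a
# log-linear ADC fit downward. When the per-channel noise level σ is
# known (from the acquisition, a background ROI, or the phantom spec),
# the bias can be removed by inverting the Rician mean function
#
#   E[M] = σ √(π/2) · L_{1/2}(−ν² / 2σ²),
#
# where ν is the underlying noiseless amplitude and L_{1/2} the
# generalized Laguerre polynomial of order 1/2. Averaged magnitudes
# (mean of repeated acquisitions) share the same expectation, so the
# same inversion applies to N-average images and to ROI means.

_INV_GRID_NU = np.linspace(0.0, 60.0, 60001)


def rician_expected_magnitude(nu: np.ndarray | float,
                              sigma: float) -> np.ndarray | float:
    """Expected magnitude E[M] of a Rician with amplitude ``nu``, noise
    ``sigma`` per channel."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(nu, dtype=float) / sigma
    x = -(r**2) / 2.0
    # L_{1/2}(x) via exponentially-scaled Bessels (stable for large ν/σ)
    lag = (1 - x) * special.ive(0, -x / 2) - x * special.ive(1, -x / 2)
    out = sigma * np.sqrt(np.pi / 2.0) * lag
    return float(out) if np.isscalar(nu) else out


_INV_GRID_M = np.asarray(rician_expected_magnitude(_INV_GRID_NU, 1.0))


def correct_rician_floor(magnitudes: np.ndarray,
                         sigma: float) -> np.ndarray:
    """Invert the Rician mean function: observed magnitude → amplitude.

    Magnitudes at or below the noise floor σ√(π/2) map to 0 (the
    amplitude is not identifiable there); callers treat those as
    unfittable points. Beyond the tabulated range the asymptotic
    inverse ``ν ≈ m − σ²/(2m)`` is used.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m = np.asarray(magnitudes, dtype=float)
    r = m / sigma
    nu = np.interp(r, _INV_GRID_M, _INV_GRID_NU, left=0.0)
    high = r > _INV_GRID_M[-1]
    if np.any(high):
        nu = np.where(high, r - 1.0 / (2.0 * np.maximum(r, 1e-12)), nu)
    return nu * sigma


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def roi_mean_signal(series: DiffusionSeries, mask: np.ndarray) -> SignalDecay:
    """Mean signal inside an ROI at each b-value.

    Parameters
    ----------
    series
        Diffusion series; mask must match its spatial shape.
    mask
        Boolean ROI over one image plane/volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} != series spatial shape "
            f"{series.spatial_shape}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    signals = series.stack[mask].mean(axis=0)
    return SignalDecay(series.bvalues.copy(), signals)


def _logspace_fit(b: np.ndarray, s: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of ln(S) on b. Returns (slope, intercept, r2, slope stderr)."""
    y = np.log(s)
    n = b.size
    bm, ym = b.mean(), y.mean()
    sxx = np.sum((b - bm) ** 2)
    sxy = np.sum((b - bm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * bm
    resid = y - (intercept + slope * b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if n > 2:
        stderr = float(np.sqrt(ss_res / (n - 2) / sxx))
    else:
        stderr = 0.0
    return float(slope), float(intercept), float(r2), stderr


def fit_adc(decay: SignalDecay, method: str = "log-linear",
            noise_sigma: float | None = None) -> ADCEstimate:
    """Fit the apparent diffusion coefficient to a signal decay.

    The default fits the slope of the logarithmic decay of signal versus
    effective b-value by ordinary least squares; ``D`` is the negated
    slope. ``method="nonlinear"`` instead fits ``S = S0 exp(-b D)`` by
    Levenberg-Marquardt least squares, seeded from the log-linear
    solution; the two agree on clean data.

    ``noise_sigma``, when given, applies the Rician noise-floor
    correction (:func:`correct_rician_floor`) to the signals before
    fitting; points at or below the noise floor become nonpositive and
    raise.

    Raises
    ------
    ValueError
        If any signal is nonpositive (naming the offending b-value) or
        fewer than two points are supplied.
    """
    b, s = decay.bvalues, decay.signals
    if noise_sigma is not None:
        s = correct_rician_floor(s, noise_sigma)
    bad = np.nonzero(s <= 0)[0]
    if bad.size:
        raise ValueError(
            f"nonpositive signal at b={b[bad[0]]:g} ms/µm²; "
            "cannot fit in log space"
        )
    slope, intercept, r2, stderr = _logspace_fit(b, s)
    if method == "log-linear":
        return ADCEstimate(-slope, intercept, r2, b.size, stderr)
    if method == "nonlinear":
        def model(bb, s0, d):
            return s0 * np.exp(-bb * d)

        p0 = (np.exp(intercept), max(-slope, 1e-6))
        popt, pcov = optimize.curve_fit(model, b, s, p0=p0, maxfev=10000)
        pred = model(b, *popt)
        ss_res = float(np.sum((s - pred) ** 2))
        ss_tot = float(np.sum((s - s.mean()) ** 2))
        r2_nl = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        d_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
        return ADCEstimate(float(popt[1]), float(np.log(popt[0])), r2_nl,
                           b.size, d_err)
    raise ValueError(f"unknown fit method {method!r}")


def fit_adc_map(series: DiffusionSeries, mask: np.ndarray,
                roi_id: str = "",
                noise_sigma: float | None = None) -> DiffusionMap:
    """Voxel-wise ADC map inside an ROI.

    Each masked voxel's decay is fitted independently in log space.
    Voxels with a nonpositive intensity at any b-value (including those
    falling below the noise floor when ``noise_sigma`` enables the
    Rician correction) are marked invalid in the validity mask rather
    than raising, so noisy maps stay robust.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValueError("mask/series shape mismatch")
    if not mask.any():
        raise ValueError("ROI mask is empty")

    b = series.bvalues
    voxels = series.stack[mask]                       # (n_vox, n_b)
    if noise_sigma is not None:
        voxels = correct_rician_floor(voxels, noise_sigma)
    fittable = np.all(voxels > 0, axis=1)

    # vectorized log-space OLS over all fittable voxels at once
    d_vals = np.full(voxels.shape[0], np.nan)
    if fittable.any():
        y = np.log(voxels[fittable])
        bm = b.mean()
        sxx = np.sum((b - bm) ** 2)
        slope = ((b - bm) @ (y - y.mean(axis=1, keepdims=True)).T) / sxx
        d_vals[fittable] = -slope

    D = np.full(series.spatial_shape, np.nan)
    valid = np.zeros(series.spatial_shape, dtype=bool)
    D[mask] = d_vals
    vm = np.zeros(voxels.shape[0], dtype=bool)
    vm[fittable] = True
    valid[mask] = vm
    return DiffusionMap(D, valid, b.copy(), roi_id=roi_id)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _masked_median_filter(values: np.ndarray, valid: np.ndarray,
                          kernel: int) -> np.ndarray:
    """Median over the k×k window, excluding invalid voxels.

    Invalid neighbours are simply dropped from each window; a voxel with
    no valid neighbours keeps NaN.
    """
    if kernel == 1:
        return values.copy()
    pad = kernel // 2
    padded = np.pad(values, pad, mode="reflect")
    padded_valid = np.pad(valid, pad, mode="reflect")
    out = np.full_like(values, np.nan)
    it = np.ndindex(values.shape)
    for idx in it:
        window = tuple(slice(i, i + kernel) for i in idx)
        vals = padded[window][padded_valid[window]]
        if vals.size:
            out[idx] = np.median(vals)
    return out


def render_diffusion_map(dmap: DiffusionMap, lower: float, upper: float,
                         kernel: int = 3) -> RenderedMap:
    """Median-filter a diffusion map and rescale to an 8-bit image.

    The map is smoothed with a median filter of odd ``kernel`` size
    (invalid voxels are excluded from each neighbourhood, reflect
    boundary handling) and linearly mapped so ``lower`` → 0 and
    ``upper`` → 255, clamping outside the window. Invalid voxels render
    as 0.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 1")
    if not lower < upper:
        raise ValueError("require lower < upper")
    smoothed = _masked_median_filter(dmap.D, dmap.valid, kernel)
    scaled = (smoothed - lower) / (upper - lower) * 255.0
    scaled = np.clip(scaled, 0, 255)
    scaled[~np.isfinite(scaled)] = 0
    return RenderedMap(np.round(scaled).astype(np.uint8), lower, upper, kernel)


# ---------------------------------------------------------------------------
# reporter contrast statistic
# ---------------------------------------------------------------------------

def percent_delta_diffusivity(D: float, D0: float) -> float:
    """Percent increase in diffusivity of reporter cells over controls.

    ``ΔD/D₀ = 100 (D - D0) / D0`` with ``D`` the reporter-expressing and
    ``D0`` the control diffusivity.
    """
    if D0 <= 0:
        raise ValueError("control diffusivity D0 must be positive")
    return 100.0 * (D - D0) / D0


def aggregate_percent_delta(D_reps: np.ndarray,
                            D0_reps: np.ndarray) -> tuple[float, float]:
    """Mean ± s.e.m. of ΔD/D₀ over paired biological replicates.

    s.e.m. uses the sample standard deviation (n−1 denominator).
    """
    D_reps = np.asarray(D_reps, dtype=float)
    D0_reps = np.asarray(D0_reps, dtype=float)
    if D_reps.size == 0 or D0_reps.size == 0 or D_reps.size != D0_reps.size:
        raise ValueError("need nonempty, equal-length replicate lists")
    pct = np.array([percent_delta_diffusivity(d, d0)
                    for d, d0 in zip(D_reps, D0_reps)])
    n = pct.size
    sem = float(pct.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(pct.mean()), sem
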