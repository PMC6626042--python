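"""FRAP quantification: normalization, recovery kinetics, diffusion estimate.

The pipeline mirrors standard confocal FRAP practice on bacterial cells:

1. *Relative recovery* — ratio of bleached-area to whole-cell intensity,
   which already cancels acquisition photobleaching.
2. *Double normalization* —

       I(t)    = I_FRAP(t)/I_FRAP(0) * I_total(0)/I_total(t)
       I_norm  = (I(t) - I(t0)) / (I(0) - I(t0))

   with 0 the pre-bleach frame and t0 the first post-bleach frame, so that
   I_norm(pre) = 1 and I_norm(t0) = 0 exactly.
3. *Recovery fit* — Y(t) = A * (1 - exp(ln(0.5)/t_half * t)), giving the
   mobile fraction A and recovery half-time t_half.
4. *Diffusion estimate* — pre-minus-post difference profiles are fitted with
   a Gaussian C * exp(-2 (s-mu)^2 / R^2); the bleach-depth decay
   C(t) = C0 * R0 * (R0^2 + 8 D t)^{-1/2} then yields D, with C0 and R0
   taken from the first post-bleach frame.

Gaussian convention (important): R is the 1/e^2 half-width, i.e. the model is
C * exp(-2 (s-mu)^2 / R^2) with R^2 = 4 sigma^2.  This is the only convention
under which the depth-decay law above is the exact solution of 1-D free
diffusion: convolving with the heat kernel gives sigma^2(t) = sigma0^2 + 2Dt,
hence R(t)^2 = R0^2 + 8Dt and C(t) = C0 R0 (R0^2 + 8Dt)^{-1/2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .profiles import IntensityProfile

__all__ = [
    "FrapSeries",
    "RecoveryFit",
    "DifferenceProfile",
    "GaussianFit",
    "DiffusionFit",
    "FitError",
    "relative_recovery",
    "double_normalize",
    "fit_recovery",
    "difference_profiles",
    "fit_gaussian",
    "estimate_D",
]

LN_HALF = np.log(0.5)


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or the input is degenerate."""


# --------------------------------------------------------------------------
# Series container
# --------------------------------------------------------------------------


@dataclass
class FrapSeries:
    """Bleached-ROI and whole-cell intensity time series.

    Exactly one time point is flagged pre-bleach; the following point is t0,
    immediately after photobleaching.
    """

    t: np.ndarray
    i_frap: np.ndarray
    i_total: np.ndarray
    prebleach: np.ndarray
    roi: tuple[float, float] | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.i_frap = np.asarray(self.i_frap, dtype=float)
        self.i_total = np.asarray(self.i_total, dtype=float)
        self.prebleach = np.asarray(self.prebleach, dtype=bool)
        n = len(self.t)
        if not (len(self.i_frap) == len(self.i_total) == len(self.prebleach) == n):
            raise ValueError("all series must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if int(self.prebleach.sum()) != 1:
            raise ValueError("exactly one pre-bleach time point must be flagged")
        if np.any(self.i_frap < 0) or np.any(self.i_total < self.i_frap):
            raise ValueError("need I_total(t) >= I_FRAP(t) >= 0 at every time point")
        if self.pre_index + 1 >= n:
            raise ValueError("no post-bleach points after the pre-bleach frame")

    @property
    def pre_index(self) -> int:
        return int(np.flatnonzero(self.prebleach)[0])

    @property
    def t0_index(self) -> int:
        return self.pre_index + 1

    @property
    def post_slice(self) -> slice:
        return slice(self.t0_index, None)


# --------------------------------------------------------------------------
# Normalizations
# --------------------------------------------------------------------------


def relative_recovery(series: FrapSeries) -> np.ndarray:
    """I_FRAP(t) / I_total(t) at every time point (pre-bleach included)."""
    if np.any(series.i_total == 0):
        bad = int(np.flatnonzero(series.i_total == 0)[0])
        raise ValueError(f"I_total is zero at time point {bad} (t={series.t[bad]} s)")
    return series.i_frap / series.i_total


def double_normalize(series: FrapSeries) -> np.ndarray:
    """Double-normalized recovery I_norm(t) for every time point.

    I(t) corrects the bleached-area signal by the whole-cell signal (common
    per-frame factors cancel), then I_norm rescales so the pre-bleach value is
    1 and the first post-bleach value is 0 — both exact by construction.
    """
    p, q = series.pre_index, series.t0_index
    if series.i_frap[p] == 0:
        raise ValueError("pre-bleach I_FRAP is zero")
    if np.any(series.i_total == 0):
        raise ValueError("I_total contains zeros")
    i_t = (series.i_frap / series.i_frap[p]) * (series.i_total[p] / series.i_total)
    if i_t[p] == i_t[q]:
        raise ValueError("no detectable bleach: I(0) equals I(t0)")
    return (i_t - i_t[q]) / (i_t[p] - i_t[q])


# --------------------------------------------------------------------------
# Recovery kinetics (mobile fraction, half-time)
# --------------------------------------------------------------------------


@dataclass
class RecoveryFit:
    """Exponential recovery fit: mobile fraction A and half-time t_half."""

    a: float
    t_half: float
    residual_norm: float
    fitted: np.ndarray
    converged: bool = True

    def __post_init__(self):
        if self.a > 1.05 + 1e-12:
            # soft cap: values above ~1 flag a normalization problem
            warnings.warn(f"mobile fraction A={self.a:.3f} exceeds 1.05 — "
                          "check normalization", stacklevel=2)

    def predict(self, t) -> np.ndarray:
        return recovery_model(np.asarray(t, float), self.a, self.t_half)


def recovery_model(t: np.ndarray, a: float, t_half: float) -> np.ndarray:
    """Y(t) = A * (1 - exp(ln(0.5)/t_half * t)); Y(t_half) = A/2."""
    return a * (1.0 - np.exp(LN_HALF / t_half * t))


def fit_recovery(i_norm: np.ndarray, times: np.ndarray) -> RecoveryFit:
    """Least-squares fit of the recovery model to post-bleach I_norm values.

    ``times`` are measured from the first post-bleach frame (shifted
    internally so times[0] -> 0).  Initialization is parameter-free: A0 is the
    last observed value, t_half0 the linearly interpolated first crossing of
    A0/2.
    """
    y = np.asarray(i_norm, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) != len(t):
        raise ValueError("i_norm and times must have equal length")
    if len(y) < 4:
        raise ValueError("need >= 4 post-bleach points to fit recovery")
    t = t - t[0]

    a0 = float(np.clip(y[-1], 1e-3, 1.05))
    above = np.flatnonzero(y >= a0 / 2)
    if len(above) and above[0] > 0:
        i = above[0]
        f = (a0 / 2 - y[i - 1]) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0.5
        th0 = t[i - 1] + f * (t[i] - t[i - 1])
    else:
        th0 = t[-1] / 4
    th0 = float(max(th0, t[1] / 10 if len(t) > 1 else 1e-3, 1e-6))

    try:
        popt, _ = curve_fit(recovery_model, t, y, p0=[a0, th0],
                            bounds=([0.0, 1e-9], [1.05, np.inf]), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"recovery fit did not converge (A0={a0:.3g}, t_half0={th0:.3g}, "
                       f"n={len(y)}, y_range=[{y.min():.3g}, {y.max():.3g}]): {exc}") from exc
    fitted = recovery_model(t, *popt)
    return RecoveryFit(a=float(popt[0]), t_half=float(popt[1]),
                       residual_norm=float(np.linalg.norm(y - fitted)), fitted=fitted)


# --------------------------------------------------------------------------
# Difference profiles and Gaussian bleach-depth fits
# --------------------------------------------------------------------------


@dataclass
class DifferenceProfile:
    """Pre-bleach minus post-bleach profile at one post-bleach time."""

    s: np.ndarray
    delta: np.ndarray
    t: float

    def __post_init__(self):
        self.s = np.asarray(self.s, float)
        self.delta = np.asarray(self.delta, float)
        if self.s.shape != self.delta.shape:
            raise ValueError("position and difference vectors must match")
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("difference profile contains non-finite values")


def difference_profiles(prebleach: IntensityProfile,
                        postbleach: Sequence[IntensityProfile],
                        times: Sequence[float],
                        resample_tol: float = 1e-6) -> list[DifferenceProfile]:
    """Pre-minus-post difference profile for each post-bleach frame.

    Profiles should be normalized the same way as kymograph columns (each
    divided by its own mean).  Post-bleach profiles on a different grid are
    linearly resampled onto the pre-bleach grid if their spans agree within
    ``resample_tol``; otherwise this is a grid-mismatch error.
    """
    if len(postbleach) != len(times):
        raise ValueError("one time per post-bleach profile required")
    out = []
    s0 = prebleach.s
    for prof, t in zip(postbleach, times):
        if prof.s.shape == s0.shape and np.allclose(prof.s, s0, atol=resample_tol):
            post = prof.intensity
        else:
            if (abs(prof.s[0] - s0[0]) > prof.step + resample_tol
                    or abs(prof.s[-1] - s0[-1]) > prof.step + resample_tol):
                raise ValueError("profile grids mismatch beyond resampling tolerance")
            post = np.interp(s0, prof.s, prof.intensity)
        out.append(DifferenceProfile(s0.copy(), prebleach.intensity - post, float(t)))
    return out


@dataclass
class GaussianFit:
    """Gaussian fit of a difference profile: depth C, 1/e^2 half-width R, center mu."""

    c: float
    r: float
    mu: float
    residual_norm: float
    baseline: float = 0.0


def gaussian_model(s: np.ndarray, c: float, mu: float, r: float) -> np.ndarray:
    """C * exp(-2 (s-mu)^2 / R^2): R is the 1/e^2 half-width (R^2 = 4 sigma^2)."""
    return c * np.exp(-2.0 * ((s - mu) ** 2) / r**2)


def fit_gaussian(dp: DifferenceProfile, baseline: bool = False) -> GaussianFit:
    """Fit C * exp(-2 (s-mu)^2/R^2) [+ b] to a difference profile.

    Initialized from a peak/half-max scan.  With ``baseline`` an additive
    constant b is fitted as well (useful when per-frame mean normalization
    leaves a uniform offset under the peak).  Degenerate profiles (no positive
    peak) and non-convergent or non-positive-depth fits raise :class:`FitError`
    so that callers can flag and exclude the frame.
    """
    y0 = dp.delta
    s = dp.s
    b0 = float(np.median(y0)) if baseline else 0.0
    y = y0 - b0  # peak scan relative to the rough baseline
    c0 = float(y.max(initial=-np.inf))
    if not c0 > 0:
        raise FitError("difference profile has no positive peak")
    i_peak = int(np.argmax(y))
    mu0 = float(s[i_peak])
    # half-width scan: half-max crossing sits at |s-mu| = R*sqrt(ln(2)/2)
    half = c0 / 2
    r0 = None
    for direction in (1, -1):
        i = i_peak
        while 0 <= i + direction < len(y) and y[i + direction] > half:
            i += direction
        if 0 <= i + direction < len(y):
            r0 = abs(s[i + direction] - mu0) / np.sqrt(np.log(2) / 2)
            break
    if not r0 or r0 <= 0:
        r0 = max((s[-1] - s[0]) / 4, 1e-3)
    span = s[-1] - s[0]
    try:
        if baseline:
            fun = lambda x, c, mu, r, b: gaussian_model(x, c, mu, r) + b
            popt, _ = curve_fit(fun, s, y0, p0=[c0, mu0, r0, b0],
                                bounds=([0.0, s[0] - span, 1e-6, -np.inf],
                                        [np.inf, s[-1] + span, np.inf, np.inf]),
                                maxfev=10000)
            c, mu, r = popt[:3]
            b = popt[3]
        else:
            popt, _ = curve_fit(gaussian_model, s, y0, p0=[c0, mu0, r0],
                                bounds=([0.0, s[0] - span, 1e-6],
                                        [np.inf, s[-1] + span, np.inf]),
                                maxfev=10000)
            c, mu, r = popt
            b = 0.0
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit did not converge (C0={c0:.3g}, R0={r0:.3g}): {exc}") from exc
    if c <= 0:
        raise FitError("Gaussian fit returned non-positive depth")
    fitted = gaussian_model(s, c, mu, r) + b
    return GaussianFit(c=float(c), r=float(abs(r)), mu=float(mu),
                       residual_norm=float(np.linalg.norm(y0 - fitted)),
                       baseline=float(b))


# --------------------------------------------------------------------------
# Diffusion coefficient from bleach-depth decay
# --------------------------------------------------------------------------


@dataclass
class DiffusionFit:
    """Diffusion estimate from the bleach-depth decay C(t)."""

    d: float
    c0: float
    r0: float
    c_inf: float               # immobile-pool floor (0 for the pure model)
    residual_norm: float
    d_ci: tuple[float, float] | None = None   # residual-bootstrap 95% CI
    n_frames: int = 0


def depth_decay_model(t: np.ndarray, d: float, c0: float, r0: float,
                      c_inf: float = 0.0) -> np.ndarray:
    """C(t) = C_inf + (C0 - C_inf) * R0 * (R0^2 + 8 D t)^{-1/2}."""
    return c_inf + (c0 - c_inf) * r0 / np.sqrt(r0**2 + 8.0 * d * t)


def estimate_D(cs: np.ndarray, ts: np.ndarray, c0: float, r0: float,
               immobile_floor: bool = False, n_boot: int = 200,
               seed: int = 0) -> DiffusionFit:
    """Least-squares diffusion coefficient from the bleach-depth series.

    ``cs`` are fitted Gaussian depths at times ``ts`` measured from the first
    post-bleach frame; ``c0`` and ``r0`` come from that first frame.  The
    default model is the free-diffusion decay C = C0*R0*(R0^2+8Dt)^{-1/2};
    with ``immobile_floor`` an additional constant C_inf absorbs the
    non-recovering (immobile) part of the bleach for samples with an immobile
    pool.  A residual bootstrap provides a 95% CI on D.
    """
    cs = np.asarray(cs, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if len(cs) != len(ts):
        raise ValueError("cs and ts must have equal length")
    if len(cs) < 3:
        raise ValueError("need >= 3 frames with valid (C, t)")
    if c0 <= 0 or r0 <= 0:
        raise ValueError("C0 and R0 must be positive")
    slope = np.polyfit(ts, cs, 1)[0]
    if slope > 0 and cs[-1] > cs[0]:
        raise ValueError("no measurable spreading: C(t) increases over the series")

    def fit_once(y):
        if immobile_floor:
            fun = lambda t, d, ci: depth_decay_model(t, d, c0, r0, ci)
            popt, _ = curve_fit(fun, ts, y, p0=[1e-3, max(y[-1], 0.0)],
                                bounds=([0.0, 0.0], [np.inf, c0]), maxfev=10000)
            return popt[0], popt[1]
        fun = lambda t, d: depth_decay_model(t, d, c0, r0, 0.0)
        popt, _ = curve_fit(fun, ts, y, p0=[1e-3], bounds=(0.0, np.inf), maxfev=10000)
        return popt[0], 0.0

    try:
        d_hat, c_inf = fit_once(cs)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"diffusion fit did not converge: {exc}") from exc
    fitted = depth_decay_model(ts, d_hat, c0, r0, c_inf)
    resid = cs - fitted

    d_ci = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            y = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                boots.append(fit_once(y)[0])
            except (RuntimeError, ValueError):
                continue
        if len(boots) >= max(20, n_boot // 4):
            d_ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return DiffusionFit(d=float(d_hat), c0=float(c0), r0=float(r0),
                        c_inf=float(c_inf),
                        residual_norm=float(np.linalg.norm(resid)),
                        d_ci=d_ci, n_frames=len(cs))
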