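"""Hours-timescale interconversion kinetics from real-time NMR.

After a temperature jump the Ground/fold-switched (FS) populations relax
to their new equilibrium with observed rate k_obs = k_f + k_r, monitored
as peak intensities in consecutive 2D spectra.  Each peak reports the
population of its assigned state scaled by an unknown amplitude, so the
two rate constants are obtained from a global fit that shares
(k_f, k_r, p0) across all peaks while profiling out per-peak amplitudes.

Uncertainty follows a double bootstrap: every intensity is resampled from
its spectrum-noise uncertainty and the peak set is resampled with
replacement within each state class, then the global fit is repeated.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize
from lmfit import Parameters, minimize as lmfit_minimize

__all__ = [
    "TimeCourse",
    "SingleExpFit",
    "RateFitResult",
    "BootstrapResult",
    "filter_peaks",
    "fit_single_exponential",
    "fit_global_rates",
    "bootstrap_rates",
    "lifetime",
    "equilibrium_fraction",
]

logger = logging.getLogger(__name__)

AMPLITUDE_THRESHOLD = 4e5  # default minimum fitted peak amplitude


@dataclass
class TimeCourse:
    """Per-peak intensity vs time (hours) after a temperature jump."""

    peak_id: str
    state: str  # "Ground" | "FS"
    times_hr: np.ndarray
    intensities: np.ndarray
    sigma: float
    amplitude: float | None = None  # filled by single-exponential prefit

    def __post_init__(self):
        self.times_hr = np.asarray(self.times_hr, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_hr.size != self.intensities.size:
            raise ValueError("times and intensities differ in length")
        if np.any(np.diff(self.times_hr) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class SingleExpFit:
    """I(t) = a * exp(-k t) + c fit of one peak."""

    peak_id: str
    rate: float
    amplitude_coeff: float  # a
    offset: float  # c
    amplitude: float  # max |fitted curve| over the observed window
    covariance: np.ndarray | None
    success: bool
    message: str = ""


def fit_single_exponential(tc: TimeCourse) -> SingleExpFit:
    """Weighted least-squares fit of a single exponential to one peak.

    The reported ``amplitude`` (used for the intensity filter) is the
    maximum absolute value of the fitted curve over the observed times.
    """
    if tc.times_hr.size < 4:
        raise ValueError(
            f"peak {tc.peak_id!r}: need >= 4 points, got {tc.times_hr.size}"
        )
    t, y = tc.times_hr, tc.intensities
    span = max(t[-1] - t[0], 1e-9)
    c0 = y[-1]
    a0 = y[0] - y[-1]
    k0 = 1.0 / span

    params = Parameters()
    params.add("a", value=a0 if a0 != 0 else np.ptp(y) + 1e-9)
    params.add("c", value=c0)
    params.add("k", value=k0, min=1e-9, max=1e4)

    def residual(p):
        return (p["a"] * np.exp(-p["k"] * t) + p["c"] - y) / tc.sigma

    try:
        out = lmfit_minimize(residual, params, method="leastsq")
        a = float(out.params["a"])
        c = float(out.params["c"])
        k = float(out.params["k"])
        curve = a * np.exp(-k * t) + c
        return SingleExpFit(
            peak_id=tc.peak_id,
            rate=k,
            amplitude_coeff=a,
            offset=c,
            amplitude=float(np.max(np.abs(curve))),
            covariance=getattr(out, "covar", None),
            success=bool(out.success),
            message=str(out.message),
        )
    except Exception as err:
        logger.warning("single-exponential fit failed for %s: %s", tc.peak_id, err)
        return SingleExpFit(
            peak_id=tc.peak_id,
            rate=float("nan"),
            amplitude_coeff=float("nan"),
            offset=float("nan"),
            amplitude=float("nan"),
            covariance=None,
            success=False,
            message=str(err),
        )


def filter_peaks(
    timecourses: Sequence[TimeCourse],
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> list[TimeCourse]:
    """Keep peaks whose prefit amplitude exceeds the threshold.

    Amplitudes missing from the TimeCourse records are computed by
    single-exponential prefits.  An empty result is legal but logged.
    """
    kept = []
    for tc in timecourses:
        amp = tc.amplitude
        if amp is None:
            fit = fit_single_exponential(tc)
            amp = fit.amplitude if fit.success else float("nan")
            tc.amplitude = amp
        if np.isfinite(amp) and amp > amplitude_threshold:
            kept.append(tc)
    logger.info(
        "amplitude filter (> %.3g): kept %d of %d peaks",
        amplitude_threshold,
        len(kept),
        len(timecourses),
    )
    if not kept:
        warnings.warn("amplitude filter removed every peak")
    return kept


@dataclass
class RateFitResult:
    """Global two-state rate fit."""

    k_forward: float  # Ground -> FS, hr^-1
    k_reverse: float  # FS -> Ground, hr^-1
    p0: float  # Ground fraction at t = 0 (pre-jump equilibrium)
    scales: dict[str, float]
    redchi2: float
    n_ground: int
    n_fs: int
    n_points: int
    bootstrap: "BootstrapResult | None" = None

    @property
    def k_obs(self) -> float:
        return self.k_forward + self.k_reverse

    @property
    def equilibrium_ground(self) -> float:
        return self.k_reverse / (self.k_forward + self.k_reverse)


def _ground_fraction(t, k_f, k_r, p0):
    p_eq = k_r / (k_f + k_r)
    return p_eq + (p0 - p_eq) * np.exp(-(k_f + k_r) * t)


def _global_residuals(theta, timecourses, return_scales=False):
    k_f, k_r, p0 = theta
    res = []
    scales = {}
    for tc in timecourses:
        p = _ground_fraction(tc.times_hr, k_f, k_r, p0)
        if tc.state != "Ground":
            p = 1.0 - p
        denom = float(p @ p)
        a = float(p @ tc.intensities) / denom if denom > 0 else 0.0
        scales[tc.peak_id] = a
        res.append((tc.intensities - a * p) / tc.sigma)
    r = np.concatenate(res)
    if return_scales:
        return r, scales
    return r


def fit_global_rates(
    timecourses: Sequence[TimeCourse],
    n_starts: int = 3,
) -> RateFitResult:
    """Global weighted fit of (k_f, k_r, p0) with per-peak amplitudes.

    The shared parameters enter through the two-state relaxation
    p_G(t) = p_eq + (p0 - p_eq) exp(-(k_f + k_r) t) with
    p_eq = k_r / (k_f + k_r); per-peak scale factors are profiled out
    exactly by linear least squares at every iteration, which makes the
    nonlinear problem three-dimensional regardless of the peak count.
    Bounded multi-start least squares; lowest chi^2 wins.
    """
    tcs = list(timecourses)
    states = {tc.state for tc in tcs}
    if "Ground" not in states or "FS" not in states:
        raise ValueError(
            f"need at least one Ground and one FS peak, got states {sorted(states)}"
        )
    n_points = sum(tc.times_hr.size for tc in tcs)
    n_params = 3 + len(tcs)
    if n_points <= n_params:
        raise ValueError(
            f"{n_points} data points cannot constrain {n_params} parameters"
        )

    # initial k_obs guesses from single-exponential prefits
    prefit_rates = []
    for tc in tcs:
        f = fit_single_exponential(tc)
        if f.success and np.isfinite(f.rate):
            prefit_rates.append(f.rate)
    k_obs0 = float(np.median(prefit_rates)) if prefit_rates else 1.0

    lo = np.array([1e-9, 1e-9, 0.0])
    hi = np.array([1e4, 1e4, 1.0])
    starts = []
    for p_eq0, p00 in [(0.7, 0.5), (0.5, 0.3), (0.3, 0.7)][: max(1, n_starts)]:
        starts.append(
            np.array([k_obs0 * (1 - p_eq0), k_obs0 * p_eq0, p00])
        )

    best = None
    for x0 in starts:
        sol = scipy.optimize.least_squares(
            _global_residuals, np.clip(x0, lo, hi), bounds=(lo, hi), args=(tcs,)
        )
        if best is None or sol.cost < best.cost:
            best = sol
    k_f, k_r, p0 = best.x
    r, scales = _global_residuals(best.x, tcs, return_scales=True)
    redchi = float(np.sum(r**2) / (n_points - n_params))
    return RateFitResult(
        k_forward=float(k_f),
        k_reverse=float(k_r),
        p0=float(p0),
        scales=scales,
        redchi2=redchi,
        n_ground=sum(tc.state == "Ground" for tc in tcs),
        n_fs=sum(tc.state != "Ground" for tc in tcs),
        n_points=n_points,
    )


@dataclass
class BootstrapResult:
    """Empirical bootstrap distributions of the two rate constants."""

    k_forward_samples: np.ndarray
    k_reverse_samples: np.ndarray
    se_k_forward: float
    se_k_reverse: float
    n_requested: int
    n_failed: int


def bootstrap_rates(
    timecourses: Sequence[TimeCourse],
    n_iterations: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """Double bootstrap of the global rate fit.

    Each iteration resamples peaks with replacement within each state class
    and perturbs every intensity by Gaussian noise of its sigma, then
    refits from the point estimate.  Iterations whose fit fails are
    dropped and counted; more than 20% failures triggers a warning.
    """
    tcs = list(timecourses)
    point = fit_global_rates(tcs, n_starts=1)
    rng = np.random.default_rng(seed)
    ground = [tc for tc in tcs if tc.state == "Ground"]
    fs = [tc for tc in tcs if tc.state != "Ground"]
    x0 = np.array([point.k_forward, point.k_reverse, point.p0])
    lo = np.array([1e-9, 1e-9, 0.0])
    hi = np.array([1e4, 1e4, 1.0])

    kfs, krs = [], []
    n_failed = 0
    for _ in range(n_iterations):
        sample = [ground[i] for i in rng.integers(len(ground), size=len(ground))]
        sample += [fs[i] for i in rng.integers(len(fs), size=len(fs))]
        perturbed = [
            TimeCourse(
                peak_id=f"{tc.peak_id}#{j}",
                state=tc.state,
                times_hr=tc.times_hr,
                intensities=tc.intensities
                + rng.normal(size=tc.intensities.size) * tc.sigma,
                sigma=tc.sigma,
                amplitude=tc.amplitude,
            )
            for j, tc in enumerate(sample)
        ]
        try:
            sol = scipy.optimize.least_squares(
                _global_residuals,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                args=(perturbed,),
            )
            if not np.all(np.isfinite(sol.x)):
                raise RuntimeError("non-finite bootstrap solution")
            kfs.append(sol.x[0])
            krs.append(sol.x[1])
        except Exception:
            n_failed += 1
    if n_iterations and n_failed > 0.2 * n_iterations:
        warnings.warn(
            f"{n_failed}/{n_iterations} bootstrap iterations failed"
        )
    kfs = np.asarray(kfs)
    krs = np.asarray(krs)
    return BootstrapResult(
        k_forward_samples=kfs,
        k_reverse_samples=krs,
        se_k_forward=float(np.std(kfs, ddof=1)) if kfs.size > 1 else 0.0,
        se_k_reverse=float(np.std(krs, ddof=1)) if krs.size > 1 else 0.0,
        n_requested=n_iterations,
        n_failed=n_failed,
    )


def lifetime(rate: float) -> float:
    """Mean lifetime 1/k (hours for an hr^-1 rate)."""
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    return 1.0 / rate


def equilibrium_fraction(k_forward: float, k_reverse: float) -> float:
    """Equilibrium fraction of the departing state: k_r / (k_f + k_r)."""
    if k_forward <= 0 or k_reverse <= 0:
        raise ValueError("both rates must be > 0")
    return k_reverse / (k_forward + k_reverse)
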