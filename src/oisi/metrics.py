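"""Evoked-response metrics and nonparametric statistics.

Metric conventions:

* amplitude — the 95th percentile (linear interpolation between order
  statistics) of the signal over the analysis window, reported in percent;
* peak position — the first time sample at or after stimulus onset where the
  signal reaches its amplitude, in seconds from onset (one-frame
  granularity);
* half-recovery T0.5 — the first post-peak time at which the signal falls to
  half its amplitude, linearly interpolated between bracketing samples, in
  seconds from the peak; ``None`` when the trace never recovers to half;
* average LFP — the rectified integral of the LFP over the stimulation
  window divided by the window duration (uV); the convention is recorded in
  output metadata since "cumulative averaged LFP" admits several readings.

Statistics are the one-tailed Mann-Whitney U test (exact by enumeration of
all C(m+n, n) group assignments for small samples, tie-corrected normal
approximation otherwise) and the one-tailed sign test (exact binomial tail).
Directions are always explicit arguments, never inferred from the data.
"""

from __future__ import annotations

from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .core import LFPTrace, TimeCourse

__all__ = [
    "peak_amplitude",
    "peak_position",
    "half_recovery",
    "average_lfp",
    "rank_stimulation_rates",
    "pearson_correlation",
    "mann_whitney_u_one_tailed",
    "sign_test_one_tailed",
    "smooth_timecourse",
    "refined_peak_time",
    "fit_gamma_kernel",
    "GammaKernelFit",
    "EXACT_MWU_MAX_N",
]

#: largest pooled sample size for which the MWU p-value is computed by
#: exact enumeration of all group assignments
EXACT_MWU_MAX_N = 12


def _window_values(tc: TimeCourse, window: tuple[float, float] | None) -> np.ndarray:
    start, end = window if window is not None else (tc.stim_onset_s, tc.t[-1])
    sel = (tc.t >= start - 1e-12) & (tc.t <= end + 1e-12)
    vals = tc.y[sel]
    if vals.size == 0:
        raise ValueError(f"window [{start}, {end}] s selects no samples")
    return vals


def peak_amplitude(
    tc: TimeCourse,
    window: tuple[float, float] | None = None,
    as_percent: bool = True,
) -> float:
    """95th-percentile amplitude of the trace over the window.

    The default window runs from stimulus onset to the end of the trace.
    With ``as_percent`` the fractional signal is scaled by 100.
    """
    vals = _window_values(tc, window)
    amp = float(np.percentile(vals, 95.0, method="linear"))
    return amp * 100.0 if as_percent else amp


def peak_position(tc: TimeCourse, amplitude: float, amplitude_is_percent: bool = True) -> float:
    """Seconds from stimulus onset to the first sample reaching ``amplitude``."""
    thr = amplitude / 100.0 if amplitude_is_percent else amplitude
    sel = tc.t >= tc.stim_onset_s - 1e-12
    t, y = tc.t[sel], tc.y[sel]
    hits = np.flatnonzero(y >= thr - 1e-15)
    if hits.size == 0:
        raise AssertionError(
            "no sample reaches the amplitude; peak_amplitude and peak_position "
            "must be evaluated on the same window"
        )
    return float(t[hits[0]] - tc.stim_onset_s)


def half_recovery(
    tc: TimeCourse,
    amplitude: float,
    peak_time_s: float,
    amplitude_is_percent: bool = True,
) -> float | None:
    """Seconds from the peak until the signal first falls to half amplitude.

    ``peak_time_s`` is relative to stimulus onset (as returned by
    :func:`peak_position`).  The crossing is linearly interpolated between
    the bracketing samples.  Returns ``None`` when the trace never reaches
    half amplitude after the peak (unresolved recovery).
    """
    amp = amplitude / 100.0 if amplitude_is_percent else amplitude
    target = 0.5 * amp
    t_peak = tc.stim_onset_s + peak_time_s
    after = np.flatnonzero(tc.t >= t_peak - 1e-12)
    if after.size < 2:
        raise ValueError("trace does not extend beyond the peak")
    t, y = tc.t[after], tc.y[after]
    below = np.flatnonzero(y <= target)
    below = below[below > 0]
    if below.size == 0:
        return None
    i = int(below[0])
    # linear interpolation between samples i-1 (above) and i (at/below)
    y0, y1 = y[i - 1], y[i]
    if y0 == y1:
        t_cross = t[i]
    else:
        t_cross = t[i - 1] + (y0 - target) / (y0 - y1) * (t[i] - t[i - 1])
    return float(t_cross - t_peak)


def average_lfp(lfp: LFPTrace, stim_window: tuple[float, float]) -> float:
    """Rectified integral of the LFP over the window, divided by its duration (uV)."""
    start, end = stim_window
    if end <= start:
        raise ValueError("empty stimulation window")
    sel = (lfp.t >= start - 1e-12) & (lfp.t <= end + 1e-12)
    if sel.sum() < 2:
        raise ValueError("stimulation window selects fewer than 2 samples")
    return float(np.trapezoid(np.abs(lfp.v[sel]), lfp.t[sel]) / (end - start))


def rank_stimulation_rates(amplitudes: Mapping[float, float], k: int = 3) -> list[float]:
    """The ``k`` stimulation rates with the largest amplitudes, descending.

    Ties in amplitude break toward the lower rate.  Mirrors the practice of
    pooling the few strongest responses when the per-rate SNR is low.
    """
    if len(amplitudes) < k:
        raise ValueError(f"need at least {k} rates, got {len(amplitudes)}")
    ranked = sorted(amplitudes.items(), key=lambda rv: (-rv[1], rv[0]))
    return [rate for rate, _ in ranked[:k]]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(_stats.pearsonr(x, y).statistic)


Direction = Literal["b_greater", "a_greater"]


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of b over a: #(b > a) pairs + 0.5 * ties."""
    diff = b[:, None] - a[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u_one_tailed(
    a: Sequence[float], b: Sequence[float], direction: Direction = "b_greater"
) -> float:
    """One-tailed Mann-Whitney U p-value for a shift between two groups.

    ``direction="b_greater"`` tests whether ``b`` tends to exceed ``a``.
    For pooled sizes m+n <= ``EXACT_MWU_MAX_N`` the p-value is exact:
    P(U >= U_obs) over all C(m+n, n) equally likely assignments of the
    pooled observations to the groups (ties handled by the 0.5 convention).
    Larger samples use the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if direction not in ("b_greater", "a_greater"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "a_greater":
        a, b = b, a
    m, n = a.size, b.size
    if m + n <= EXACT_MWU_MAX_N:
        pooled = np.concatenate([a, b])
        u_obs = _u_statistic(a, b)
        idx = range(m + n)
        count = total = 0
        for b_idx in combinations(idx, n):
            b_set = set(b_idx)
            bb = pooled[list(b_idx)]
            aa = pooled[[i for i in idx if i not in b_set]]
            total += 1
            if _u_statistic(aa, bb) >= u_obs - 1e-12:
                count += 1
        return count / total
    res = _stats.mannwhitneyu(b, a, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def sign_test_one_tailed(
    values: Sequence[float],
    threshold: float,
    direction: Literal["greater", "less"] = "greater",
) -> float:
    """Exact one-tailed sign test of the median against a threshold.

    Exact ties with the threshold are dropped; the p-value is the binomial
    tail P(X >= k) with X ~ Binomial(n, 1/2), k the count of values on the
    tested side.
    """
    values = np.asarray(values, dtype=float)
    diffs = values - threshold
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise ValueError("all values tie the threshold; sign test undefined")
    if direction == "greater":
        k = int(np.sum(diffs > 0))
    elif direction == "less":
        k = int(np.sum(diffs < 0))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(_stats.binomtest(k, diffs.size, 0.5, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# estimators for kernel parameters on noisy decomposed traces


def smooth_timecourse(tc: TimeCourse, window_s: float = 3.0, polyorder: int = 2) -> TimeCourse:
    """Savitzky-Golay smoothing of a time course.

    A short quadratic-preserving smooth: unbiased for locally parabolic
    signals (the peak neighborhood of the response kernels) while strongly
    attenuating frame-to-frame noise.  Used by the pipeline before kernel
    parameter read-out; never applied to raw frame stacks.
    """
    n = max(polyorder + 2, int(round(window_s / tc.dt)) | 1)  # odd window
    n = min(n, tc.y.size if tc.y.size % 2 else tc.y.size - 1)
    y = _signal.savgol_filter(tc.y, window_length=n, polyorder=polyorder)
    return TimeCourse(
        t=tc.t, y=y, stim_onset_s=tc.stim_onset_s, mode=tc.mode, polarity=tc.polarity, band=tc.band
    )


def refined_peak_time(
    tc: TimeCourse,
    window: tuple[float, float] | None = None,
    fit_halfwidth_s: float = 2.0,
) -> float:
    """Sub-frame peak time: quadratic vertex fit around the sample argmax.

    Returns seconds from stimulus onset.  Falls back to the raw argmax when
    the local fit is degenerate (flat or inverted curvature).
    """
    start, end = window if window is not None else (tc.stim_onset_s, tc.t[-1])
    sel = np.flatnonzero((tc.t >= start - 1e-12) & (tc.t <= end + 1e-12))
    if sel.size == 0:
        raise ValueError("window selects no samples")
    t, y = tc.t[sel], tc.y[sel]
    i = int(np.argmax(y))
    h = max(2, int(round(fit_halfwidth_s / tc.dt)))
    lo, hi = max(0, i - h), min(t.size, i + h + 1)
    if hi - lo >= 3:
        c2, c1, _ = np.polyfit(t[lo:hi] - t[i], y[lo:hi], 2)
        if c2 < 0:
            vertex = t[i] - c1 / (2.0 * c2)
            if t[lo] <= vertex <= t[hi - 1]:
                return float(vertex - tc.stim_onset_s)
    return float(t[i] - tc.stim_onset_s)


from dataclasses import dataclass as _dataclass


@_dataclass
class GammaKernelFit:
    """Least-squares gamma-variate fit of an evoked trace.

    ``peak_time_s`` is the kernel peak relative to stimulus onset (delay
    included); ``half_recovery_s`` is the post-peak half-amplitude time
    implied by the fitted kernel shape.
    """

    amplitude: float
    peak_time_s: float
    shape: float
    delay_s: float
    half_recovery_s: float
    rms_residual: float


def _half_recovery_of_shape(peak_time: float, shape: float) -> float:
    """Invert a = ln2 / (r - ln(1+r)) for r = t_half / t_peak."""
    from scipy.optimize import brentq

    target = np.log(2.0) / shape

    def g(r: float) -> float:
        return r - np.log1p(r) - target

    return peak_time * brentq(g, 1e-9, 1e6)


def fit_gamma_kernel(
    tc: TimeCourse,
    fit_delay: bool = False,
    flip: bool = False,
) -> GammaKernelFit:
    """Fit ``A * (x/tp)^a exp(a(1 - x/tp))``, x = t - onset - delay, to a trace.

    The gamma-variate is the standard parametric form for evoked
    hemodynamic-type transients; fitting it reads peak time, amplitude and
    recovery off a noisy trace without the bias of local polynomial
    estimators on asymmetric peaks.  ``flip`` fits the negated trace
    (negative-going responses); the returned amplitude is then negative.
    """
    from scipy.optimize import curve_fit

    t_rel = tc.t - tc.stim_onset_s
    y = -tc.y if flip else tc.y
    i = int(np.argmax(y))
    tp0 = max(float(t_rel[i]), 2.0 * tc.dt)
    amp0 = float(y[i])

    def model(x: np.ndarray, amp: float, delay: float, tp: float, shape: float) -> np.ndarray:
        xx = x - delay
        out = np.zeros_like(xx)
        pos = xx > 0
        z = xx[pos] / tp
        out[pos] = amp * np.exp(shape * (np.log(z) + 1.0 - z))
        return out

    if fit_delay:
        p0 = [amp0, 0.0, tp0, 3.0]
        bounds = ([-np.inf, 0.0, 2.0 * tc.dt, 0.05], [np.inf, t_rel[-1], 10.0 * t_rel[-1], 100.0])
        popt, _ = curve_fit(model, t_rel, y, p0=p0, bounds=bounds, maxfev=20000)
        amp, delay, tp, shape = popt
    else:
        p0 = [amp0, tp0, 3.0]
        bounds = ([-np.inf, 2.0 * tc.dt, 0.05], [np.inf, 10.0 * t_rel[-1], 100.0])
        popt, _ = curve_fit(
            lambda x, amp, tp, shape: model(x, amp, 0.0, tp, shape),
            t_rel, y, p0=p0, bounds=bounds, maxfev=20000,
        )
        amp, tp, shape = popt
        delay = 0.0
    resid = y - model(t_rel, amp, delay, tp, shape)
    return GammaKernelFit(
        amplitude=float(-amp if flip else amp),
        peak_time_s=float(delay + tp),
        shape=float(shape),
        delay_s=float(delay),
        half_recovery_s=float(_half_recovery_of_shape(tp, shape)),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )
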