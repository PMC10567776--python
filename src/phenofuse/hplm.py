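"""Hybrid piecewise-logistic phenology detection (HPLM-LSPD).

A gap-free annual EVI2 series is processed in five steps:

1. the dormant-season background ``EVI2_b`` is the mean of values below the
   10th percentile of the sorted series;
2. the series is smoothed by a moving-median / moving-average /
   Savitzky-Golay cascade;
3. growth cycles are delimited by sustained slope-sign changes, each cycle
   split into a greenup and a senescence phase at its peak;
4. each phase is fitted with a hybrid piecewise logistic model,

       EVI2(t) = c / (1 + exp(a + b t)) + EVI2_b            (favorable)
       EVI2(t) = (c + d t) / (1 + exp(a + b t)) + EVI2_b    (stress)

   where t is day of year, b sets the rate of green-leaf development, c the
   seasonal amplitude and d a linear vegetation-stress modulation;
5. transition dates (greenup, maturity, senescence, dormancy onsets) are the
   local extremes of the curvature change rate dK/dt of the fitted curve,
   with K = f''/(1+f'^2)^(3/2).

Up to three cycles per pixel are reported; the main (largest-amplitude)
cycle is conventionally stored in slot 2 of the 12-value output record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .timegrid import WINDOW_CENTER_DOYS

#: Minimum peak-minus-background amplitude for a cycle to count (EVI2 units).
MIN_CYCLE_AMPLITUDE = 0.1

#: Centered window (composite steps) for the slope used to delimit phases.
SLOPE_WINDOW_STEPS = 5

_EXP_CLIP = 80.0


class SegmentUnfittableError(RuntimeError):
    """Raised when neither HPLM form converges on a segment."""


def hplm_favorable(t, a, b, c, evi2_b):
    """Single logistic: c / (1 + exp(a + b*t)) + EVI2_b."""
    z = np.exp(np.clip(a + b * np.asarray(t, dtype=float), -_EXP_CLIP, _EXP_CLIP))
    return c / (1.0 + z) + evi2_b


def hplm_stress(t, a, b, c, d, evi2_b):
    """Stress form: (c + d*t) / (1 + exp(a + b*t)) + EVI2_b."""
    t = np.asarray(t, dtype=float)
    z = np.exp(np.clip(a + b * t, -_EXP_CLIP, _EXP_CLIP))
    return (c + d * t) / (1.0 + z) + evi2_b


@dataclass(frozen=True)
class HPLMParams:
    """Fitted parameters of one greenup or senescence segment."""

    form: str  # 'favorable' | 'stress'
    a: float
    b: float
    c: float
    evi2_b: float
    d: float | None = None
    sse: float = np.nan

    def predict(self, t):
        if self.form == "favorable":
            return hplm_favorable(t, self.a, self.b, self.c, self.evi2_b)
        return hplm_stress(t, self.a, self.b, self.c, self.d, self.evi2_b)


@dataclass(frozen=True)
class GrowthCycle:
    """One detected cycle: step index ranges of its two phases."""

    greenup_segment: tuple[int, int]  # (start, peak) inclusive
    senescence_segment: tuple[int, int]  # (peak, end) inclusive
    amplitude: float


@dataclass
class Phenometrics:
    """Four transition dates (DOY) of one growth cycle; None = undetected."""

    greenup: float | None = None
    maturity: float | None = None
    senescence: float | None = None
    dormancy: float | None = None
    cycle_slot: int | None = None

    def as_tuple(self) -> tuple:
        return (self.greenup, self.maturity, self.senescence, self.dormancy)


def background_evi2(values: np.ndarray) -> float:
    """Dormant-season background: mean of values below the 10th percentile.

    The percentile follows the inverted-CDF convention (the ceil(0.1*n)-th
    order statistic).  If no value lies strictly below it (heavy ties), the
    mean of the smallest decile by count is used; a constant series returns
    the constant.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need at least 10 values")
    thresh = np.percentile(v, 10, method="inverted_cdf")
    low = v[v < thresh]
    if low.size == 0:
        k = max(1, v.size // 10)
        low = np.sort(v)[:k]
    return float(low.mean())


def _rolling(values: np.ndarray, window: int, fn) -> np.ndarray:
    """Centered rolling statistic with shrinking windows at the edges."""
    n = values.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        out[i] = fn(values[max(0, i - half) : min(n, i + half + 1)])
    return out


def smooth_series(values: np.ndarray) -> np.ndarray:
    """Three-stage smoothing: moving median (3), moving average (3),
    Savitzky-Golay (window 5, order 2).  Length-preserving; window edges
    shrink at the series ends."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("smooth_series requires a gap-free series")
    v = _rolling(v, 3, np.median)
    v = _rolling(v, 3, np.mean)
    return savgol_filter(v, 5, 2, mode="interp")


def _slopes(values: np.ndarray, window: int, step_days: float = 3.0) -> np.ndarray:
    """Least-squares slope (per day) over a centered window of steps."""
    n = values.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = np.arange(lo, hi) * step_days
        out[i] = np.polyfit(x, values[lo:hi], 1)[0]
    return out


def detect_cycles(
    smoothed: np.ndarray,
    evi2_b: float,
    min_amplitude: float = MIN_CYCLE_AMPLITUDE,
    slope_window: int = SLOPE_WINDOW_STEPS,
    slope_tol: float = 2e-4,
    min_run: int = 2,
    max_cycles: int = 3,
) -> list[GrowthCycle]:
    """Delimit up to three growth cycles from sustained slope-sign changes.

    Slopes are least-squares fits over a centered ``slope_window``-step
    (15-day) window.  A peak is a transition from a sustained rising run to
    a sustained falling run; cycles whose peak sits less than
    ``min_amplitude`` above the background are discarded.  When more than
    ``max_cycles`` qualify, the largest amplitudes are kept; cycles are
    returned chronologically.
    """
    y = np.asarray(smoothed, dtype=float)
    n = y.size
    s = _slopes(y, slope_window)
    sign = np.where(s > slope_tol, 1, np.where(s < -slope_tol, -1, 0))
    # carry the previous non-flat sign through flat stretches
    for i in range(1, n):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    nz = np.nonzero(sign)[0]
    if nz.size == 0:
        return []
    sign[: nz[0]] = sign[nz[0]]

    # run-length encode and locate sustained +/- transitions (peaks)
    runs: list[tuple[int, int, int]] = []  # (sign, start, end_exclusive)
    start = 0
    for i in range(1, n + 1):
        if i == n or sign[i] != sign[start]:
            runs.append((int(sign[start]), start, i))
            start = i
    peaks = []
    for j in range(len(runs) - 1):
        s0, a0, b0 = runs[j]
        s1, a1, b1 = runs[j + 1]
        if s0 == 1 and s1 == -1 and (b0 - a0) >= min_run and (b1 - a1) >= min_run:
            seg = y[a0:b1]
            peaks.append(a0 + int(np.argmax(seg)))

    peaks = [p for p in peaks if y[p] - evi2_b >= min_amplitude]
    # merge peaks separated by shallow troughs: a real cycle boundary dips
    # well below both neighbors, a noise wiggle on one season does not
    merge_depth = 0.5 * min_amplitude
    while len(peaks) > 1:
        depths = []
        for j in range(len(peaks) - 1):
            trough = y[peaks[j] : peaks[j + 1] + 1].min()
            depths.append(min(y[peaks[j]], y[peaks[j + 1]]) - trough)
        jmin = int(np.argmin(depths))
        if depths[jmin] >= merge_depth:
            break
        drop = jmin if y[peaks[jmin]] <= y[peaks[jmin + 1]] else jmin + 1
        peaks.pop(drop)
    if not peaks:
        return []
    if len(peaks) > max_cycles:
        keep = sorted(
            sorted(range(len(peaks)), key=lambda i: y[peaks[i]], reverse=True)[
                :max_cycles
            ]
        )
        peaks = [peaks[i] for i in keep]

    cycles = []
    for k, p in enumerate(peaks):
        lo = 0 if k == 0 else peaks[k - 1] + int(np.argmin(y[peaks[k - 1] : p + 1]))
        hi = (
            n - 1
            if k == len(peaks) - 1
            else p + int(np.argmin(y[p : peaks[k + 1] + 1]))
        )
        cycles.append(
            GrowthCycle(
                greenup_segment=(lo, p),
                senescence_segment=(p, hi),
                amplitude=float(y[p] - evi2_b),
            )
        )
    return cycles


def _fit_form(form, t, y, evi2_b, direction, rng):
    amp = float(np.max(y) - evi2_b)
    if amp <= 1e-3 or np.std(y) < 1e-6:
        return None
    half = evi2_b + amp / 2.0
    t_mid = float(t[np.argmin(np.abs(y - half))])
    b_mags = (0.03, 0.08, 0.15)
    b_sign = -1.0 if direction == "rising" else 1.0

    starts = []
    for m in b_mags:
        b0 = b_sign * m
        starts.append((-b0 * t_mid, b0))
    for m in b_mags:  # jittered restarts around the midpoint crossing
        b0 = b_sign * m * float(rng.uniform(0.6, 1.6))
        tm = t_mid + float(rng.normal(0.0, 6.0))
        starts.append((-b0 * tm, b0))

    best = None
    for a0, b0 in starts:
        if form == "favorable":
            x0 = [a0, b0, amp]
            lb = [-300.0, -2.0 if b_sign < 0 else 1e-4, 1e-4]
            ub = [300.0, -1e-4 if b_sign < 0 else 2.0, 3.0]

            def resid(x):
                return hplm_favorable(t, x[0], x[1], x[2], evi2_b) - y
        else:
            x0 = [a0, b0, amp, 0.0]
            lb = [-300.0, -2.0 if b_sign < 0 else 1e-4, 1e-4, -0.05]
            ub = [300.0, -1e-4 if b_sign < 0 else 2.0, 3.0, 0.05]

            def resid(x):
                return hplm_stress(t, x[0], x[1], x[2], x[3], evi2_b) - y

        try:
            res = least_squares(resid, x0, bounds=(lb, ub), method="trf")
        except ValueError:
            continue
        if not res.success:
            continue
        if form == "stress" and np.min(res.x[2] + res.x[3] * t) <= 0:
            continue  # stress amplitude c + d*t must stay positive
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res.x)
    return best


def fit_hplm(
    t: np.ndarray,
    y: np.ndarray,
    evi2_b: float,
    direction: str,
    seed: int | None = 0,
    stress_improvement: float = 0.1,
) -> HPLMParams:
    """Fit both HPLM forms to one segment and keep the better.

    ``direction`` ('rising' for greenup, 'falling' for senescence) fixes the
    sign of b.  The background is held fixed.  Each form is started from
    three deterministic midpoint-crossing initializations plus three seeded
    jittered restarts.  The stress form is preferred only when it lowers the
    SSE by more than ``stress_improvement`` (relative): it nests the
    favorable form, so on noisy data it is almost always marginally lower
    and a small gain is not evidence of stress.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise SegmentUnfittableError("segment shorter than 5 steps")
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    rng = np.random.default_rng(seed)
    fav = _fit_form("favorable", t, y, evi2_b, direction, rng)
    sts = _fit_form("stress", t, y, evi2_b, direction, rng)
    if fav is None and sts is None:
        raise SegmentUnfittableError("neither HPLM form converged")
    if fav is not None and (
        sts is None or sts[0] >= (1.0 - stress_improvement) * fav[0]
    ):
        sse, x = fav
        return HPLMParams("favorable", x[0], x[1], x[2], evi2_b, sse=sse)
    sse, x = sts
    return HPLMParams("stress", x[0], x[1], x[2], evi2_b, d=x[3], sse=sse)


def _derivatives(fit: HPLMParams, t: np.ndarray):
    """(f', f'', f''') of the fitted curve.

    Analytic for the favorable logistic; 4th-order central finite
    differences (h = 0.05 day) for the stress form.
    """
    t = np.asarray(t, dtype=float)
    if fit.form == "favorable":
        a, b, c = fit.a, fit.b, fit.c
        z = np.exp(np.clip(a + b * t, -_EXP_CLIP, _EXP_CLIP))
        one = 1.0 + z
        d1 = -c * b * z / one**2
        d2 = -c * b**2 * z * (1.0 - z) / one**3
        d3 = -c * b**3 * z * (1.0 - 4.0 * z + z**2) / one**4
        return d1, d2, d3
    h = 0.05
    f = fit.predict
    d1 = (-f(t + 2 * h) + 8 * f(t + h) - 8 * f(t - h) + f(t - 2 * h)) / (12 * h)
    d2 = (
        -f(t + 2 * h) + 16 * f(t + h) - 30 * f(t) + 16 * f(t - h) - f(t - 2 * h)
    ) / (12 * h**2)
    d3 = (
        -f(t + 3 * h)
        + 8 * f(t + 2 * h)
        - 13 * f(t + h)
        + 13 * f(t - h)
        - 8 * f(t - 2 * h)
        + f(t - 3 * h)
    ) / (8 * h**3)
    return d1, d2, d3


def curvature_change_rate(fit: HPLMParams, t: np.ndarray) -> np.ndarray:
    """dK/dt of the fitted curve, K = f''/(1+f'^2)^(3/2)."""
    d1, d2, d3 = _derivatives(fit, t)
    return (d3 * (1.0 + d1**2) - 3.0 * d1 * d2**2) / (1.0 + d1**2) ** 2.5


def _local_extrema(values: np.ndarray, kind: str, rel_tol: float = 0.01) -> np.ndarray:
    """Interior local extrema, ignoring numerically flat tail wiggles.

    Only extrema whose magnitude reaches ``rel_tol`` of the strongest value
    of the same sign count — dK/dt of a logistic decays to zero in the
    dormant tails, where rounding noise produces meaningless extrema.
    """
    v = values if kind == "max" else -values
    idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
    if idx.size:
        idx = idx[v[idx] > rel_tol * v.max()]
    return idx


def transition_dates(
    fit: HPLMParams,
    t_start: float,
    t_end: float,
    phase: str,
    dt: float = 0.1,
    extend_days: float = 0.0,
) -> tuple[float | None, float | None]:
    """Locate a phase's two transition dates from the curvature change rate.

    dK/dt is evaluated on a dense ``dt``-day grid over the segment domain.
    In a greenup phase the first and last local maxima of dK/dt are the
    greenup and maturity onsets; in a senescence phase the first and last
    local minima are the senescence and dormancy onsets (the falling curve
    mirrors the rising one, flipping the sign of dK/dt).  Fewer than two
    extrema yield a partial result (None entries).

    ``extend_days`` widens the evaluated domain on both sides (clipped to
    DOY 1-366): segment boundaries come from a noisy peak estimate, and the
    fitted curve's bend can sit marginally outside them.
    """
    if phase not in ("greenup", "senescence"):
        raise ValueError("phase must be 'greenup' or 'senescence'")
    t_start = max(1.0, t_start - extend_days)
    t_end = min(366.0, t_end + extend_days)
    grid = np.arange(t_start, t_end + dt / 2.0, dt)
    if grid.size < 3:
        return (None, None)
    kp = curvature_change_rate(fit, grid)
    idx = _local_extrema(kp, "max" if phase == "greenup" else "min")
    if idx.size == 0:
        return (None, None)
    if idx.size == 1:
        return (float(grid[idx[0]]), None)
    return (float(grid[idx[0]]), float(grid[idx[-1]]))


def detect_phenometrics(
    values: np.ndarray,
    t: np.ndarray | None = None,
    min_amplitude: float = MIN_CYCLE_AMPLITUDE,
    seed: int | None = 0,
    extend_days: float = 15.0,
) -> tuple[float, list[GrowthCycle], list[Phenometrics]]:
    """Run the five-step detection on one gap-free annual EVI2 series.

    Returns the background value, the detected cycles, and one
    ``Phenometrics`` per cycle (chronological; ``cycle_slot`` set by
    :func:`assign_cycle_slots` convention).

    Short residual gaps (e.g., steps a warped fusion donor could not cover
    at the series edges) are filled by linear interpolation / nearest-value
    extension first; the five-step procedure itself needs gap-free input.
    """
    if t is None:
        t = WINDOW_CENTER_DOYS.astype(float)
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).any():
        raise ValueError("all-gap series")
    if not np.isfinite(values).all():
        ok = np.nonzero(np.isfinite(values))[0]
        values = np.interp(np.arange(values.size), ok, values[ok])
    # background from the smoothed series: the lowest-decile mean applied to
    # raw noisy values is biased low by the order statistics of the noise,
    # which drags the fixed model floor down and spreads the fitted dates
    smoothed = smooth_series(values)
    evi2_b = background_evi2(smoothed)
    cycles = detect_cycles(smoothed, evi2_b, min_amplitude=min_amplitude)

    phenos: list[Phenometrics] = []
    for cyc in cycles:
        ph = Phenometrics()
        g0, g1 = cyc.greenup_segment
        s0, s1 = cyc.senescence_segment
        try:
            if g1 - g0 + 1 >= 5:
                fit = fit_hplm(t[g0 : g1 + 1], smoothed[g0 : g1 + 1], evi2_b,
                               "rising", seed=seed)
                ph.greenup, ph.maturity = transition_dates(
                    fit, t[g0], t[g1], "greenup", extend_days=extend_days
                )
        except SegmentUnfittableError:
            pass
        try:
            if s1 - s0 + 1 >= 5:
                fit = fit_hplm(t[s0 : s1 + 1], smoothed[s0 : s1 + 1], evi2_b,
                               "falling", seed=seed)
                ph.senescence, ph.dormancy = transition_dates(
                    fit, t[s0], t[s1], "senescence", extend_days=extend_days
                )
        except SegmentUnfittableError:
            pass
        phenos.append(ph)

    slots = assign_cycle_slots(cycles, phenos)
    for ph, slot in zip(phenos, slots):
        ph.cycle_slot = slot
    return evi2_b, cycles, phenos


def assign_cycle_slots(
    cycles: list[GrowthCycle], phenos: list[Phenometrics]
) -> list[int]:
    """Chronological slot (1-3) of each cycle, main cycle pinned to slot 2.

    Layouts: no cycle -> nothing; one cycle -> slot 2; two cycles -> the
    main (largest-amplitude) one in slot 2, the other in slot 1 (if earlier)
    or 3 (if later); three cycles -> slots 1, 2, 3 chronologically (so a
    main cycle preceded by two smaller ones lands in slot 3).
    """
    n = len(cycles)
    if n == 0:
        return []
    if n == 1:
        return [2]
    if n == 2:
        main = 0 if cycles[0].amplitude >= cycles[1].amplitude else 1
        return [2, 3] if main == 0 else [1, 2]
    return [1, 2, 3]


def phenometrics_record(phenos: list[Phenometrics]) -> np.ndarray:
    """12-value record: (greenup, maturity, senescence, dormancy) x slots 1-3.

    Unused slots and undetected dates are NaN (encoded as nodata on write).
    """
    out = np.full(12, np.nan)
    for ph in phenos:
        if ph.cycle_slot is None:
            continue
        base = (ph.cycle_slot - 1) * 4
        for k, v in enumerate(ph.as_tuple()):
            if v is not None:
                out[base + k] = v
    return out
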