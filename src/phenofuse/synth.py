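"""Seeded synthetic scenes: truth phenology, degraded EVI2, donor GCC series.

Everything the pipeline consumes can be generated here without any
downloads: double-logistic seasonal truth curves with known transition
dates, noisy quality-flagged reflectance observations with clustered cloud
gaps (persistent cloud cover produces multi-week runs of missing
composites), and camera GCC donor collections related to the EVI2 truth by
the SSMM scaling family (a, b, lambda, beta), plus uncorrelated / flat /
out-of-season decoy donors.

Truth transition dates are computed by a dense-grid *numeric* curvature
change-rate oracle applied to the generating curve — never by the fitting
path under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composite import EVI2Series
from .phenocam import GCCCollection, GCCSeries
from .ssmm import ScalingFactors, warp_time
from .timegrid import N_STEPS, WINDOW_CENTER_DOYS, days_in_year, window_index

#: Default observation noise, EVI2 units.
DEFAULT_NOISE_SD = 0.02

#: Default mean gap-run length, composite steps (12 days).
DEFAULT_GAP_RUN = 4

#: Typical GCC dynamic range of a vegetated camera grid.
GCC_BASE, GCC_AMPLITUDE = 0.34, 0.10


@dataclass(frozen=True)
class TruthCycle:
    """One growth cycle of the generating double-logistic curve."""

    rise_mid: float  # DOY of the greenup inflection
    rise_rate: float  # 1/day
    fall_mid: float  # DOY of the senescence inflection
    fall_rate: float  # 1/day
    amplitude: float  # EVI2 units


@dataclass(frozen=True)
class TruthParams:
    cycles: tuple[TruthCycle, ...]
    evi2_b: float = 0.08


@dataclass
class TruthPixel:
    """A synthetic pixel: generating parameters, truth dates, degradation."""

    params: TruthParams
    true_dates: list  # one 4-tuple (greenup, maturity, senescence, dormancy)/cycle
    noise_sd: float
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def truth_curve(params: TruthParams):
    """Continuous EVI2 truth f(t), t in days (vectorized)."""

    def f(t):
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, params.evi2_b)
        for c in params.cycles:
            rise = 1.0 / (1.0 + np.exp(-c.rise_rate * (t - c.rise_mid)))
            fall = 1.0 / (1.0 + np.exp(c.fall_rate * (t - c.fall_mid)))
            out = out + c.amplitude * (rise + fall - 1.0)
        return out

    return f


def make_truth_curve(params: TruthParams, year: int) -> np.ndarray:
    """Daily truth composited to the 122-step grid (window means)."""
    f = truth_curve(params)
    doys = np.arange(1, days_in_year(year) + 1)
    daily = f(doys)
    idx = window_index(doys)
    out = np.zeros(N_STEPS)
    count = np.zeros(N_STEPS)
    np.add.at(out, idx, daily)
    np.add.at(count, idx, 1)
    return out / count


def numeric_transition_dates(
    f, t_start: float, t_peak: float, t_end: float, dt: float = 0.1
) -> tuple:
    """Dense-grid numeric curvature change-rate oracle on a curve callable.

    Derivatives come from repeated second-order finite differencing
    (np.gradient) of samples on a ``dt``-day grid; transition dates are the
    first/last local maxima of dK/dt before the peak and the first/last
    local minima after it.
    """
    pad = 30  # samples trimmed per side: repeated np.gradient corrupts edges
    grid = np.arange(t_start - pad * dt, t_end + (pad + 0.5) * dt, dt)
    y = f(grid)
    d1 = np.gradient(y, dt)
    d2 = np.gradient(d1, dt)
    d3 = np.gradient(d2, dt)
    kp = (d3 * (1.0 + d1**2) - 3.0 * d1 * d2**2) / (1.0 + d1**2) ** 2.5
    grid, kp = grid[pad:-pad], kp[pad:-pad]

    def extrema(lo, hi, kind):
        seg = kp[lo:hi]
        v = seg if kind == "max" else -seg
        idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
        if idx.size:  # drop rounding-noise wiggles in the flat tails
            idx = idx[v[idx] > 0.01 * v.max()]
        return idx + lo

    peak_i = int(np.searchsorted(grid, t_peak))
    up = extrema(0, peak_i + 1, "max")
    down = extrema(peak_i, grid.size, "min")
    greenup = float(grid[up[0]]) if up.size else None
    maturity = float(grid[up[-1]]) if up.size > 1 else None
    senescence = float(grid[down[0]]) if down.size else None
    dormancy = float(grid[down[-1]]) if down.size > 1 else None
    return (greenup, maturity, senescence, dormancy)


def true_dates(params: TruthParams, dt: float = 0.1) -> list[tuple]:
    """Truth transition dates per cycle via the numeric oracle."""
    f = truth_curve(params)
    cycles = sorted(params.cycles, key=lambda c: c.rise_mid)
    out = []
    for k, c in enumerate(cycles):
        lo = c.rise_mid - 4.0 / c.rise_rate
        hi = c.fall_mid + 4.0 / c.fall_rate
        if k > 0:
            lo = max(lo, 0.5 * (cycles[k - 1].fall_mid + c.rise_mid))
        if k < len(cycles) - 1:
            hi = min(hi, 0.5 * (c.fall_mid + cycles[k + 1].rise_mid))
        lo, hi = max(lo, 1.0), min(hi, 365.0)
        grid = np.arange(lo, hi, dt)
        t_peak = float(grid[np.argmax(f(grid))])
        out.append(numeric_transition_dates(f, lo, t_peak, hi, dt))
    return out


def degrade(
    values: np.ndarray,
    noise_sd: float,
    gap_fraction: float,
    rng: np.random.Generator,
    mean_run: float = DEFAULT_GAP_RUN,
) -> EVI2Series:
    """Add seeded Gaussian noise and clustered gaps to a 122-step truth.

    Gap runs have geometric lengths (mean ``mean_run`` steps), emulating
    persistent cloud cover; the run pattern is then trimmed/extended at run
    edges so the realized gap count equals round(gap_fraction * 122)
    exactly (well within the +-5% tolerance).
    """
    if not 0.0 <= gap_fraction <= 1.0:
        raise ValueError("gap_fraction must be in [0, 1]")
    v = np.asarray(values, dtype=float) + rng.normal(0.0, noise_sd, N_STEPS)
    target = int(round(gap_fraction * N_STEPS))
    mask = np.zeros(N_STEPS, dtype=bool)
    if target > 0:
        p_gap = 1.0 / mean_run
        clear_mean = max(1.0, mean_run * (1.0 - gap_fraction) / max(gap_fraction, 1e-9))
        pos, state = 0, bool(rng.random() < gap_fraction)
        while pos < N_STEPS:
            run = int(rng.geometric(p_gap if state else 1.0 / clear_mean))
            if state:
                mask[pos : pos + run] = True
            pos += run
            state = not state
        # adjust at run edges to hit the target count exactly
        while mask.sum() > target:
            edges = np.nonzero(mask & ~np.roll(mask, 1))[0]
            mask[rng.choice(edges)] = False
        while mask.sum() < target:
            candidates = np.nonzero(~mask & (np.roll(mask, 1) | np.roll(mask, -1)))[0]
            if candidates.size == 0:
                candidates = np.nonzero(~mask)[0]
            mask[rng.choice(candidates)] = True
    return EVI2Series(2019, np.where(mask, np.nan, v), mask)


def gcc_shape_curve(params: TruthParams):
    """A GCC-like continuous curve sharing the truth's temporal shape."""
    f = truth_curve(params)
    amp = sum(c.amplitude for c in params.cycles)

    def g(t):
        return GCC_BASE + GCC_AMPLITUDE * (f(t) - params.evi2_b) / max(amp, 1e-9)

    return g


def donor_from_truth(
    params: TruthParams,
    factors: ScalingFactors,
    year: int,
    site_id: str,
    grid_index: tuple[int, int] = (0, 0),
) -> tuple[GCCSeries, ScalingFactors]:
    """A donor whose warped, rescaled shape reproduces the truth curve.

    The donor GCC is sampled at ``T/lambda - beta`` of the truth's GCC-shaped
    curve, so warping it by (lambda, beta) recovers the truth shape; the
    returned factors map the donor onto the EVI2 truth via Eq.-1 scaling.
    """
    g = gcc_shape_curve(params)
    T = WINDOW_CENTER_DOYS.astype(float)
    gcc_vals = g(T / factors.lam - factors.beta)
    donor = GCCSeries(site_id, grid_index, year, gcc_vals)
    amp = sum(c.amplitude for c in params.cycles)
    a = amp / GCC_AMPLITUDE
    b = params.evi2_b - a * GCC_BASE
    return donor, ScalingFactors(a, b, factors.lam, factors.beta)


def pixel_from_donor(
    donor: GCCSeries, factors: ScalingFactors, year: int
) -> tuple[np.ndarray, np.ndarray]:
    """EVI2 truth constructed from a donor by the exact scaling family.

    Returns (values, valid) where values = a*GCC(lambda*(t+beta)) + b on the
    122-step grid and ``valid`` marks steps whose warped time falls inside
    the donor's domain (the matcher can reproduce these exactly).
    """
    warped, valid = warp_time(donor, factors.lam, factors.beta)
    donor_t = WINDOW_CENTER_DOYS.astype(float)
    T = factors.lam * (donor_t + factors.beta)
    clamped = np.interp(T, donor_t, donor.values)
    values = factors.a * np.where(valid, warped, clamped) + factors.b
    return values, valid


def make_decoy_donors(
    rng: np.random.Generator, year: int, n_noise: int = 2, n_flat: int = 1,
    n_shifted: int = 1, shape_params: TruthParams | None = None,
) -> list[GCCSeries]:
    """Donors that must never win: white noise, flat, far-out-of-season."""
    donors = []
    for k in range(n_noise):
        vals = GCC_BASE + GCC_AMPLITUDE * rng.random(N_STEPS)
        donors.append(GCCSeries("decoy-noise", (k, 0), year, vals))
    for k in range(n_flat):
        vals = np.full(N_STEPS, GCC_BASE + 0.04)
        donors.append(GCCSeries("decoy-flat", (k, 0), year, vals))
    if n_shifted and shape_params is not None:
        g = gcc_shape_curve(shape_params)
        T = WINDOW_CENTER_DOYS.astype(float)
        for k in range(n_shifted):
            donors.append(
                GCCSeries("decoy-shifted", (k, 0), year, g(T - 80.0 * (k + 1)))
            )
    return donors


def make_donor_collection(
    matched: list[GCCSeries], decoys: list[GCCSeries]
) -> GCCCollection:
    return GCCCollection(list(matched) + list(decoys))


def score_recovery(detected: np.ndarray, truth: np.ndarray) -> dict:
    """Agreement metrics between detected and truth dates.

    R^2 (squared Pearson correlation), RMSE, MAD (mean absolute difference)
    and MSB (mean systematic bias, detected minus truth), over pairs where
    both are present.
    """
    d = np.asarray(detected, dtype=float)
    t = np.asarray(truth, dtype=float)
    ok = np.isfinite(d) & np.isfinite(t)
    d, t = d[ok], t[ok]
    if d.size < 3:
        raise ValueError("need at least 3 paired dates")
    diff = d - t
    r = np.corrcoef(d, t)[0, 1]
    return {
        "r2": float(r**2),
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "mad": float(np.mean(np.abs(diff))),
        "msb": float(np.mean(diff)),
        "n": int(d.size),
    }


# --- raw-observation synthesis for end-to-end runs ------------------------

_RED, _GREEN, _SWIR1 = 0.05, 0.08, 0.25


def reflectance_from_evi2(evi2: np.ndarray) -> dict:
    """Invert the EVI2 formula at fixed red reflectance (0.05).

    Solves 2.5*(nir-red)/(nir+2.4*red+1) = evi2 for nir; green and SWIR1 are
    constants chosen so that NDVI > EVI2/0.9 and NDWI < NDVI for healthy
    vegetation (the screening rules stay quiet on clean data).
    """
    evi2 = np.asarray(evi2, dtype=float)
    nir = (2.5 * _RED + evi2 * (2.4 * _RED + 1.0)) / (2.5 - evi2)
    return {
        "red": np.full(evi2.shape, _RED),
        "nir": nir,
        "green": np.full(evi2.shape, _GREEN),
        "swir1": np.full(evi2.shape, _SWIR1),
    }


def make_observations(
    params: TruthParams,
    year: int,
    rng: np.random.Generator,
    noise_sd: float = DEFAULT_NOISE_SD,
    cloud_fraction: float = 0.5,
    mean_run_days: float = 12.0,
) -> pd.DataFrame:
    """Daily quality-flagged reflectance observations for one pixel.

    Cloudy days come in geometric-length runs; cloudy observations carry a
    perturbed signal and a ``cloud`` QA flag, clear days carry Gaussian
    EVI2 noise and ``high`` QA.
    """
    n_days = days_in_year(year)
    doys = np.arange(1, n_days + 1)
    evi2 = truth_curve(params)(doys) + rng.normal(0.0, noise_sd, n_days)

    cloudy = np.zeros(n_days, dtype=bool)
    pos = 0
    state = bool(rng.random() < cloud_fraction)
    clear_mean = max(1.0, mean_run_days * (1.0 - cloud_fraction) / max(cloud_fraction, 1e-9))
    while pos < n_days:
        run = int(rng.geometric(1.0 / mean_run_days if state else 1.0 / clear_mean))
        if state:
            cloudy[pos : pos + run] = True
        pos += run
        state = not state

    evi2 = np.where(cloudy, np.clip(evi2 - 0.3, -0.5, None), evi2)
    evi2 = np.clip(evi2, 0.01, 0.95)
    bands = reflectance_from_evi2(evi2)
    dates = pd.Timestamp(f"{year}-01-01") + pd.to_timedelta(doys - 1, unit="D")
    return pd.DataFrame(
        {
            "date": dates,
            "red": bands["red"],
            "nir": bands["nir"],
            "green": bands["green"],
            "swir1": bands["swir1"],
            "qa": np.where(cloudy, "cloud", "high"),
        }
    )


def random_truth_params(
    rng: np.random.Generator, n_cycles: int = 1, evi2_b: float | None = None
) -> TruthParams:
    """Realistic mid-latitude parameters: greenup around May, senescence
    around late September, amplitude 0.3-0.5."""
    if evi2_b is None:
        evi2_b = float(rng.uniform(0.06, 0.12))
    cycles = []
    if n_cycles == 1:
        cycles.append(
            TruthCycle(
                rise_mid=float(rng.uniform(120, 150)),
                rise_rate=float(rng.uniform(0.07, 0.12)),
                fall_mid=float(rng.uniform(255, 285)),
                fall_rate=float(rng.uniform(0.07, 0.12)),
                amplitude=float(rng.uniform(0.3, 0.5)),
            )
        )
    else:
        spans = np.linspace(60, 330, 2 * n_cycles + 1)
        for k in range(n_cycles):
            cycles.append(
                TruthCycle(
                    rise_mid=float(spans[2 * k] + rng.uniform(-5, 5)),
                    rise_rate=float(rng.uniform(0.09, 0.14)),
                    fall_mid=float(spans[2 * k + 1] + rng.uniform(-5, 5)),
                    fall_rate=float(rng.uniform(0.09, 0.14)),
                    amplitude=float(rng.uniform(0.25, 0.5)),
                )
            )
    return TruthParams(cycles=tuple(cycles), evi2_b=evi2_b)
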