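"""3-day EVI2 compositing of quality-screened surface-reflectance observations.

Raw multi-band observations (red, NIR, green, SWIR1 plus a per-observation
quality class) are reduced to a 122-step annual EVI2 series.  Only
high-quality observations contribute; windows without any are gaps.  Three
screening rules then convert suspect composite values into gaps:

(i)   EVI2 exceeding 90% of the co-located 3-day NDVI,
(ii)  EVI2 exceeding 110% of the non-gap EVI2 values in the preceding and
      succeeding one-month period (a spike that sticks out on both sides),
(iii) NDVI below NDWI (residual cloud / snow / surface-water contamination).

Vegetation indices are computed per observation and then composited, so the
quality screen applies at observation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timegrid import N_STEPS, WINDOW_START_DOYS, window_index

QA_HIGH = "high"
QA_CLASSES = frozenset(
    {"high", "snow_ice", "cloud", "cloud_shadow", "adjacent_cloud", "cirrus"}
)

#: Composite steps on each side of a step making up the "one-month period"
#: of spike rule (ii): 10 steps = 30 days.
SPIKE_NEIGHBORHOOD_STEPS = 10


class InvalidObservationError(ValueError):
    """Raised for non-finite reflectance or a degenerate index denominator."""


@dataclass
class EVI2Series:
    """One pixel's annual 3-day EVI2 composite with explicit gap marks.

    ``values`` holds NaN at gap steps; ``gap_mask`` is True there.
    """

    year: int
    values: np.ndarray
    gap_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STEPS,):
            raise ValueError(f"EVI2Series needs exactly {N_STEPS} steps")
        if self.gap_mask is None:
            self.gap_mask = ~np.isfinite(self.values)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != (N_STEPS,):
            raise ValueError("gap_mask length mismatch")
        self.values = np.where(self.gap_mask, np.nan, self.values)

    @property
    def window_start_doys(self) -> np.ndarray:
        return WINDOW_START_DOYS

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())


def _as_finite(name: str, value):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidObservationError(f"non-finite {name} reflectance")
    return arr


def compute_evi2(red, nir):
    """Two-band enhanced vegetation index, 2.5*(NIR-Red)/(NIR+2.4*Red+1)."""
    red = _as_finite("red", red)
    nir = _as_finite("nir", nir)
    return 2.5 * (nir - red) / (nir + 2.4 * red + 1.0)


def compute_ndvi(red, nir):
    """Normalized difference vegetation index, (NIR-Red)/(NIR+Red)."""
    red = _as_finite("red", red)
    nir = _as_finite("nir", nir)
    denom = nir + red
    if np.any(denom == 0):
        raise InvalidObservationError("zero NDVI denominator")
    return (nir - red) / denom


def compute_ndwi(nir, swir1):
    """Normalized difference water index, (NIR-SWIR1)/(NIR+SWIR1)."""
    nir = _as_finite("nir", nir)
    swir1 = _as_finite("swir1", swir1)
    denom = nir + swir1
    if np.any(denom == 0):
        raise InvalidObservationError("zero NDWI denominator")
    return (nir - swir1) / denom


def composite_3day(
    observations: pd.DataFrame, year: int
) -> tuple[EVI2Series, np.ndarray, np.ndarray]:
    """Build the 122-step EVI2 composite plus parallel NDVI and NDWI series.

    Parameters
    ----------
    observations
        Long-format table with columns ``date`` (parsable to datetime),
        ``red``, ``nir``, ``green``, ``swir1`` and ``qa`` (one of
        ``QA_CLASSES``).  Observations outside ``year`` are ignored.
    year
        Target calendar year anchoring the 122-window grid.

    Each step is the mean of the high-quality observations falling in its
    window (a single observation is taken as-is); steps without any
    high-quality observation are gaps.  An empty input yields an all-gap
    series.
    """
    evi2_sum = np.zeros(N_STEPS)
    ndvi_sum = np.zeros(N_STEPS)
    ndwi_sum = np.zeros(N_STEPS)
    count = np.zeros(N_STEPS, dtype=int)

    if len(observations):
        obs = observations.copy()
        bad_qa = set(obs["qa"]) - QA_CLASSES
        if bad_qa:
            raise ValueError(f"unknown qa classes: {sorted(bad_qa)}")
        dates = pd.to_datetime(obs["date"])
        obs = obs[(dates.dt.year == year) & (obs["qa"] == QA_HIGH)]
        if len(obs):
            doys = pd.to_datetime(obs["date"]).dt.dayofyear.to_numpy()
            idx = window_index(doys)
            evi2 = compute_evi2(obs["red"].to_numpy(), obs["nir"].to_numpy())
            ndvi = compute_ndvi(obs["red"].to_numpy(), obs["nir"].to_numpy())
            ndwi = compute_ndwi(obs["nir"].to_numpy(), obs["swir1"].to_numpy())
            np.add.at(evi2_sum, idx, evi2)
            np.add.at(ndvi_sum, idx, ndvi)
            np.add.at(ndwi_sum, idx, ndwi)
            np.add.at(count, idx, 1)

    with np.errstate(invalid="ignore"):
        evi2_series = np.where(count > 0, evi2_sum / np.maximum(count, 1), np.nan)
        ndvi_series = np.where(count > 0, ndvi_sum / np.maximum(count, 1), np.nan)
        ndwi_series = np.where(count > 0, ndwi_sum / np.maximum(count, 1), np.nan)

    return EVI2Series(year, evi2_series), ndvi_series, ndwi_series


def _spike_mask(values: np.ndarray, gap: np.ndarray, spike_rule: str) -> np.ndarray:
    """Rule (ii): EVI2 above 110% of its +-1-month non-gap neighborhood.

    With ``spike_rule='all'`` the step must exceed 110% of every available
    non-gap value on both sides; with ``'any'`` it must exceed 110% of at
    least one value on each side.  The rule is skipped when either side has
    no non-gap value.
    """
    out = np.zeros(values.size, dtype=bool)
    for i in np.nonzero(~gap)[0]:
        lo = max(0, i - SPIKE_NEIGHBORHOOD_STEPS)
        prev = values[lo:i][~gap[lo:i]]
        nxt_slice = slice(i + 1, i + 1 + SPIKE_NEIGHBORHOOD_STEPS)
        nxt = values[nxt_slice][~gap[nxt_slice]]
        if prev.size == 0 or nxt.size == 0:
            continue
        if spike_rule == "all":
            out[i] = values[i] > 1.1 * max(prev.max(), nxt.max())
        else:
            out[i] = values[i] > 1.1 * prev.min() and values[i] > 1.1 * nxt.min()
    return out


def apply_fill_rules(
    evi2: EVI2Series,
    ndvi: np.ndarray,
    ndwi: np.ndarray,
    spike_rule: str = "all",
) -> EVI2Series:
    """Screen a composite EVI2 series, converting contaminated steps to gaps.

    Applies the three gap rules described in the module docstring.  Rule (ii)
    is iterated to a fixed point (removing a spike can expose another), which
    makes the whole operation idempotent.  Original gaps are preserved.
    """
    if spike_rule not in ("all", "any"):
        raise ValueError("spike_rule must be 'all' or 'any'")
    ndvi = np.asarray(ndvi, dtype=float)
    ndwi = np.asarray(ndwi, dtype=float)
    if ndvi.shape != (N_STEPS,) or ndwi.shape != (N_STEPS,):
        raise ValueError("ndvi/ndwi must share the 122-step grid")

    values = evi2.values.copy()
    gap = evi2.gap_mask.copy()

    with np.errstate(invalid="ignore"):
        rule_i = ~gap & (values > 0.9 * ndvi)
        rule_iii = ~gap & (ndvi < ndwi)
    gap |= rule_i | rule_iii

    for _ in range(N_STEPS):
        spikes = _spike_mask(values, gap, spike_rule)
        if not spikes.any():
            break
        gap |= spikes

    return EVI2Series(evi2.year, np.where(gap, np.nan, values), gap)
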