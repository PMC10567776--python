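"""Gridded green-chromatic-coordinate (GCC) extraction from canopy imagery.

A fixed camera's RGB frames are divided into a 10 x 10 grid of near-equal
rectangular blocks; each block yields its own GCC time series
(GCC = G / (R + G + B) of the block channel means).  Half-hourly values are
aggregated to the annual 122-step grid by taking the 90th percentile within
each 3-day window, which suppresses weather and exposure noise and makes the
series temporally consistent with the satellite EVI2 composite.  The
resulting per-grid series from any number of cameras form a donor collection
for shape matching, indexed by (site_id, grid_index) and used irrespective
of camera location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timegrid import N_STEPS, window_index

GRID_SHAPE = (10, 10)

#: Local hours of imagery ingested (inclusive start, exclusive end).
DAY_HOURS = (9, 17)


class UndefinedGCCError(ValueError):
    """Raised for an all-black pixel block (zero channel sum)."""


@dataclass(frozen=True)
class GCCSeries:
    """One camera grid cell's annual 3-day 90th-percentile GCC composite."""

    site_id: str
    grid_index: tuple[int, int]
    year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (N_STEPS,):
            raise ValueError(f"GCCSeries needs exactly {N_STEPS} steps")

    @property
    def donor_id(self) -> tuple[str, tuple[int, int]]:
        return (self.site_id, self.grid_index)


def compute_gcc(block: np.ndarray) -> float:
    """GCC of an RGB pixel block: mean(G) / (mean(R)+mean(G)+mean(B))."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 3 or block.shape[-1] != 3 or block[..., 0].size == 0:
        raise ValueError("block must be a non-empty HxWx3 array")
    means = block.reshape(-1, 3).mean(axis=0)
    total = means.sum()
    if total <= 0:
        raise UndefinedGCCError("all-black block: GCC undefined")
    return float(means[1] / total)


def partition_grid(image: np.ndarray) -> list[np.ndarray]:
    """Split an HxWx3 image into 100 contiguous blocks (row-major order).

    Blocks are of near-equal size; remainder rows/columns are absorbed by the
    last block row/column so every pixel belongs to exactly one block.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    h, w = image.shape[:2]
    nr, nc = GRID_SHAPE
    if h < nr or w < nc:
        raise ValueError(f"image must be at least {nr}x{nc} pixels")
    row_edges = [i * (h // nr) for i in range(nr)] + [h]
    col_edges = [j * (w // nc) for j in range(nc)] + [w]
    return [
        image[row_edges[r] : row_edges[r + 1], col_edges[c] : col_edges[c + 1]]
        for r in range(nr)
        for c in range(nc)
    ]


def composite_gcc_3day(
    half_hourly: pd.DataFrame,
    year: int,
    site_id: str = "",
    grid_index: tuple[int, int] = (0, 0),
    day_hours: tuple[int, int] = DAY_HOURS,
) -> GCCSeries:
    """Aggregate timestamped GCC values to a gap-free 122-step composite.

    Parameters
    ----------
    half_hourly
        Table with columns ``timestamp`` and ``gcc``.  Only values whose
        local hour falls within ``day_hours`` and whose year matches are
        used.
    year
        Target calendar year.

    Each window takes the 90th percentile of its values (plotting-position
    convention ``(n+1)p``, linear between order statistics).  Windows without
    imagery are filled by linear interpolation between neighboring steps
    (end gaps take the nearest composite value), so the output is gap-free.
    """
    ts = pd.to_datetime(half_hourly["timestamp"])
    keep = (
        (ts.dt.year == year)
        & (ts.dt.hour >= day_hours[0])
        & (ts.dt.hour < day_hours[1])
    )
    doys = ts[keep].dt.dayofyear.to_numpy()
    vals = half_hourly.loc[keep, "gcc"].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"no usable GCC values in {year}")

    idx = window_index(doys)
    out = np.full(N_STEPS, np.nan)
    for k in np.unique(idx):
        out[k] = np.percentile(vals[idx == k], 90, method="weibull")

    filled = np.nonzero(np.isfinite(out))[0]
    if filled.size < N_STEPS:
        out = np.interp(np.arange(N_STEPS), filled, out[filled])
    return GCCSeries(site_id, grid_index, year, out)


class GCCCollection:
    """Flat, order-preserving collection of donor GCC series.

    Donors keep their (site_id, grid_index) provenance but are otherwise
    treated identically — the shape matcher ignores where a camera stands.
    Duplicate series are admitted unchanged.
    """

    def __init__(self, series: list[GCCSeries]):
        if not series:
            raise ValueError("empty donor collection")
        self.series = list(series)

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, i: int) -> GCCSeries:
        return self.series[i]

    def lookup(self, donor_id: tuple[str, tuple[int, int]]) -> GCCSeries:
        for s in self.series:
            if s.donor_id == donor_id:
                return s
        raise KeyError(donor_id)


def build_gcc_collection(sites: list[list[GCCSeries]] | list[GCCSeries]) -> GCCCollection:
    """Flatten per-site series lists into one donor collection."""
    flat: list[GCCSeries] = []
    for item in sites:
        if isinstance(item, GCCSeries):
            flat.append(item)
        else:
            flat.extend(item)
    return GCCCollection(flat)
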