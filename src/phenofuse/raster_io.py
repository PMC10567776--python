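"""Reading and writing the published two-file raster product layout.

Each region-year yields two multiband int16 TIFFs:

* ``HLS-PhenoCam.AYYYY.SiteID.HLStile.LSP-EVI2.tif`` — 122 bands, the 3-day
  gap-free EVI2 series scaled by 10000 (valid codes -10000..10000);
* ``HLS-PhenoCam.AYYYY.SiteID.HLStile.LSP-Date.tif`` — 12 bands, the four
  transition dates (greenup, maturity, senescence, dormancy) for cycle
  slots 1-3, in day-of-year units.

Both use 32767 as the nodata code.  A JSON ImageDescription tag records the
grid metadata (synthetic products use a nominal UTM-like 30 m grid).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

NODATA = 32767
EVI2_SCALE = 10000
EVI2_CODE_MIN, EVI2_CODE_MAX = -10000, 10000

#: Nominal grid for synthetic products: 30 m pixels, arbitrary UTM-like origin.
DEFAULT_GRID_META = {"pixel_size_m": 30.0, "origin": [500000.0, 4700000.0]}


def product_filename(year: int, site_id: str, tile: str, kind: str) -> str:
    if kind not in ("LSP-EVI2", "LSP-Date"):
        raise ValueError("kind must be 'LSP-EVI2' or 'LSP-Date'")
    return f"HLS-PhenoCam.A{year}.{site_id}.{tile}.{kind}.tif"


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def encode_evi2(values: np.ndarray) -> np.ndarray:
    """EVI2 -> int16 codes (x10000, half-away-from-zero; NaN -> nodata)."""
    v = np.asarray(values, dtype=float)
    codes = _round_half_away(v * EVI2_SCALE)
    out_of_range = np.isfinite(codes) & (
        (codes < EVI2_CODE_MIN) | (codes > EVI2_CODE_MAX)
    )
    if out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} EVI2 code(s) outside "
            f"[{EVI2_CODE_MIN}, {EVI2_CODE_MAX}]; clipped",
            stacklevel=2,
        )
        codes = np.clip(codes, EVI2_CODE_MIN, EVI2_CODE_MAX)
    codes = np.where(np.isfinite(codes), codes, NODATA)
    return codes.astype(np.int16)


def decode_evi2(codes: np.ndarray) -> np.ndarray:
    """int16 codes -> EVI2 floats (nodata -> NaN)."""
    codes = np.asarray(codes)
    return np.where(codes == NODATA, np.nan, codes / EVI2_SCALE)


def encode_dates(dates: np.ndarray) -> np.ndarray:
    """DOY floats -> int16 (rounded; NaN -> nodata)."""
    d = np.asarray(dates, dtype=float)
    codes = np.where(np.isfinite(d), _round_half_away(d), NODATA)
    return codes.astype(np.int16)


def decode_dates(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    return np.where(codes == NODATA, np.nan, codes.astype(float))


def _write(path: Path, bands: np.ndarray, meta: dict) -> Path:
    description = json.dumps(meta)
    tifffile.imwrite(
        path,
        bands,
        dtype=np.int16,
        photometric="minisblack",
        description=description,
        metadata=None,
    )
    return path


def write_lsp_evi2(
    series_grid: np.ndarray,
    year: int,
    site_id: str,
    tile: str,
    outdir: str | Path,
    grid_meta: dict | None = None,
) -> Path:
    """Write the 122-band EVI2 product for a region.

    ``series_grid`` is (122, H, W) float EVI2 (NaN = missing) or int16 codes.
    """
    series_grid = np.asarray(series_grid)
    if series_grid.ndim != 3 or series_grid.shape[0] != 122:
        raise ValueError("series_grid must be (122, H, W)")
    codes = (
        series_grid.astype(np.int16)
        if np.issubdtype(series_grid.dtype, np.integer)
        else encode_evi2(series_grid)
    )
    meta = {
        "product": "LSP-EVI2",
        "year": year,
        "site_id": site_id,
        "tile": tile,
        "nodata": NODATA,
        "scale": 1.0 / EVI2_SCALE,
        **(grid_meta or DEFAULT_GRID_META),
    }
    path = Path(outdir) / product_filename(year, site_id, tile, "LSP-EVI2")
    return _write(path, codes, meta)


def write_lsp_date(
    dates_grid: np.ndarray,
    year: int,
    site_id: str,
    tile: str,
    outdir: str | Path,
    grid_meta: dict | None = None,
) -> Path:
    """Write the 12-band transition-date product ((4 onsets) x (3 slots))."""
    dates_grid = np.asarray(dates_grid)
    if dates_grid.ndim != 3 or dates_grid.shape[0] != 12:
        raise ValueError("dates_grid must be (12, H, W)")
    codes = (
        dates_grid.astype(np.int16)
        if np.issubdtype(dates_grid.dtype, np.integer)
        else encode_dates(dates_grid)
    )
    meta = {
        "product": "LSP-Date",
        "year": year,
        "site_id": site_id,
        "tile": tile,
        "nodata": NODATA,
        "unit": "day of year",
        **(grid_meta or DEFAULT_GRID_META),
    }
    path = Path(outdir) / product_filename(year, site_id, tile, "LSP-Date")
    return _write(path, codes, meta)


def read_product(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a product file back as (bands, metadata)."""
    with tifffile.TiffFile(path) as tif:
        bands = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    if bands.ndim == 2:
        bands = bands[None]
    return bands, meta
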