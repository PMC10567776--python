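"""The annual 3-day compositing grid.

Every time series in this package lives on a fixed grid of 122 three-day
windows per calendar year.  Window ``k`` (0-based) covers days of year
``3k+1 .. 3k+3``; the final window additionally absorbs day 365 (and 366 in
leap years), so the grid always has exactly 122 steps from January 1 to
December 31.
"""

from __future__ import annotations

import calendar

import numpy as np

#: Number of 3-day windows per year.
N_STEPS = 122

#: First day of year of each window (1, 4, ..., 364).
WINDOW_START_DOYS = np.arange(1, 365, 3)

#: Nominal centre day of year of each window (2, 5, ..., 365).
WINDOW_CENTER_DOYS = WINDOW_START_DOYS + 1

assert WINDOW_START_DOYS.size == N_STEPS


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def window_index(doy: np.ndarray | int) -> np.ndarray | int:
    """Map day of year (1-based) to its 3-day window index (0..121).

    Days 365/366 fall into the last window.
    """
    idx = (np.asarray(doy) - 1) // 3
    return np.minimum(idx, N_STEPS - 1)
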