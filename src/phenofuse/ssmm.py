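"""Spatiotemporal shape-matching model (SSMM) for EVI2 gap filling.

A gappy satellite EVI2 series is compared against every donor camera GCC
series under a family of shape transformations

    EVI2_hat(t) = a * GCC(T) + b,      T = lambda * (t + beta)

where ``lambda`` (0.90..1.10, step 0.05) stretches the growing-season length,
``beta`` (-30..+30 days, step 3) shifts the season, and ``(a, b)`` rescale
greenness amplitude.  For each (donor, lambda, beta) the linear scaling is
estimated by geometric mean functional regression (GMFR, also known as
reduced major axis) over the non-gap steps, and the candidate is scored by
the mean squared deviation (MSD) between observed and predicted EVI2 plus
the Pearson correlation R and its p-value.  The best qualifying candidate
(R > 0.6, p <= 0.02; smallest MSD) donates its scaled, time-warped GCC values
to fill every gap.  If no candidate qualifies the pixel is left unfused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .composite import EVI2Series
from .phenocam import GCCCollection, GCCSeries
from .timegrid import WINDOW_CENTER_DOYS

LAMBDA_GRID = (0.90, 0.95, 1.00, 1.05, 1.10)
BETA_GRID = tuple(range(-30, 31, 3))

#: Minimum number of overlapping non-gap pairs for a valid candidate fit.
MIN_OVERLAP = 8

R_MIN = 0.6
P_MAX = 0.02


class InvalidCandidateError(ValueError):
    """Raised when a candidate has too few pairs or zero variance."""


@dataclass(frozen=True)
class ScalingFactors:
    """The four SSMM scaling factors."""

    a: float  # slope, EVI2 per GCC
    b: float  # intercept, EVI2
    lam: float  # growing-season-length ratio
    beta: float  # seasonal shift, days


@dataclass(frozen=True)
class MatchCandidate:
    donor_id: tuple[str, tuple[int, int]]
    factors: ScalingFactors
    msd: float
    r: float
    p: float
    n_pairs: int


def warp_time(
    gcc: GCCSeries, lam: float, beta: float, t: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a donor GCC series onto the EVI2 time grid under (lam, beta).

    Returns ``(warped, valid)`` where ``warped[i]`` is the donor value
    linearly interpolated at ``T = lam * (t_i + beta)`` and ``valid[i]`` is
    False where T falls outside the donor's sampled domain (such steps are
    excluded from comparison and filling, never extrapolated).
    """
    if t is None:
        t = WINDOW_CENTER_DOYS.astype(float)
    T = lam * (np.asarray(t, dtype=float) + beta)
    donor_t = WINDOW_CENTER_DOYS.astype(float)
    valid = (T >= donor_t[0]) & (T <= donor_t[-1])
    warped = np.interp(T, donor_t, gcc.values)
    return np.where(valid, warped, np.nan), valid


def gmfr_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Geometric mean functional regression (reduced major axis) of y on x.

    Slope magnitude is sd(y)/sd(x) with the sign of the correlation;
    intercept passes the line through the means.  Symmetric in x and y:
    slope(x->y) * slope(y->x) = 1 for the same correlation sign.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < MIN_OVERLAP:
        raise InvalidCandidateError(f"need >= {MIN_OVERLAP} pairs, got {x.size}")
    sx = x.std()
    sy = y.std()
    # near-zero covers exactly-constant donors resampled through interp,
    # which picks up ~1e-16 rounding jitter
    if sx <= 1e-12 or sy <= 1e-12:
        raise InvalidCandidateError("zero variance in x or y")
    r = np.corrcoef(x, y)[0, 1]
    sign = 1.0 if r >= 0 else -1.0
    a = sign * sy / sx
    b = y.mean() - a * x.mean()
    return float(a), float(b)


def evaluate_match(
    evi2: EVI2Series, gcc: GCCSeries, lam: float, beta: float
) -> MatchCandidate:
    """Score one (donor, lambda, beta) candidate against an EVI2 series.

    Fits (a, b) by GMFR over the non-gap overlap, predicts EVI2 from the
    warped donor, and returns MSD, Pearson R and its two-sided p-value
    (t-distribution with n-2 degrees of freedom).
    """
    warped, valid = warp_time(gcc, lam, beta)
    mask = valid & ~evi2.gap_mask
    x = warped[mask]
    y = evi2.values[mask]
    a, b = gmfr_fit(x, y)
    pred = a * x + b
    msd = float(np.mean((y - pred) ** 2))
    res = stats.pearsonr(x, y)
    return MatchCandidate(
        donor_id=gcc.donor_id,
        factors=ScalingFactors(a, b, lam, beta),
        msd=msd,
        r=float(res.statistic),
        p=float(res.pvalue),
        n_pairs=int(x.size),
    )


def select_best_match(
    evi2: EVI2Series,
    collection: GCCCollection,
    r_min: float = R_MIN,
    p_max: float = P_MAX,
) -> MatchCandidate | None:
    """Exhaustively search donors x lambda x beta for the best qualifying fit.

    Candidates must satisfy R > ``r_min`` and p <= ``p_max``; among those the
    smallest MSD wins (ties: highest R, then lowest donor position in the
    collection sorted by donor id).  Returns None when nothing qualifies —
    the fusion is then not performed.
    """
    order = sorted(range(len(collection)), key=lambda i: collection[i].donor_id)
    best: MatchCandidate | None = None
    best_key: tuple | None = None
    for rank, i in enumerate(order):
        gcc = collection[i]
        for lam in LAMBDA_GRID:
            for beta in BETA_GRID:
                try:
                    cand = evaluate_match(evi2, gcc, lam, beta)
                except InvalidCandidateError:
                    continue
                if not (cand.r > r_min and cand.p <= p_max):
                    continue
                key = (cand.msd, -cand.r, rank)
                if best_key is None or key < best_key:
                    best, best_key = cand, key
    return best


def fuse_series(
    evi2: EVI2Series, best: MatchCandidate, collection: GCCCollection
) -> EVI2Series:
    """Fill every gap with the best donor's scaled, warped prediction.

    Observed (non-gap) values are never touched.  A gap where the warped
    donor is undefined (T outside its domain) remains a gap and stays marked
    in the output's ``gap_mask``.
    """
    gcc = collection.lookup(best.donor_id)
    f = best.factors
    warped, valid = warp_time(gcc, f.lam, f.beta)
    values = evi2.values.copy()
    fill = evi2.gap_mask & valid
    values[fill] = f.a * warped[fill] + f.b
    remaining = evi2.gap_mask & ~valid
    return EVI2Series(evi2.year, np.where(remaining, np.nan, values), remaining)


def match_report_row(
    pixel_id: str, best: MatchCandidate | None
) -> dict:
    """One row of the fusion report CSV for a pixel."""
    if best is None:
        return {
            "pixel_id": pixel_id,
            "site_id": "",
            "grid_row": -1,
            "grid_col": -1,
            "a": np.nan,
            "b": np.nan,
            "lambda": np.nan,
            "beta": np.nan,
            "msd": np.nan,
            "r": np.nan,
            "p": np.nan,
            "n_pairs": 0,
            "status": "no-match",
        }
    site, (row, col) = best.donor_id
    f = best.factors
    return {
        "pixel_id": pixel_id,
        "site_id": site,
        "grid_row": row,
        "grid_col": col,
        "a": f.a,
        "b": f.b,
        "lambda": f.lam,
        "beta": f.beta,
        "msd": best.msd,
        "r": best.r,
        "p": best.p,
        "n_pairs": best.n_pairs,
        "status": "fused",
    }
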