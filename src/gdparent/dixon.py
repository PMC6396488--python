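"""Dixon ratio test for a single extreme value, with Monte-Carlo p-values.

The Dixon family of statistics measures the gap between an extreme value
and its neighbours relative to the sample range, with the variant chosen by
sample size (the larger-n variants ignore additional points at each end to
resist masking):

    r10 = (x(2) - x(1)) / (x(n)   - x(1))   3 <= n <= 7
    r11 = (x(2) - x(1)) / (x(n-1) - x(1))   8 <= n <= 10
    r21 = (x(3) - x(1)) / (x(n-1) - x(1))   11 <= n <= 13
    r22 = (x(3) - x(1)) / (x(n-2) - x(1))   n >= 14

(written for a suspected minimum; the maximum case is the mirror image).
Classical critical-value tables stop near n = 30, so p-values here come
from a seeded Monte-Carlo simulation of the null — standard normal samples
of the same size — which supports arbitrary n and is exactly reproducible.
"""

from __future__ import annotations

import numpy as np

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _variant(n: int) -> str:
    if n <= 7:
        return "r10"
    if n <= 10:
        return "r11"
    if n <= 13:
        return "r21"
    return "r22"


def _min_ratio(sorted_rows: np.ndarray) -> np.ndarray:
    """Dixon ratio for the minimum on row-sorted data (2-D or 1-D)."""
    x = np.atleast_2d(sorted_rows)
    n = x.shape[1]
    variant = _variant(n)
    lo = x[:, 0]
    if variant == "r10":
        num, den = x[:, 1] - lo, x[:, n - 1] - lo
    elif variant == "r11":
        num, den = x[:, 1] - lo, x[:, n - 2] - lo
    elif variant == "r21":
        num, den = x[:, 2] - lo, x[:, n - 2] - lo
    else:
        num, den = x[:, 2] - lo, x[:, n - 3] - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r


def dixon_ratio(sample: np.ndarray, candidate_position: str) -> float:
    """Observed Dixon ratio for the extreme at ``candidate_position``."""
    x = np.sort(np.asarray(sample, dtype=np.float64))
    if x.size < 3:
        raise ValueError(f"Dixon test requires n >= 3, got n = {x.size}")
    if candidate_position == "min":
        return float(_min_ratio(x)[0])
    if candidate_position == "max":
        return float(_min_ratio(np.sort(-x))[0])
    raise ValueError(f"candidate_position must be 'min' or 'max', got {candidate_position!r}")


def _null_ratios(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null distribution of the size-n Dixon ratio."""
    key = (n, n_mc, seed)
    cached = _NULL_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_mc, n))
    draws.sort(axis=1)
    ratios = np.sort(_min_ratio(draws))
    if len(_NULL_CACHE) > 64:
        _NULL_CACHE.clear()
    _NULL_CACHE[key] = ratios
    return ratios


def dixon_test(
    sample: np.ndarray,
    candidate_position: str = "min",
    *,
    seed: int = 0,
    n_mc: int = 10_000,
) -> float:
    """One-sided Monte-Carlo p-value for the extreme value being an outlier.

    The null distribution is the Dixon ratio of i.i.d. standard normal
    samples of the same size (the statistic is location/scale free, so the
    normal parameters are immaterial).  A constant sample returns p = 1.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"Dixon test requires n >= 3, got n = {x.size}")
    if np.ptp(x) == 0:
        return 1.0
    r_obs = dixon_ratio(x, candidate_position)
    null = _null_ratios(int(x.size), n_mc, seed)
    n_ge = null.size - np.searchsorted(null, r_obs, side="left")
    return float((1 + n_ge) / (n_mc + 1))
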