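import numpy as np
import pytest

from thermolag.growth import CurveMeta, GrowthCurve


@pytest.fixture
def exp_curve() -> GrowthCurve:
    """Pure exponential: od = 0.01 * exp(0.2 t) on a 0.25 h grid over 20 h."""
    t = np.arange(0.0, 20.0 + 1e-9, 0.25)
    return GrowthCurve(time_h=t, od=0.01 * np.exp(0.2 * t), meta=CurveMeta(well="A1"))


def brute_force_max_slope(
    t: np.ndarray,
    y: np.ndarray,
    min_window_h: float = 3.0,
    min_elapsed_h: float = 6.0,
    min_r2: float = 0.95,
):
    """Independent window enumeration + polyfit oracle for the max-slope fit.

    Enumerates every admissible window, fits it with polyfit, and selects
    the steepest among windows whose R-squared clears ``min_r2`` (falling
    back to all windows if none qualify).  Iterating in (start, end) order
    and keeping strict improvements reproduces the earliest-start /
    shortest-span tie-break.  Returns (slope, start, end, intercept).
    """
    windows = []
    n = len(t)
    for i in range(n):
        for j in range(i + 1, n):
            if t[j] - t[i] < min_window_h - 1e-12:
                continue
            if t[j] < t[0] + min_elapsed_h - 1e-12:
                continue
            tt, yy = t[i : j + 1], y[i : j + 1]
            slope, intercept = np.polyfit(tt, yy, 1)
            sst = ((yy - yy.mean()) ** 2).sum()
            if sst > 0:
                resid = yy - (intercept + slope * tt)
                r2 = 1.0 - (resid**2).sum() / sst
            else:
                r2 = 1.0
            windows.append((slope, t[i], t[j], intercept, r2))
    pool = [w for w in windows if w[4] >= min_r2] or windows
    best = None
    for w in pool:
        if best is None or w[0] > best[0] + 1e-12:
            best = w
    return best[:4]
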