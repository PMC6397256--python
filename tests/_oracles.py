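"""Independently coded brute-force oracles used to cross-check the package.

Everything here is written from the definitions with plain loops and
elementary arithmetic, deliberately avoiding the package's code paths (and,
where reasonable, its library calls), so that agreement is evidence and not
tautology.
"""

import math
from itertools import product


# ---------------------------------------------------------------------------
# Detrending / standardized anomaly
# ---------------------------------------------------------------------------


def ols_fit(xs, ys):
    """Least-squares line via the closed-form normal equations."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    return slope, my - slope * mx


def detrend_linear_oracle(years, values):
    slope, intercept = ols_fit(list(years), list(values))
    return [v - (intercept + slope * y) for y, v in zip(years, values)]


def detrend_constant_oracle(values):
    m = sum(values) / len(values)
    return [v - m for v in values]


def detrend_moving_average_oracle(values, window):
    n = len(values)
    hmax = (window - 1) // 2
    out = []
    for i in range(n):
        h = min(hmax, i, n - 1 - i)
        win = values[i - h : i + h + 1]
        out.append(values[i] - sum(win) / len(win))
    return out


def detrend_oracle(years, values, method, window=7):
    if method == "linear":
        return detrend_linear_oracle(years, values)
    if method == "constant":
        return detrend_constant_oracle(list(values))
    return detrend_moving_average_oracle(list(values), window)


def sample_sd(values):
    n = len(values)
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def standardized_anomaly_oracle(
    years, values, event_year, method, window=7, sigma_years=None
):
    years = list(years)
    values = list(values)
    resid = detrend_oracle(years, values, method, window)
    e = years.index(event_year)
    lo, hi = sigma_years if sigma_years else (years[0], years[-1])
    pool = [r for y, r in zip(years, resid) if lo <= y <= hi and y != event_year]
    return resid[e] / sample_sd(pool)


# ---------------------------------------------------------------------------
# Mortality (scalar day loop)
# ---------------------------------------------------------------------------


def tetens_oracle(t):
    return 6.1078 * math.pow(10.0, 7.5 * t / (t + 237.3))


def dew_point_oracle(t_mean, rh):
    e = rh / 100.0 * tetens_oracle(t_mean)
    x = math.log10(e / 6.1078)
    return 237.3 * x / (7.5 - x)


def at_max_oracle(t_mean, t_max, rh):
    td = dew_point_oracle(t_mean, rh)
    return -2.653 + 0.994 * t_max + 0.0153 * td * td


def attributable_deaths_oracle(days, threshold, b, d_obs, period_mask):
    """days: list of (t_mean, t_max, rh); trailing 3-day mean, then sum.

    ``period_mask`` selects which days belong to the analysis period (the
    smoothing still sees all days).
    """
    ats = [at_max_oracle(*d) for d in days]
    total = 0.0
    b = max(b, 0.0)
    for i, in_period in enumerate(period_mask):
        if not in_period:
            continue
        window = ats[max(0, i - 2) : i + 1]
        at3 = sum(window) / len(window)
        delta = at3 - threshold
        if delta > 0:
            total += d_obs * (1.0 - math.exp(-b * delta))
    return total


# ---------------------------------------------------------------------------
# Ensemble statistics / classification
# ---------------------------------------------------------------------------


def quantile_oracle(values, p):
    """Linear interpolation between order statistics at position (n-1)p."""
    xs = sorted(values)
    pos = (len(xs) - 1) * p
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return xs[lo] + (xs[hi] - xs[lo]) * (pos - lo)


def classify_oracle(observed, simulated, threshold, sign):
    """Rule enumeration straight from the category definitions."""
    harm_obs = sign * observed
    harms = [sign * v for v in simulated]
    n = len(harms)
    severe = harm_obs > threshold
    if severe:
        n_under = len([h for h in harms if h < harm_obs])
        if n_under == n:
            return "underestimated_by_all"
        if n_under / n >= 0.75:
            return "underestimated_by_75plus"
        return "captured"
    n_beyond = len([h for h in harms if h > threshold])
    if n_beyond / n >= 0.75:
        return "false_alarm"
    return "unremarkable"


def all_sign_magnitude_patterns(grid, max_models):
    """Every (observed, simulated-tuple) combination over a value grid."""
    for obs in grid:
        for m in range(1, max_models + 1):
            for sims in product(grid, repeat=m):
                yield obs, sims
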