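"""Model II major-axis (MA) regression against a 1:1 null.

Both variables (an index for the current and the projected assemblage)
are measured in the same units and both carry error, so an ordinary
least-squares fit of y on x would bias the slope toward zero. The major
axis is the first principal axis of the (x, y) scatter: the line
minimizing perpendicular distances. Departure from the identity line
(slope 1, intercept 0) is read off the 95% confidence intervals, and the
strength of association is tested by permutation of y against x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class MAFit:
    slope: float
    intercept: float
    r: float
    n: int
    slope_ci: tuple[float, float] | None = None
    intercept_ci: tuple[float, float] | None = None
    slope_ci_wraps: bool = False
    p_perm: float | None = None
    n_perm: int | None = None

    def slope_in_ci(self, value: float) -> bool:
        """Whether ``value`` lies in the slope CI.

        When the angle interval crosses the vertical the CI wraps through
        infinity: it is (-inf, hi] ∪ [lo, +inf) with lo > hi.
        """
        if self.slope_ci is None:
            raise ValueError("confidence intervals not computed")
        lo, hi = self.slope_ci
        if self.slope_ci_wraps:
            return value >= lo or value <= hi
        return lo <= value <= hi

    @property
    def departs_from_identity(self) -> bool:
        """True when the 95% CIs exclude the 1:1 line."""
        if self.slope_ci is None or self.intercept_ci is None:
            raise ValueError("confidence intervals not computed")
        int_excludes = not (self.intercept_ci[0] <= 0.0 <= self.intercept_ci[1])
        return (not self.slope_in_ci(1.0)) or int_excludes


def _moments(x: np.ndarray, y: np.ndarray):
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2) / (n - 1)
    syy = np.sum((y - y.mean()) ** 2) / (n - 1)
    sxy = np.sum((x - x.mean()) * (y - y.mean())) / (n - 1)
    return sxx, syy, sxy


def ma_fit(x, y) -> MAFit:
    """Major-axis slope, intercept and Pearson correlation.

    slope = (s_yy − s_xx + √((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy); the
    intercept passes the line through the bivariate mean. Undefined when
    either variable is constant or when s_xy = 0 with s_xx = s_yy (the
    scatter has no preferred axis).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx, syy, sxy = _moments(x, y)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("degenerate variance: a variable is constant")
    if sxy == 0.0:
        if np.isclose(sxx, syy):
            raise ValueError("MA slope undefined: isotropic scatter")
        # principal axis aligns with the higher-variance coordinate
        slope = 0.0 if sxx > syy else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()
    r = sxy / np.sqrt(sxx * syy)
    return MAFit(slope=float(slope), intercept=float(intercept), r=float(r), n=n)


def ma_confidence(x, y, fit: MAFit, alpha: float = 0.05) -> MAFit:
    """95% (or 1−alpha) CIs for the MA slope and intercept.

    The slope interval is the classical angle bound: with λ1 ≥ λ2 the
    eigenvalues of the covariance matrix, H = t²_{α/2,n−2} /
    ((λ1/λ2 + λ2/λ1 − 2)(n − 2)); the limits are tan(atan(b) ± atan(A))
    with A = √(H/(1−H)), i.e. (b ∓ A)/(1 ± bA). H ≥ 1 means the axis
    direction is unresolved and the interval is the whole line. The
    intercept interval is propagated through the sample means from the
    slope limits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = fit.n
    sxx, syy, sxy = _moments(x, y)
    cov = np.array([[sxx, sxy], [sxy, syy]])
    l2, l1 = np.sort(np.linalg.eigvalsh(cov))  # l1 >= l2 >= 0
    b = fit.slope
    if l2 <= 0 or np.isclose(l1, l2):
        # perfect fit: zero-width interval; isotropic handled in ma_fit
        if l2 <= 1e-300 * max(l1, 1.0):
            fit.slope_ci = (b, b)
            fit.intercept_ci = (fit.intercept, fit.intercept)
            return fit
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    h = t**2 / ((l1 / l2 + l2 / l1 - 2.0) * (n - 2))
    if h >= 1.0:
        fit.slope_ci = (-np.inf, np.inf)
        fit.intercept_ci = (-np.inf, np.inf)
        return fit
    a = np.sqrt(h / (1.0 - h))
    # rotate the fitted angle by ±atan(a)
    theta = np.arctan(b)
    phi = np.arctan(a)
    lo = np.tan(theta - phi)
    hi = np.tan(theta + phi)
    if abs(theta - phi) < np.pi / 2 > abs(theta + phi):
        fit.slope_ci = (float(lo), float(hi))
        fit.slope_ci_wraps = False
        ints = sorted([y.mean() - lo * x.mean(), y.mean() - hi * x.mean()])
        fit.intercept_ci = (float(ints[0]), float(ints[1]))
    else:
        # angle interval crosses the vertical: CI wraps through infinity
        fit.slope_ci = (float(lo), float(hi))  # lo > hi
        fit.slope_ci_wraps = True
        fit.intercept_ci = (-np.inf, np.inf)
    return fit


def permutation_test(
    x, y, n_perm: int = 999, seed: int | np.random.Generator = 0
) -> tuple[float, int]:
    """Two-tailed permutation p-value for the Pearson correlation.

    y is permuted against x ``n_perm`` times; p = (1 + #{|r_perm| ≥
    |r_obs|}) / (n_perm + 1), so the smallest attainable p is
    1/(n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations to permute")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        raise ValueError("degenerate variance: a variable is constant")
    r_obs = abs(np.sum(xc * yc) / denom)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(yc)
        r = abs(np.sum(xc * perm) / denom)
        if r >= r_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1), n_perm


def ma_regression(
    x, y, n_perm: int = 999, alpha: float = 0.05, seed: int = 0
) -> MAFit:
    """Full MA analysis: fit, CIs, and permutation test in one call."""
    fit = ma_fit(x, y)
    fit = ma_confidence(x, y, fit, alpha=alpha)
    fit.p_perm, fit.n_perm = permutation_test(x, y, n_perm=n_perm, seed=seed)
    return fit
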