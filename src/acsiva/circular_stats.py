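"""Circular statistics for niche-vector angles.

All angles are in degrees on the mathematical convention: 0° along the
positive x axis, increasing counterclockwise, reduced to [0, 360).

The module provides the mean vector (direction and resultant length),
dispersion measures, a von Mises concentration estimate, the Rayleigh and
Rao spacing uniformity tests, and a circular-linear correlation.  Undefined
quantities (direction of a zero resultant, concentration of a singleton,
Rao's test below the minimum sample size) are returned as ``None`` so that
report writers can print the conventional dash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import DomainError
from .rao_table import rao_bracket, rao_montecarlo_pvalue

__all__ = [
    "CircularSummary",
    "CircLinCorr",
    "RaoBracket",
    "circular_mean",
    "circular_dispersion",
    "vonmises_kappa",
    "rayleigh_test",
    "rao_spacing_statistic",
    "rao_spacing_test",
    "circ_linear_correlation",
    "summarize",
]

#: resultant lengths below this are treated as exactly zero (direction undefined)
_R_EPS = 1e-12


@dataclass(frozen=True)
class RaoBracket:
    """A bracketed p-value ``upper > P > lower`` from a critical-value table.

    ``lower`` is ``None`` for an open bottom bracket (``P < upper``) and
    ``upper`` is ``None`` for an open top bracket (``P > lower``).
    """

    lower: Optional[float]
    upper: Optional[float]

    def __contains__(self, p: float) -> bool:
        lo = 0.0 if self.lower is None else self.lower
        hi = 1.0 if self.upper is None else self.upper
        return lo <= p <= hi

    def __str__(self) -> str:
        if self.lower is None:
            return f"< {self.upper:.2f}"
        if self.upper is None:
            return f"> {self.lower:.2f}"
        return f"{self.upper:.2f} > P > {self.lower:.2f}"


@dataclass(frozen=True)
class CircularSummary:
    """Per-group circular statistics block (one summary-table row)."""

    n: int
    mu_deg: Optional[float]  # None iff r == 0
    r: float
    kappa: Optional[float]  # None for n == 1
    circ_variance: float
    circ_sd_deg: float  # inf at r == 0
    rayleigh_Z: float
    rayleigh_P: float
    rao_U: Optional[float]  # None for n < 4
    rao_P: Optional[RaoBracket]


@dataclass(frozen=True)
class CircLinCorr:
    """Circular-linear and ordinary linear correlation against a covariate."""

    n: int
    circ_R2: Optional[float]
    circ_P: Optional[float]
    lin_R2: Optional[float]
    lin_P: Optional[float]

    @property
    def defined(self) -> bool:
        return self.circ_R2 is not None


def _as_radians(angles_deg: Sequence[float]) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise DomainError("at least one angle is required")
    if not np.all(np.isfinite(a)):
        raise DomainError("angles must be finite")
    return np.deg2rad(a)


def circular_mean(angles_deg: Sequence[float]) -> Tuple[Optional[float], float]:
    """Mean vector of a set of angles.

    Returns ``(mu_deg, r)`` where ``mu_deg`` is the direction of the
    resultant in ``[0, 360)`` and ``r`` the mean resultant length in
    ``[0, 1]``.  ``mu_deg`` is ``None`` when ``r`` vanishes.
    """
    rad = _as_radians(angles_deg)
    c = float(np.cos(rad).sum())
    s = float(np.sin(rad).sum())
    n = rad.size
    r = min(math.hypot(c, s) / n, 1.0)
    if r < _R_EPS:
        return None, 0.0
    mu = math.degrees(math.atan2(s, c)) % 360.0
    if mu >= 360.0:  # guard the float fencepost at the wrap point
        mu = 0.0
    return mu, r


def circular_dispersion(r: float) -> Tuple[float, float]:
    """Circular variance ``1 - r`` and circular SD ``sqrt(-2 ln r)`` in degrees.

    The SD is infinite at ``r = 0``.
    """
    if not 0.0 <= r <= 1.0:
        raise DomainError(f"r must be in [0, 1], got {r}")
    variance = 1.0 - r
    if r == 0.0:
        return variance, math.inf
    sd = math.degrees(math.sqrt(max(-2.0 * math.log(r), 0.0)))
    return variance, sd


def vonmises_kappa(r: float, n: int) -> Optional[float]:
    """Von Mises concentration estimate with small-sample bias correction.

    Uses the piecewise maximum-likelihood approximation

    * ``r < 0.53``:            ``2r + r^3 + 5 r^5 / 6``
    * ``0.53 <= r < 0.85``:    ``-0.4 + 1.39 r + 0.43 / (1 - r)``
    * ``r >= 0.85``:           ``1 / (r^3 - 4 r^2 + 3 r)``

    followed, for ``n <= 15``, by the bias correction
    ``max(k - 2/(n k), 0)`` when ``k < 2`` and ``k (n-1)^3 / (n^3 + n)``
    otherwise.  Returns ``None`` for ``n == 1`` (undefined) and ``inf`` at
    ``r == 1`` with ``n > 1``.
    """
    if not 0.0 <= r <= 1.0:
        raise DomainError(f"r must be in [0, 1], got {r}")
    if n < 1:
        raise DomainError("n must be >= 1")
    if n == 1:
        return None
    if r < 0.53:
        kappa = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        denom = r**3 - 4.0 * r**2 + 3.0 * r
        if denom <= 0.0:
            return math.inf
        kappa = 1.0 / denom
    if n <= 15:
        if kappa < 2.0:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0) if kappa > 0.0 else 0.0
        else:
            kappa = kappa * (n - 1) ** 3 / (n**3 + n)
    return kappa


def rayleigh_test(r: float, n: int) -> Tuple[float, float]:
    """Rayleigh uniformity test from the resultant length.

    ``Z = n r^2``; the p-value uses the second-order series

    ``P = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``

    clamped to ``[0, 1]``.
    """
    if not 0.0 <= r <= 1.0:
        raise DomainError(f"r must be in [0, 1], got {r}")
    if n < 1:
        raise DomainError("n must be >= 1")
    Z = n * r * r
    correction = (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    P = math.exp(-Z) * correction
    return Z, min(max(P, 0.0), 1.0)


def rao_spacing_statistic(angles_deg: Sequence[float]) -> float:
    """Rao's spacing statistic ``U = 1/2 sum |T_i - lambda|`` in degrees.

    ``T_i`` are the successive gaps of the sorted angles (including the
    wrap-around gap) and ``lambda = 360 / n``.  Duplicate angles (zero gaps)
    are permitted.
    """
    a = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    n = a.size
    if n < 2:
        raise DomainError("Rao's statistic needs at least 2 angles")
    gaps = np.diff(a, append=a[0] + 360.0)
    lam = 360.0 / n
    return float(0.5 * np.abs(gaps - lam).sum())


def rao_spacing_test(
    angles_deg: Sequence[float],
    *,
    monte_carlo: bool = False,
    reps: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Optional[float], Optional[Union[RaoBracket, float]]]:
    """Rao's spacing test of circular uniformity.

    For ``n < 4`` both return values are ``None`` (reported as a dash).  By
    default the p-value is a :class:`RaoBracket` read from a critical-value
    table; with ``monte_carlo=True`` a continuous p-value is estimated from
    ``reps`` seeded uniform resamples instead.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 4:
        return None, None
    U = rao_spacing_statistic(a)
    if monte_carlo:
        return U, rao_montecarlo_pvalue(U, n, reps=reps, rng=rng)
    lower, upper = rao_bracket(U, n)
    return U, RaoBracket(lower, upper)


def circ_linear_correlation(
    angles_deg: Sequence[float], x: Sequence[float]
) -> CircLinCorr:
    """Correlation of a circular variable (and of vector length) with ``x``.

    The circular-linear squared correlation is

    ``R2 = (r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2)``

    with ``r_xc = corr(x, cos θ)``, ``r_xs = corr(x, sin θ)`` and
    ``r_cs = corr(cos θ, sin θ)``; its p-value compares ``n R2`` to a
    chi-squared distribution with 2 degrees of freedom.  The linear slots
    are left ``None`` here; callers pair them with a magnitude variable via
    :func:`linear_correlation`.  Returns an all-``None`` (flagged) result
    when ``x`` has zero variance.
    """
    theta = _as_radians(angles_deg)
    xv = np.asarray(x, dtype=float)
    if xv.size != theta.size:
        raise DomainError("angles and x must be paired")
    n = xv.size
    if n < 4:
        raise DomainError("circular-linear correlation needs n >= 4")
    if np.ptp(xv) == 0.0 or not np.all(np.isfinite(xv)):
        return CircLinCorr(n=n, circ_R2=None, circ_P=None, lin_R2=None, lin_P=None)
    c, s = np.cos(theta), np.sin(theta)
    # degenerate angle sets (all identical) also have no circular variance
    if np.ptp(c) == 0.0 and np.ptp(s) == 0.0:
        return CircLinCorr(n=n, circ_R2=None, circ_P=None, lin_R2=None, lin_P=None)

    def _corr(u: np.ndarray, v: np.ndarray) -> float:
        su, sv = u.std(), v.std()
        if su == 0.0 or sv == 0.0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    r_xc = _corr(xv, c)
    r_xs = _corr(xv, s)
    r_cs = _corr(c, s)
    denom = 1.0 - r_cs * r_cs
    if denom <= 0.0:
        # cos and sin perfectly collinear: angles lie on a 1-d slice
        r2 = max(r_xc * r_xc, r_xs * r_xs)
    else:
        r2 = (r_xc * r_xc + r_xs * r_xs - 2.0 * r_xc * r_xs * r_cs) / denom
    r2 = min(max(r2, 0.0), 1.0)
    p = float(stats.chi2.sf(n * r2, df=2))
    return CircLinCorr(n=n, circ_R2=r2, circ_P=p, lin_R2=None, lin_P=None)


def linear_correlation(y: Sequence[float], x: Sequence[float]) -> Tuple[Optional[float], Optional[float]]:
    """Ordinary squared Pearson correlation and its p-value, or ``(None, None)``."""
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    if np.ptp(xv) == 0.0:
        return None, None  # degenerate covariate: flagged undefined
    if np.ptp(yv) == 0.0:
        return 0.0, 1.0  # constant response: no linear association
    res = stats.pearsonr(yv, xv)
    return float(res.statistic) ** 2, float(res.pvalue)


def summarize(
    angles_deg: Sequence[float],
    *,
    min_n_rao: int = 4,
    rao_monte_carlo: bool = False,
    rao_reps: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> CircularSummary:
    """Full circular summary of a set of angles (one report row)."""
    a = np.asarray(angles_deg, dtype=float)
    n = int(a.size)
    mu, r = circular_mean(a)
    variance, sd = circular_dispersion(r)
    kappa = vonmises_kappa(r, n)
    Z, P = rayleigh_test(r, n)
    if n >= max(min_n_rao, 4):
        U, rao_P = rao_spacing_test(
            a, monte_carlo=rao_monte_carlo, reps=rao_reps, rng=rng
        )
    else:
        U, rao_P = None, None
    return CircularSummary(
        n=n,
        mu_deg=mu,
        r=r,
        kappa=kappa,
        circ_variance=variance,
        circ_sd_deg=sd,
        rayleigh_Z=Z,
        rayleigh_P=P,
        rao_U=U,
        rao_P=rao_P,
    )
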