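"""Critical values for Rao's spacing test.

The packaged table ``data/rao_critical_values.tsv`` holds upper-tail
critical values of the null distribution of Rao's U (uniform angles) for
n = 4..100 at the significance levels conventionally published for this
test.  It was generated by ``scripts/make_rao_table.py`` with 200,000
Monte Carlo replicates per sample size; at these replicate counts the
quantiles are stable to well under a degree.

Observed statistics are reported as brackets between adjacent table
levels (e.g. ``0.50 > P > 0.10``), with one-sided labels at the extremes
(``< 0.01``, ``> 0.99``) and the conventional collapsing of the
(0.01, 0.05) bracket to ``< 0.05``.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import DomainError

#: upper-tail significance levels, most significant first
LEVELS: Tuple[float, ...] = (0.01, 0.05, 0.10, 0.50, 0.90, 0.95, 0.99)

_TABLE: Optional[Dict[int, np.ndarray]] = None
_TABLE_MAX_N = 100


def _load_table() -> Dict[int, np.ndarray]:
    global _TABLE
    if _TABLE is None:
        text = (
            resources.files("acsiva").joinpath("data/rao_critical_values.tsv")
        ).read_text()
        table: Dict[int, np.ndarray] = {}
        for line in text.splitlines():
            if not line or line.startswith("n\t"):
                continue
            parts = line.split("\t")
            table[int(parts[0])] = np.array([float(v) for v in parts[1:]])
        _TABLE = table
    return _TABLE


def null_sample(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``reps`` values of Rao's U for ``n`` i.i.d. uniform angles."""
    a = np.sort(rng.uniform(0.0, 360.0, size=(reps, n)), axis=1)
    gaps = np.diff(a, axis=1)
    wrap = 360.0 - a[:, -1] + a[:, 0]
    lam = 360.0 / n
    return 0.5 * (
        np.abs(gaps - lam).sum(axis=1) + np.abs(wrap - lam)
    )


def critical_values(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo upper-tail critical values of U at :data:`LEVELS`."""
    u = null_sample(n, reps, rng)
    return np.quantile(u, [1.0 - a for a in LEVELS])


def _crits_for(n: int) -> np.ndarray:
    if n < 4:
        raise DomainError("Rao's test needs n >= 4")
    if n <= _TABLE_MAX_N:
        return _load_table()[n]
    # beyond the table: deterministic on-demand Monte Carlo
    rng = np.random.default_rng(881293 + n)
    return critical_values(n, 20000, rng)


def rao_bracket(U: float, n: int) -> Tuple[Optional[float], Optional[float]]:
    """Bracket the p-value of an observed U between published table levels.

    Returns ``(lower, upper)`` where ``None`` marks an open end:
    ``(None, 0.01)`` means ``P < 0.01`` and ``(0.99, None)`` means
    ``P > 0.99``.
    """
    crits = _crits_for(n)
    # crits are decreasing in index as LEVELS increase
    if U >= crits[0]:
        return None, LEVELS[0]
    for i in range(1, len(LEVELS)):
        if U >= crits[i]:
            lower, upper = LEVELS[i - 1], LEVELS[i]
            if upper <= 0.05:
                return None, upper  # print "< 0.05" like the published tables
            return lower, upper
    return LEVELS[-1], None


def rao_montecarlo_pvalue(
    U: float,
    n: int,
    *,
    reps: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Continuous Monte Carlo p-value ``P(U_null >= U)`` (add-one estimator)."""
    if rng is None:
        rng = np.random.default_rng()
    u = null_sample(n, reps, rng)
    return float((np.count_nonzero(u >= U) + 1) / (reps + 1))
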