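"""Exact small-sample statistics: two-sided Fisher exact and Mann-Whitney U.

Both tests are implemented exactly for the small sample sizes that arise in
per-particle count data: Fisher's exact p sums hypergeometric probability
masses over all tables with the observed margins (the conventional two-sided
definition), and the Mann-Whitney null distribution is built by dynamic
programming, which is feasible and exact for groups up to 25 without ties.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .errors import DegenerateStatisticsError


@dataclass
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]``: rows = particle class, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("table entries must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    sided: str = "two-sided"
    exact: bool = True

    def to_json(self) -> str:
        return json.dumps({"method": self.method, "statistic": self.statistic,
                           "p_value": self.p_value, "n": list(self.n),
                           "sided": self.sided, "exact": self.exact})


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test by probability-mass summation.

    p is the sum of hypergeometric probabilities of all tables sharing the
    observed margins whose probability does not exceed the observed table's
    (with a ``1 + 1e-7`` relative slack to absorb floating error).  A zero
    margin makes every table with these margins identical, so p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("degenerate 2x2 table (a zero margin); p = 1",
                      stacklevel=2)
        return TestResult("fisher_exact", _odds_ratio(a, b, c, d), 1.0,
                          (a + b, c + d))
    # p is mathematically invariant under row/column swaps and transposition;
    # computing on a canonical orbit representative makes that hold bitwise
    orbit = {(a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a),
             (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a)}
    ca, cb, cc, cd = min(orbit)
    n_total = ca + cb + cc + cd
    row1, col1 = ca + cb, ca + cc
    lo = max(0, col1 - (cc + cd))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n_total, col1, row1)
    p_obs = pmf[ca - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return TestResult("fisher_exact", _odds_ratio(a, b, c, d),
                      min(p, 1.0), (a + b, c + d))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_distribution(n: int, m: int) -> tuple[int, ...]:
    """Counts of arrangements per U value for group sizes (n, m), no ties.

    Recurrence: f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u).
    """
    if n == 0 or m == 0:
        return (1,)
    left = _u_distribution(n - 1, m)
    right = _u_distribution(n, m - 1)
    out = [0] * (n * m + 1)
    for u, cnt in enumerate(left):
        out[u + m] += cnt
    for u, cnt in enumerate(right):
        out[u] += cnt
    return tuple(out)


def mann_whitney_two_tailed(x, y, exact_max_n: int = 25) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    U is the smaller of U_x and U_y with midrank tie handling.  Without ties
    and with both groups at most ``exact_max_n``, the p-value is exact
    (doubled lower tail of the dynamic-programming null distribution, capped
    at 1); otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise DegenerateStatisticsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    u_y = nx * ny - u_x
    u = min(u_x, u_y)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and nx <= exact_max_n and ny <= exact_max_n:
        dist = np.array(_u_distribution(nx, ny), dtype=float)
        p = float(min(1.0, 2.0 * dist[: int(u) + 1].sum() / dist.sum()))
        return TestResult("mann_whitney_u", u, p, (nx, ny), exact=True)

    n_tot = nx + ny
    mu = nx * ny / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())
                     / (n_tot * (n_tot - 1))) if n_tot > 1 else 0.0
    var = nx * ny / 12.0 * ((n_tot + 1) - tie_term)
    if var <= 0:
        # every pooled value tied: no evidence of any difference
        return TestResult("mann_whitney_u", u, 1.0, (nx, ny), exact=False)
    z = (u - mu + 0.5) / math.sqrt(var)          # continuity-corrected
    p = float(min(1.0, 2.0 * sps.norm.cdf(z))) if u < mu else 1.0
    return TestResult("mann_whitney_u", u, p, (nx, ny), exact=False)


def group_compare(measurements) -> tuple[dict[str, float], TestResult]:
    """Per-group medians plus the Mann-Whitney comparison of two groups.

    Accepts a :class:`~tomovault.profile_thickness.GroupMeasurements` or any
    object with a ``values`` dict of exactly two ``label -> list`` entries.
    """
    groups = measurements.values
    if len(groups) != 2:
        raise DegenerateStatisticsError(
            f"need exactly two groups, got {sorted(groups)}")
    (la, va), (lb, vb) = sorted(groups.items())
    medians = {la: float(np.median(va)), lb: float(np.median(vb))}
    return medians, mann_whitney_two_tailed(va, vb)
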