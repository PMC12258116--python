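"""Closed-form layer: Fibonacci p-numbers, growth roots and the c <-> k2 map.

The total population of the linear model obeys
``N(t) = N(t−1) + N(t−c)`` with ``N(t) = t + 1`` for ``t <= c``, which
is the Fibonacci p-number sequence with ``p = c − 1`` under the seeding
``F_0 = … = F_{c−1} = 1``; the two indexings are related by
``N(t) = F_{t+c−1}`` (for c = 6 this is OEIS A005708).

Its growth rate is the golden p-section: the unique root
``rho in (1, 2]`` of ``rho^c − rho^{c−1} − 1 = 0``.  The limiting
mature/immature ratio is ``lambda = rho − 1``, the unique root in
``(0, 1]`` of ``lambda (1 + lambda)^{c−1} = 1``, and the companion
continuous model reproduces that growth when its immature-division rate
is ``k2 = lambda^2`` (with ``k1 = 1``), since its leading eigenvalue is
then ``sqrt(k1 k2) = lambda``.  ``c_from_lambda`` inverts the root
equation in closed form: ``c = 1 − ln(lambda)/ln(1 + lambda)``.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Callable, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .rosette import RosetteRun

__all__ = [
    "p_fib",
    "total_cells_formula",
    "mi_ratio_discrete",
    "growth_root",
    "solve_lambda",
    "c_from_lambda",
    "k2_from_c",
    "table3",
    "branch_counts",
]


def p_fib(c: int, n: int) -> int:
    """Exact Fibonacci p-number F_n (p = c − 1): F_n = F_{n−1} + F_{n−c}.

    Seeded with F_0 … F_{c−1} = 1; arbitrary-precision integers.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    vals = [1] * c
    if n < c:
        return 1
    for m in range(c, n + 1):
        vals.append(vals[m - 1] + vals[m - c])
    return vals[n]


def total_cells_formula(c: int, t: int) -> int:
    """Closed-form total population of the linear model: N(t) = F_{t+c−1}."""
    return p_fib(c, t + c - 1)


def mi_ratio_discrete(c: int, t: int) -> Fraction:
    """Exact M/I ratio of the linear model (n_wm = L = ∞) at step t.

    Uses the identities M(t) = N(t−c) and I(t) = N(t) − N(t−c).
    """
    if t <= c:
        raise ValueError("need t > c for a nonzero immature population")
    m = total_cells_formula(c, t - c)
    n = total_cells_formula(c, t)
    return Fraction(m, n - m)


def _bisect(f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-13) -> float:
    """Bisection on a bracketed monotone root; guaranteed convergence."""
    flo = f(lo)
    if flo == 0.0:
        return lo
    fhi = f(hi)
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise ValueError("root not bracketed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def growth_root(c: int) -> float:
    """Golden p-section: the root rho in (1, 2] of rho^c − rho^{c−1} − 1 = 0.

    Equals the limit of F_{n+1}/F_n for the order-c p-Fibonacci sequence.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if c == 1:
        return 2.0
    return _bisect(lambda r: r**c - r ** (c - 1) - 1.0, 1.0, 2.0)


def solve_lambda(c: int) -> float:
    """The root lambda in (0, 1] of lambda (1 + lambda)^{c−1} = 1.

    This is the limiting M/I ratio of the discrete model and equals
    ``growth_root(c) − 1``.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if c == 1:
        return 1.0
    return _bisect(lambda x: x * (1.0 + x) ** (c - 1) - 1.0, 1e-12, 1.0)


def c_from_lambda(lam: float) -> float:
    """Inverse of :func:`solve_lambda`: c = 1 − ln(lambda)/ln(1 + lambda)."""
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"lambda must lie in (0, 1], got {lam}")
    if lam == 1.0:
        return 1.0
    return 1.0 - math.log(lam) / math.log(1.0 + lam)


def k2_from_c(c: int) -> float:
    """Immature-division rate k2 of the continuous model matching maturation c.

    With k1 = 1 the continuous growth eigenvalue is sqrt(k1 k2); setting
    k2 = lambda(c)^2 makes it equal the discrete limiting ratio lambda.
    """
    lam = solve_lambda(c)
    return lam * lam


def table3(c_max: int = 6) -> pd.DataFrame:
    """Discrete <-> continuous correspondence table for c = 1..c_max.

    Columns: c, k1 (= 1), k2 (= lambda^2), lambda1 (= sqrt(k1 k2)) and
    the limiting M/I ratio (= lambda1).
    """
    rows = []
    for c in range(1, c_max + 1):
        lam = solve_lambda(c)
        rows.append({"c": c, "k1": 1.0, "k2": lam * lam, "lambda1": lam, "M_over_I": lam})
    return pd.DataFrame(rows)


def branch_counts(c: int, t: int, run: "RosetteRun | None" = None) -> list[int]:
    """Cells per branch of the rosette at step t.

    Excludes the clonogenic cell and the first circumferential leaflet
    layer (the ``D = 360/R`` unit-radius positions), so the counts sum
    to ``total − 1 − D`` once the leaflet layer is full.  Each remaining
    cell is assigned to the angular sector centred on its nearest branch
    ray (ties broken toward the lower ray index).  A run may be passed
    in to avoid re-simulating.
    """
    from .rosette import run_rosette  # local import to keep module load light
    from .rules import RuleParameters

    if run is None:
        run = run_rosette(RuleParameters(c=c, T=t))
    if t > run.params.T:
        raise ValueError("requested time beyond the simulated horizon")
    D = run.params.n_directions
    sector = 2.0 * math.pi / D
    counts = [0] * D
    snap = run.snapshot_at(t)
    for lab, (x, y) in snap.positions.items():
        r = math.hypot(x, y)
        if r < 1e-6 or abs(r - 1.0) < 1e-6:
            continue  # origin or first leaflet layer
        ang = math.atan2(y, x) % (2.0 * math.pi)
        idx = int(math.floor(ang / sector + 0.5)) % D
        counts[idx] += 1
    return counts
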