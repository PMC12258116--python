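"""Linear four-compartment model of proliferative/differentiated dynamics.

Compartments: mature dividing cells M, immature cells I, and two wholly
mature (terminally differentiated) pools W1 (from I) and W2 (from M).
Division is asymmetric production without self-loss — an M cell yields
an additional I cell at rate k1, an I cell an additional M cell at rate
k2 — while differentiation drains the proliferative pool:

    dM/dt  = k2 I − k4 M
    dI/dt  = k1 M − k3 I
    dW1/dt = k3 I − k5 W1
    dW2/dt = k4 M − k6 W2

The W compartments decouple, so the spectrum is

    lambda_{1,2} = [−(k3 + k4) ± sqrt((k3 + k4)^2 − 4 (k3 k4 − k1 k2))] / 2,
    lambda_3 = −k5,  lambda_4 = −k6,

always real (the discriminant is (k3 − k4)^2 + 4 k1 k2 >= 0).  The
leading eigenvalue lambda_1 is zero, positive or negative according to
whether k3 k4 = k1 k2, < or >: balanced differentiation gives steady
renewal, and differentiation along only one lineage (k3 = 0 or k4 = 0)
can never balance positive division rates.  Under the balance condition
the steady-state proportions are M/I = k2/k4 = k3/k1, W2/M = k4/k6 and
W1/I = k3/k5.

k1 is the natural time unit (one cell cycle); choosing k1 = 1 measures
time in cycles and makes the correspondence with the discrete model's
maturation period c read k2 = lambda(c)^2 (see
:func:`cryptsim.sequences.k2_from_c`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "ContinuousParams",
    "ContinuousState",
    "Regime",
    "system_matrix",
    "eigenvalues",
    "steady_state_ratios",
    "integrate",
    "classify_regime",
]


@dataclass(frozen=True)
class ContinuousParams:
    """Nonnegative rate constants, per cell cycle (k1 normalized to 1).

    k1: M division; k2: I division; k3: I -> W1 differentiation;
    k4: M -> W2 differentiation; k5: W1 death; k6: W2 death.
    """

    k1: float = 1.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0 (it sets the time unit)")


@dataclass(frozen=True)
class ContinuousState:
    """Compartment sizes (cells); the state vector order is (M, I, W1, W2)."""

    M: float = 0.0
    I: float = 0.0  # noqa: E741
    W1: float = 0.0
    W2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.M, self.I, self.W1, self.W2) < 0:
            raise ValueError("compartment sizes must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.I, self.W1, self.W2], dtype=float)


class Regime(str, Enum):
    STEADY = "steady"
    GROWTH = "growth"
    DECAY = "decay"


def system_matrix(params: ContinuousParams) -> np.ndarray:
    """Generator A of dx/dt = A x in state order (M, I, W1, W2).

    The proliferative 2x2 block has trace −(k3 + k4) and determinant
    k3 k4 − k1 k2; the W rows decouple with rates −k5, −k6.
    """
    p = params
    return np.array(
        [
            [-p.k4, p.k2, 0.0, 0.0],
            [p.k1, -p.k3, 0.0, 0.0],
            [0.0, p.k3, -p.k5, 0.0],
            [p.k4, 0.0, 0.0, -p.k6],
        ]
    )


def eigenvalues(params: ContinuousParams) -> tuple[float, float, float, float]:
    """Closed-form spectrum (lambda1 >= lambda2, then −k5, −k6); all real."""
    p = params
    s = p.k3 + p.k4
    disc = s * s - 4.0 * (p.k3 * p.k4 - p.k1 * p.k2)
    root = math.sqrt(disc)  # = (k3−k4)^2 + 4 k1 k2 >= 0
    lam1 = 0.5 * (-s + root)
    lam2 = 0.5 * (-s - root)
    return (lam1, lam2, -p.k5, -p.k6)


def classify_regime(params: ContinuousParams, tol: float = 1e-12) -> Regime:
    """Steady, growth or decay by the sign of k1 k2 − k3 k4."""
    d = params.k1 * params.k2 - params.k3 * params.k4
    if abs(d) <= tol:
        return Regime.STEADY
    return Regime.GROWTH if d > 0 else Regime.DECAY


def steady_state_ratios(
    params: ContinuousParams, tol: float = 1e-9
) -> tuple[float, float, float]:
    """Steady-state proportions (M/I, W2/M, W1/I) under balance.

    Requires k3 k4 = k1 k2 (within ``tol``) so that lambda1 = 0, and
    positive k4, k5, k6 so the ratios are finite.  These are the limits
    of the trajectory ratios from any positive initial state.
    """
    p = params
    if abs(p.k3 * p.k4 - p.k1 * p.k2) > tol * max(1.0, p.k1 * p.k2):
        raise ValueError(
            "balance condition k3*k4 == k1*k2 violated: system grows or decays"
        )
    if min(p.k4, p.k5, p.k6) <= 0:
        raise ValueError("k4, k5, k6 must be positive for finite steady-state ratios")
    return (p.k2 / p.k4, p.k4 / p.k6, p.k3 / p.k5)


def integrate(
    params: ContinuousParams, init: ContinuousState, times: np.ndarray | list[float]
) -> pd.DataFrame:
    """Exact trajectory x(t) = exp(A t) x0 on the given time grid.

    Columns: t, M, I, W1, W2.  The generator moves mass between
    compartments (Metzler structure), so nonnegative initial data stay
    nonnegative.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    A = system_matrix(params)
    x0 = init.as_array()
    rows = np.empty((t.size, 4))
    for i, ti in enumerate(t):
        rows[i] = expm(A * ti) @ x0
    out = pd.DataFrame(rows, columns=["M", "I", "W1", "W2"])
    out.insert(0, "t", t)
    return out
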