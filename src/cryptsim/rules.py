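"""Division rules shared by the lineage and rosette simulators.

The renewal program of a crypt-like tissue is encoded here as five rules:

1. *Timing* — one simulation step is one cell cycle; all divisions are
   synchronous on that clock.
2. *Temporal order* — division is asymmetric: a mature (M) cell divides
   every cycle, producing one immature (I) daughter; an I cell divides
   only once it has matured, i.e. reached age ``c`` (the maturation
   period), at which point it immediately becomes an M cell and divides.
3. *Direction* — the split angle of a cell rotates counterclockwise by a
   fixed increment ``R`` (degrees) at each division; both daughters
   inherit the rotated orientation.  By default ``R = 360/c``.
4. *Number of divisions* — a cell stops dividing at age ``n_wm`` (whole
   maturation), becoming a terminally differentiated W cell; it therefore
   performs exactly ``n_wm − c`` divisions.  In steady-state mode
   ``n_wm`` shrinks with generation ``g`` as ``n_wm = n_wm0 − g``
   (floored at ``c``, where the division count hits zero).
5. *Lifespan* — a cell dies and vacates the tissue at age ``L``.

The clonogenic cell (label 0, generation 0; biological analog: the crypt
stem cell) is permanently mature and immortal: it divides every cycle,
forever.

Ages, ``c``, ``n_wm`` and ``L`` are all measured in cell cycles.
Unbounded ``n_wm0``/``L`` are represented by ``math.inf`` and flow
through the same comparisons as finite values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Any

__all__ = [
    "UNBOUNDED",
    "CellState",
    "RuleParameters",
    "Cell",
    "n_wm_effective",
    "classify",
    "classify_age",
    "divides_now",
]

#: Sentinel for an unbounded whole-maturation age or lifespan.
UNBOUNDED: float = math.inf


class CellState(IntEnum):
    """Maturation state of a cell.

    The non-clonogenic states are ordered by age: ``I < M < W < DEAD``;
    a cell only ever moves forward along that ladder.  The clonogenic
    cell is a permanently M-like, immortal special case.
    """

    I = 0  # noqa: E741 - domain name: immature cell
    M = 1
    W = 2
    DEAD = 3
    CLONOGENIC = 4


@dataclass(frozen=True)
class RuleParameters:
    """The five-rule parameter set governing a simulation.

    Parameters
    ----------
    c
        Maturation period in cell cycles (``>= 1``).
    n_wm0
        Base whole-maturation age (cycles); ``math.inf`` disables
        terminal differentiation.
    L
        Lifespan (cycles); ``math.inf`` makes cells immortal.
    R_degrees
        Rotation increment of the split angle per division, in degrees.
        ``None`` selects the default ``360 / c``.  Must divide 360 for
        the spatial model.
    steady_state
        If true, schedule ``n_wm`` per generation as
        ``max(n_wm0 − g, c)``.
    T
        Simulation horizon in cycles.
    """

    c: int
    n_wm0: float = UNBOUNDED
    L: float = UNBOUNDED
    R_degrees: float | None = None
    steady_state: bool = False
    T: int = 0

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError(f"maturation period c must be >= 1, got {self.c}")
        if self.n_wm0 < self.c:
            raise ValueError(
                f"whole-maturation base n_wm0 ({self.n_wm0}) must be >= c ({self.c})"
            )
        if self.L < self.n_wm0:
            raise ValueError(f"lifespan L ({self.L}) must be >= n_wm0 ({self.n_wm0})")
        R = self.rotation_degrees
        if not 0.0 < R <= 360.0:
            raise ValueError(f"rotation increment R must lie in (0, 360], got {R}")
        if self.T < 0:
            raise ValueError(f"horizon T must be >= 0, got {self.T}")

    @property
    def rotation_degrees(self) -> float:
        """Rotation increment in degrees (default ``360 / c``)."""
        return 360.0 / self.c if self.R_degrees is None else float(self.R_degrees)

    @property
    def n_directions(self) -> int:
        """Number of distinct split directions, ``360 / R``.

        Raises ``ValueError`` if R does not divide 360.
        """
        ratio = 360.0 / self.rotation_degrees
        k = round(ratio)
        if k < 1 or abs(ratio - k) > 1e-9:
            raise ValueError(
                f"rotation increment {self.rotation_degrees} deg does not divide 360"
            )
        return k

    # -- JSON config -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Flat JSON-ready mapping; ``None`` encodes unbounded / default R."""
        return {
            "c": self.c,
            "n_wm0": None if math.isinf(self.n_wm0) else int(self.n_wm0),
            "L": None if math.isinf(self.L) else int(self.L),
            "R_degrees": self.R_degrees,
            "steady_state": self.steady_state,
            "T": self.T,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RuleParameters":
        return cls(
            c=int(d["c"]),
            n_wm0=UNBOUNDED if d.get("n_wm0") is None else float(d["n_wm0"]),
            L=UNBOUNDED if d.get("L") is None else float(d["L"]),
            R_degrees=d.get("R_degrees"),
            steady_state=bool(d.get("steady_state", False)),
            T=int(d.get("T", 0)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RuleParameters":
        return cls.from_dict(json.loads(text))


@dataclass(slots=True)
class Cell:
    """One cell agent.

    ``label`` is the birth-order identifier (0 = clonogenic); labels are
    unique and strictly increasing in birth order and are never reused.
    ``age`` is kept equal to ``current time − birth_time`` by the
    simulators.  ``split_angle`` is an index into the ``360/R`` discrete
    directions (spatial model only); ``position`` is a planar coordinate
    or ``None`` in the non-spatial model.
    """

    label: int
    birth_time: int
    generation: int
    parent_label: int
    age: int = 0
    split_angle: int = 0
    position: tuple[float, float] | None = None


def n_wm_effective(g: int, params: RuleParameters) -> float:
    """Whole-maturation age for a generation-``g`` cell.

    Fixed at ``n_wm0`` normally; in steady-state mode it decreases
    linearly with generation, ``n_wm0 − g``, floored at ``c`` so the
    division count ``n_wm − c`` never goes negative (a cell with
    ``n_wm = c`` skips the M stage entirely and performs no divisions).
    """
    if g < 0:
        raise ValueError("generation must be >= 0")
    if not params.steady_state:
        return params.n_wm0
    return max(params.n_wm0 - g, params.c)


def classify_age(age: int, generation: int, params: RuleParameters) -> CellState:
    """State of a (non-clonogenic) cell of the given age and generation."""
    if age >= params.L:
        return CellState.DEAD
    if age < params.c:
        return CellState.I
    if age < n_wm_effective(generation, params):
        return CellState.M
    return CellState.W


def classify(cell: Cell, params: RuleParameters) -> CellState:
    """State of a cell; label 0 is always CLONOGENIC."""
    if cell.label == 0:
        return CellState.CLONOGENIC
    return classify_age(cell.age, cell.generation, params)


def divides_now(cell: Cell, params: RuleParameters) -> bool:
    """True iff the cell divides this cycle (state M, or clonogenic).

    A cell divides at ages ``c, c+1, …, n_wm − 1`` — exactly
    ``n_wm − c`` times over its life.
    """
    return classify(cell, params) in (CellState.M, CellState.CLONOGENIC)
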