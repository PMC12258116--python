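"""Spatial agent-based model: rosette growth on a planar lattice.

The division bookkeeping is identical to the linear model; on top of it
every cell carries a planar position and a split-angle index into the
``D = 360/R`` discrete directions.  Each step, dividing cells (in birth
order, clonogenic first) place their immature daughter on the
neighbouring position one unit step along their current split angle;
both daughters then rotate their orientation by one increment
counterclockwise.  If the target position is occupied, the entire
occupied chain of cells along that ray is displaced one position
outward before the daughter is placed, so at the end of every step each
position holds at most one cell.  The clonogenic cell sits at the
origin and is never displaced (a displacement chain skips over the
origin).  Dead cells vacate their position without back-filling.

With ``n_wm = L = ∞`` the structure grows without bound and shows
``D``-fold rotational symmetry (the leaflet/branch pattern).  With the
steady-state schedule ``n_wm = n_wm0 − g`` and a finite lifespan the
population becomes bounded: a dividing region persists around the
origin while wholly mature cells stream outward and die near the edge,
which is the planar picture of a renewing crypt.  Wrapping the plane on
a cylinder (:func:`project_cylinder`) gives the 3D crypt-like view.

Positions are exact unit-vector sums stored as floats; occupancy keys
round coordinates to 6 decimals, far below the lattice spacing for any
structure the package simulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .lineage import LineageRecord, LinearRun
from .rules import RuleParameters, CellState, classify_age, n_wm_effective

__all__ = [
    "RosetteSnapshot",
    "RosetteRun",
    "run_rosette",
    "run_steady_state",
    "symmetry_order",
    "project_cylinder",
]

_KEY_DECIMALS = 6

PosKey = tuple[float, float]


def _key(x: float, y: float) -> PosKey:
    # normalize -0.0 so keys are stable
    return (round(x, _KEY_DECIMALS) + 0.0, round(y, _KEY_DECIMALS) + 0.0)


_ORIGIN_KEY = _key(0.0, 0.0)


@dataclass
class RosetteSnapshot:
    """State of the tissue at the end of one step.

    ``positions``/``angles`` map live-cell labels to planar coordinates
    and split-angle indices.
    """

    time: int
    positions: dict[int, tuple[float, float]]
    angles: dict[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.positions)


@dataclass
class RosetteRun:
    """A finished spatial run: record (as in the linear model) + snapshots."""

    params: RuleParameters
    record: LineageRecord
    snapshots: list[RosetteSnapshot]

    def snapshot_at(self, t: int) -> RosetteSnapshot:
        if not 0 <= t <= self.params.T:
            raise ValueError(f"time {t} outside simulated horizon [0, {self.params.T}]")
        return self.snapshots[t]

    def as_linear(self) -> LinearRun:
        """View the run through the non-spatial counting API."""
        return LinearRun(params=self.params, record=self.record)


def _directions(D: int) -> list[tuple[float, float]]:
    return [
        (math.cos(2.0 * math.pi * k / D), math.sin(2.0 * math.pi * k / D))
        for k in range(D)
    ]


def _resolve_placement(
    occ: dict[PosKey, int],
    pos: dict[int, tuple[float, float]],
    target: tuple[float, float],
    step_vec: tuple[float, float],
) -> tuple[float, float]:
    """Free ``target`` by pushing the occupied chain one step outward.

    Cells are displaced along ``step_vec`` (the division ray); their
    relative radial order along the ray is preserved.  The origin slot
    is skipped: the clonogenic cell is immovable and chains pass over
    it.  Returns the (possibly shifted) position where the new daughter
    should be placed.
    """
    ux, uy = step_vec
    slots: list[tuple[tuple[float, float], PosKey]] = []
    qx, qy = target
    while True:
        qk = _key(qx, qy)
        if qk == _ORIGIN_KEY:
            qx, qy = qx + ux, qy + uy
            continue
        slots.append(((qx, qy), qk))
        if qk not in occ:
            break
        qx, qy = qx + ux, qy + uy
    # shift occupants outward, far end first
    for i in range(len(slots) - 2, -1, -1):
        lab = occ.pop(slots[i][1])
        occ[slots[i + 1][1]] = lab
        pos[lab] = slots[i + 1][0]
    return slots[0][0]


def run_rosette(params: RuleParameters) -> RosetteRun:
    """Run the spatial model for ``params.T`` cycles. Deterministic.

    Placement never creates or destroys cells, so total counts match
    :func:`cryptsim.lineage.run_linear` under identical parameters.
    """
    D = params.n_directions  # raises if R does not divide 360
    dirs = _directions(D)

    birth: list[int] = [0]
    parent: list[int] = [-1]
    generation: list[int] = [0]
    events: list[list[tuple[int, int]]] = [[]]

    pos: dict[int, tuple[float, float]] = {0: (0.0, 0.0)}
    angle: dict[int, int] = {0: 0}
    occ: dict[PosKey, int] = {_ORIGIN_KEY: 0}

    snapshots = [RosetteSnapshot(time=0, positions=dict(pos), angles=dict(angle))]

    for t in range(1, params.T + 1):
        # deaths first: vacate, no back-fill
        for lab in [la for la in pos if la != 0 and t - birth[la] >= params.L]:
            del occ[_key(*pos[lab])]
            del pos[lab]
            del angle[lab]

        n_now = len(birth)
        step_events: list[tuple[int, int]] = []
        for lab in range(n_now):
            if lab not in pos:
                continue  # dead
            age = t - birth[lab]
            if lab != 0 and not (
                params.c <= age < min(n_wm_effective(generation[lab], params), params.L)
            ):
                continue
            a = angle[lab]
            ux, uy = dirs[a]
            px, py = pos[lab]
            target = (px + ux, py + uy)
            placed = _resolve_placement(occ, pos, target, dirs[a])
            child = len(birth)
            birth.append(t)
            parent.append(lab)
            generation.append(generation[lab] + 1)
            step_events.append((lab, child))
            pos[child] = placed
            occ[_key(*placed)] = child
            # both daughters inherit the orientation, rotated by one increment
            new_a = (a + 1) % D
            angle[lab] = new_a
            angle[child] = new_a
        events.append(step_events)
        snapshots.append(RosetteSnapshot(time=t, positions=dict(pos), angles=dict(angle)))

    record = LineageRecord(events=events, birth_time=birth, parent=parent, generation=generation)
    return RosetteRun(params=params, record=record, snapshots=snapshots)


def run_steady_state(params: RuleParameters) -> RosetteRun:
    """Run the spatial model under the steady-state schedule.

    Requires ``steady_state=True`` and a finite lifespan ``L >= n_wm0``
    (the parameter invariants already enforce the ordering).
    """
    if not params.steady_state:
        raise ValueError("run_steady_state requires steady_state=True")
    if math.isinf(params.L) or math.isinf(params.n_wm0):
        raise ValueError("steady-state runs require finite n_wm0 and L")
    return run_rosette(params)


def _states_at(run: RosetteRun, t: int) -> dict[int, CellState]:
    snap = run.snapshot_at(t)
    rec = run.record
    out: dict[int, CellState] = {}
    for lab in snap.positions:
        if lab == 0:
            out[lab] = CellState.CLONOGENIC
        else:
            out[lab] = classify_age(t - rec.birth_time[lab], rec.generation[lab], run.params)
    return out


def symmetry_order(run: RosetteRun, t: int | None = None) -> int:
    """Largest k such that a 360/k rotation maps the structure onto itself.

    The occupied positions (excluding the origin), tagged with their
    cell states, are compared as multisets under rotation.  k = 1 (full
    turn) always holds, so the return value is >= 1.
    """
    if t is None:
        t = run.params.T
    snap = run.snapshot_at(t)
    states = _states_at(run, t)
    items = [
        (x, y, states[lab])
        for lab, (x, y) in snap.positions.items()
        if _key(x, y) != _ORIGIN_KEY
    ]
    if not items:
        return 1
    base = frozenset(
        (k, sum(1 for it in items if (_key(it[0], it[1]), it[2]) == k))
        for k in {(_key(x, y), s) for x, y, s in items}
    )
    for k in range(len(items), 1, -1):
        theta = 2.0 * math.pi / k
        ct, st = math.cos(theta), math.sin(theta)
        rotated: dict[tuple[PosKey, CellState], int] = {}
        for x, y, s in items:
            kk = (_key(x * ct - y * st, x * st + y * ct), s)
            rotated[kk] = rotated.get(kk, 0) + 1
        if frozenset(rotated.items()) == base:
            return k
    return 1


def project_cylinder(
    run: RosetteRun, circumference: int = 42, t: int | None = None
) -> dict[int, tuple[float, float]]:
    """Wrap the planar structure onto a cylinder surface.

    Maps each occupied position ``(x, y)`` to
    ``(angle, height) = (2*pi*(x mod circumference)/circumference, y)``,
    simulating a crypt wall of single-cell thickness with the given
    columnar circumference (default 42 cells).  Injective as long as no
    two occupied positions differ by a multiple of the circumference in
    x at equal y.
    """
    if circumference < 1:
        raise ValueError("circumference must be >= 1")
    if t is None:
        t = run.params.T
    snap = run.snapshot_at(t)
    out: dict[int, tuple[float, float]] = {}
    for lab, (x, y) in snap.positions.items():
        ang = 2.0 * math.pi * ((x % circumference) / circumference)
        out[lab] = (ang, y)
    return out
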