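"""Non-spatial (linear / tree) model of asymmetric-division lineages.

Starting from the single clonogenic cell at t = 0, every mature cell
divides once per cycle, appending one immature daughter.  Daughters are
labelled in birth order — within a step, parents divide in ascending
label order with the clonogenic cell first — so the label sequence is
the global division order.  With ``n_wm = L = ∞`` the total population
follows the generalized Fibonacci recurrence

    N(t) = N(t−1) + N(t−c),    N(t) = t + 1 for t <= c,

which is the Fibonacci p-number sequence with p = c − 1 under the
seeding ``F_0 … F_{c−1} = 1`` (the two index conventions are tied by
``N(t) = F_{t+c−1}``; see :mod:`cryptsim.sequences`).
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import NamedTuple

from .rules import CellState, RuleParameters, classify_age, n_wm_effective

__all__ = [
    "LineageRecord",
    "LinearRun",
    "StateCounts",
    "run_linear",
    "total_cells",
    "counts_by_state",
    "counts_by_generation",
    "first_event_of_generation",
    "lineage_to_newick",
]


@dataclass
class LineageRecord:
    """Complete division history of a run.

    ``events[t]`` is the ordered list of ``(parent_label, child_label)``
    division events at step ``t``.  Per-cell arrays are indexed by label;
    dead cells are retained (labels are never reused), so the record is
    the bijection label <-> birth order.
    """

    events: list[list[tuple[int, int]]]
    birth_time: list[int]
    parent: list[int]
    generation: list[int]

    @property
    def n_cells_ever(self) -> int:
        return len(self.birth_time)


@dataclass
class LinearRun:
    """A finished linear-model run: parameters plus its lineage record."""

    params: RuleParameters
    record: LineageRecord


class StateCounts(NamedTuple):
    M: int
    I: int  # noqa: E741
    W: int


def _divides_at(age: int, g: int, params: RuleParameters) -> bool:
    # non-clonogenic eligibility: mature, not yet wholly mature, alive
    return params.c <= age < min(n_wm_effective(g, params), params.L)


def run_linear(params: RuleParameters) -> LinearRun:
    """Run the non-spatial model for ``params.T`` cycles.

    Deterministic: identical parameters give identical runs.  Division
    is evaluated at the *start* of each step on the advanced clock, so a
    cell born at time ``b`` first divides at ``t = b + c`` (the step it
    reaches age ``c``), and the clonogenic cell divides at every
    ``t >= 1``.
    """
    birth: list[int] = [0]
    parent: list[int] = [-1]
    generation: list[int] = [0]
    events: list[list[tuple[int, int]]] = [[]]

    for t in range(1, params.T + 1):
        n_now = len(birth)
        step_events: list[tuple[int, int]] = []
        next_label = n_now
        for lab in range(n_now):
            age = t - birth[lab]
            if lab == 0 or _divides_at(age, generation[lab], params):
                step_events.append((lab, next_label))
                next_label += 1
        for p, _child in step_events:
            birth.append(t)
            parent.append(p)
            generation.append(generation[p] + 1)
        events.append(step_events)

    record = LineageRecord(events=events, birth_time=birth, parent=parent, generation=generation)
    return LinearRun(params=params, record=record)


def _check_time(run: LinearRun, t: int) -> None:
    if not 0 <= t <= run.params.T:
        raise ValueError(f"time {t} outside simulated horizon [0, {run.params.T}]")


def total_cells(run: LinearRun, t: int) -> int:
    """Number of ever-born, non-dead cells at step ``t``."""
    _check_time(run, t)
    birth = run.record.birth_time
    n_born = bisect_right(birth, t)
    # deaths: age >= L, clonogenic exempt
    n_dead = bisect_right(birth, t - run.params.L)
    if n_dead > 0:
        n_dead -= 1  # label 0 never dies
    return n_born - n_dead


def counts_by_state(run: LinearRun, t: int) -> StateCounts:
    """(M, I, W) counts at step ``t``; the clonogenic cell counts as M."""
    _check_time(run, t)
    rec = run.record
    n_born = bisect_right(rec.birth_time, t)
    m = i = w = 0
    for lab in range(1, n_born):
        state = classify_age(t - rec.birth_time[lab], rec.generation[lab], run.params)
        if state is CellState.M:
            m += 1
        elif state is CellState.I:
            i += 1
        elif state is CellState.W:
            w += 1
    return StateCounts(M=m + 1, I=i, W=w)


def counts_by_generation(run: LinearRun, t: int) -> dict[int, int]:
    """Live-cell count per generation at step ``t`` (generation 0 is 1)."""
    _check_time(run, t)
    rec = run.record
    n_born = bisect_right(rec.birth_time, t)
    counts: Counter[int] = Counter({0: 1})
    for lab in range(1, n_born):
        if t - rec.birth_time[lab] < run.params.L:
            counts[rec.generation[lab]] += 1
    return dict(counts)


def first_event_of_generation(run: LinearRun, g: int) -> int:
    """Earliest step at which a generation-``g`` cell is produced."""
    if g < 1:
        raise ValueError("generation must be >= 1")
    rec = run.record
    for lab in range(1, rec.n_cells_ever):
        if rec.generation[lab] == g:
            return rec.birth_time[lab]  # labels are in birth order
    raise ValueError(f"no generation-{g} cell produced within the horizon")


def lineage_to_newick(record: LineageRecord) -> str:
    """Division tree in Newick form.

    Node names are cell labels; each non-root branch is annotated with
    the cell's birth time as its branch length.  Children (direct
    progeny) appear in birth order.  A single division renders as
    ``(1:1)0;``.
    """
    if record.n_cells_ever == 0:
        raise ValueError("empty lineage record")
    children: dict[int, list[int]] = defaultdict(list)
    for lab in range(1, record.n_cells_ever):
        children[record.parent[lab]].append(lab)

    def subtree(lab: int) -> str:
        kids = children.get(lab, [])
        suffix = f"{lab}" if lab == 0 else f"{lab}:{record.birth_time[lab]}"
        if not kids:
            return suffix
        return "(" + ",".join(subtree(k) for k in kids) + ")" + suffix

    return subtree(0) + ";"
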