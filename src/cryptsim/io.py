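"""File exports, configuration and deterministic fixture generation.

All tabular exports are UTF-8 CSV/TSV with a header row and "."
decimals, preceded by ``#``-prefixed provenance comment lines (package
version and the parameter JSON) so every artifact is reproducible
bit-for-bit from its own header.  Division events are exported with
separate parent/child columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .continuum import ContinuousParams, ContinuousState, integrate
from .lineage import (
    LinearRun,
    counts_by_generation,
    counts_by_state,
    lineage_to_newick,
    run_linear,
    total_cells,
)
from .rosette import RosetteRun, project_cylinder, run_rosette, run_steady_state
from .rules import RuleParameters, classify_age, CellState
from .sequences import table3

__all__ = [
    "write_events_tsv",
    "write_counts_csv",
    "write_snapshot_csv",
    "write_newick",
    "write_table3_csv",
    "write_trajectory_csv",
    "load_config",
    "save_config",
    "make_fixtures",
]


def _provenance(params_json: str | None) -> str:
    lines = [f"# cryptsim {__version__}"]
    if params_json is not None:
        lines.append(f"# params: {params_json}")
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path: Path, sep: str, params_json: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance(params_json))
        df.to_csv(fh, sep=sep, index=False, float_format="%.6f", lineterminator="\n")


def write_events_tsv(run: LinearRun | RosetteRun, path: str | Path) -> None:
    """Division events as TSV with columns (time, parent, child)."""
    rows = [
        (t, p, ch)
        for t, evs in enumerate(run.record.events)
        for p, ch in evs
    ]
    df = pd.DataFrame(rows, columns=["time", "parent", "child"])
    _write_frame(df, Path(path), "\t", run.params.to_json())


def write_counts_csv(run: LinearRun | RosetteRun, path: str | Path) -> None:
    """Counts per step: time, total, M, I, W and per-generation columns."""
    lin = run.as_linear() if isinstance(run, RosetteRun) else run
    max_g = max(lin.record.generation) if lin.record.generation else 0
    rows = []
    for t in range(lin.params.T + 1):
        sc = counts_by_state(lin, t)
        row = {
            "time": t,
            "total": total_cells(lin, t),
            "M": sc.M,
            "I": sc.I,
            "W": sc.W,
        }
        by_g = counts_by_generation(lin, t)
        for g in range(max_g + 1):
            row[f"gen_{g}"] = by_g.get(g, 0)
        rows.append(row)
    _write_frame(pd.DataFrame(rows), Path(path), ",", lin.params.to_json())


def write_snapshot_csv(
    run: RosetteRun,
    path: str | Path,
    t: int | None = None,
    cylinder_circumference: int | None = None,
) -> None:
    """One CSV row per live cell at step t (default: final step).

    Columns: time, label, state, generation, age, x, y,
    split_angle_index; with ``cylinder_circumference`` set, adds the 3D
    projection columns (angle_rad, height).
    """
    if t is None:
        t = run.params.T
    snap = run.snapshot_at(t)
    rec = run.record
    proj = (
        project_cylinder(run, cylinder_circumference, t)
        if cylinder_circumference is not None
        else None
    )
    rows = []
    for lab in sorted(snap.positions):
        age = t - rec.birth_time[lab]
        state = (
            CellState.CLONOGENIC
            if lab == 0
            else classify_age(age, rec.generation[lab], run.params)
        )
        x, y = snap.positions[lab]
        row = {
            "time": t,
            "label": lab,
            "state": state.name,
            "generation": rec.generation[lab],
            "age": age,
            "x": x,
            "y": y,
            "split_angle_index": snap.angles[lab],
        }
        if proj is not None:
            row["angle_rad"], row["height"] = proj[lab]
        rows.append(row)
    _write_frame(pd.DataFrame(rows), Path(path), ",", run.params.to_json())


def write_newick(run: LinearRun | RosetteRun, path: str | Path) -> None:
    """Lineage tree in Newick form (integer labels, birth-time branch lengths)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(lineage_to_newick(run.record) + "\n", encoding="utf-8")


def write_table3_csv(path: str | Path, c_max: int = 6) -> None:
    """Regenerate the discrete<->continuous correspondence table as CSV."""
    _write_frame(table3(c_max), Path(path), ",", None)


def write_trajectory_csv(
    params: ContinuousParams,
    init: ContinuousState,
    times,
    path: str | Path,
) -> None:
    """Integrate the compartment model and export (t, M, I, W1, W2)."""
    df = integrate(params, init, times)
    meta = json.dumps(
        {"params": params.__dict__, "init": init.__dict__}, sort_keys=True
    )
    _write_frame(df, Path(path), ",", meta)


def load_config(path: str | Path) -> RuleParameters:
    return RuleParameters.from_json(Path(path).read_text(encoding="utf-8"))


def save_config(params: RuleParameters, path: str | Path) -> None:
    Path(path).write_text(params.to_json() + "\n", encoding="utf-8")


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the canonical small runs used by the test suite.

    Byte-stable across runs: every simulator is deterministic and all
    floats are formatted to 6 decimals.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    lin = run_linear(RuleParameters(c=6, T=15))
    paths["linear_events"] = outdir / "linear_c6_T15_events.tsv"
    write_events_tsv(lin, paths["linear_events"])
    paths["linear_counts"] = outdir / "linear_c6_T15_counts.csv"
    write_counts_csv(lin, paths["linear_counts"])
    paths["linear_newick"] = outdir / "linear_c6_T15.nwk"
    write_newick(lin, paths["linear_newick"])

    ros = run_rosette(RuleParameters(c=6, T=12))
    paths["rosette_snapshot"] = outdir / "rosette_c6_T12_snapshot.csv"
    write_snapshot_csv(ros, paths["rosette_snapshot"])

    ss = run_steady_state(
        RuleParameters(c=6, n_wm0=11, L=35, steady_state=True, T=200)
    )
    paths["steady_counts"] = outdir / "steady_c6_L35_nwm11_T200_counts.csv"
    write_counts_csv(ss, paths["steady_counts"])
    paths["steady_snapshot"] = outdir / "steady_c6_L35_nwm11_T200_snapshot.csv"
    write_snapshot_csv(ss, paths["steady_snapshot"], cylinder_circumference=42)

    times = [float(t) for t in range(0, 51)]
    balanced = ContinuousParams(k1=1.0, k2=0.25, k3=0.5, k4=0.5, k5=0.2, k6=0.2)
    paths["ode_balanced"] = outdir / "ode_balanced.csv"
    write_trajectory_csv(balanced, ContinuousState(M=1.0, I=1.0), times, paths["ode_balanced"])
    growth = ContinuousParams(k1=1.0, k2=0.081338)
    paths["ode_growth"] = outdir / "ode_growth.csv"
    write_trajectory_csv(growth, ContinuousState(M=1.0), times, paths["ode_growth"])

    return paths
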