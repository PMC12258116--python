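"""Tests for the spatial rosette model: placement, displacement, symmetry,
steady-state boundedness and the cylinder projection."""

import math

import numpy as np
import pytest

from cryptsim import (
    CellState,
    RuleParameters,
    classify_age,
    project_cylinder,
    run_linear,
    run_rosette,
    run_steady_state,
    symmetry_order,
    total_cells,
)
from cryptsim.rosette import _ORIGIN_KEY, _key, _resolve_placement

# horizons chosen so the agent population stays modest per c
_EQUIV_T = {2: 13, 3: 16, 4: 18, 5: 20, 6: 20, 7: 20, 8: 20}


class TestPlacement:
    def test_single_daughter_adjacent_to_origin(self):
        run = run_rosette(RuleParameters(c=6, T=1))
        snap = run.snapshot_at(1)
        assert snap.n_cells == 2
        x, y = snap.positions[1]
        assert math.hypot(x, y) == pytest.approx(1.0)
        assert snap.positions[0] == (0.0, 0.0)

    def test_rotation_requires_divisor_of_full_turn(self):
        with pytest.raises(ValueError):
            run_rosette(RuleParameters(c=6, R_degrees=70.0, T=2))

    @pytest.mark.parametrize("c", sorted(_EQUIV_T))
    def test_counts_match_linear_model(self, c):
        # geometry never creates or destroys cells
        t_max = _EQUIV_T[c]
        ros = run_rosette(RuleParameters(c=c, T=t_max))
        lin = run_linear(RuleParameters(c=c, T=t_max))
        for t in range(t_max + 1):
            assert total_cells(ros.as_linear(), t) == total_cells(lin, t)
            assert ros.snapshot_at(t).n_cells == total_cells(lin, t)

    def test_occupancy_one_cell_per_position(self, rosette_c6_t12, steady_run):
        for run in (rosette_c6_t12, steady_run):
            for snap in run.snapshots:
                keys = {_key(x, y) for x, y in snap.positions.values()}
                assert len(keys) == snap.n_cells

    def test_clonogenic_holds_origin_forever(self, steady_run):
        for snap in steady_run.snapshots:
            assert _key(*snap.positions[0]) == _ORIGIN_KEY

    def test_chain_push_preserves_radial_order(self):
        # three cells in a row along +x; freeing the innermost slot shifts
        # the whole chain outward by one without reordering
        occ, pos = {}, {}
        for lab, x in [(1, 1.0), (2, 2.0), (3, 3.0)]:
            pos[lab] = (x, 0.0)
            occ[_key(x, 0.0)] = lab
        placed = _resolve_placement(occ, pos, (1.0, 0.0), (1.0, 0.0))
        assert placed == (1.0, 0.0)
        assert _key(*placed) not in occ
        assert [occ[_key(float(x), 0.0)] for x in (2, 3, 4)] == [1, 2, 3]

    def test_chain_push_skips_the_origin(self):
        # a chain aimed across the origin passes over it: the clonogenic
        # cell is immovable
        occ = {_ORIGIN_KEY: 0}
        pos = {0: (0.0, 0.0)}
        placed = _resolve_placement(occ, pos, (0.0, 0.0), (1.0, 0.0))
        assert _key(*placed) == _key(1.0, 0.0)
        assert occ[_ORIGIN_KEY] == 0


class TestSymmetry:
    def test_single_neighbor_has_no_rotational_symmetry(self):
        run = run_rosette(RuleParameters(c=6, T=1))
        assert symmetry_order(run, 1) == 1

    @pytest.mark.parametrize("c", [4, 6])
    def test_full_leaflet_ring_has_c_fold_symmetry(self, c):
        # after c steps the clonogenic cell has seeded one immature daughter
        # on each of the 360/R directions
        run = run_rosette(RuleParameters(c=c, T=c))
        assert symmetry_order(run, c) == c

    @pytest.mark.parametrize("c,t", [(4, 16), (6, 20)])
    def test_branches_are_approximately_c_fold_symmetric(self, c, t):
        # branches are seeded one per step, so the pattern is c-fold
        # symmetric only up to one step of development: rotating by 360/c
        # maps most occupied positions onto occupied positions, while a
        # half-increment rotation maps none
        run = run_rosette(RuleParameters(c=c, T=t))
        keys = {
            _key(x, y)
            for lab, (x, y) in run.snapshot_at(t).positions.items()
            if lab != 0
        }

        def overlap(theta):
            ct, st = math.cos(theta), math.sin(theta)
            return sum(
                1 for (x, y) in keys if _key(x * ct - y * st, x * st + y * ct) in keys
            ) / len(keys)

        assert overlap(2 * math.pi / c) > 0.6
        assert overlap(math.pi / c) == 0.0


class TestSteadyState:
    def test_requires_steady_schedule_and_finite_lifespan(self):
        with pytest.raises(ValueError):
            run_steady_state(RuleParameters(c=6, n_wm0=11, L=35, T=10))
        with pytest.raises(ValueError):
            run_steady_state(RuleParameters(c=6, steady_state=True, T=10))

    def test_population_bounded_and_trendless(self, steady_run):
        totals = np.array([s.n_cells for s in steady_run.snapshots])
        window = totals[105:]
        assert window.max() == window.min()  # exactly constant after transient
        slope = np.polyfit(np.arange(window.size), window, 1)[0]
        assert abs(slope) < 1e-9

    def test_dividing_region_persists_while_edges_die(self, steady_run):
        t = steady_run.params.T
        rec = steady_run.record
        snap = steady_run.snapshot_at(t)
        radii_by_state = {CellState.M: [], CellState.W: []}
        for lab, (x, y) in snap.positions.items():
            if lab == 0:
                continue
            s = classify_age(t - rec.birth_time[lab], rec.generation[lab], steady_run.params)
            if s in radii_by_state:
                radii_by_state[s].append(math.hypot(x, y))
        assert radii_by_state[CellState.M], "mature cells persist near the centre"
        assert max(radii_by_state[CellState.W]) > max(radii_by_state[CellState.M])
        # deaths do occur: some cells ever born are gone
        assert snap.n_cells < rec.n_cells_ever

    def test_zero_division_progeny_when_wm_equals_c(self):
        # n_wm0 = c: progeny never divide, the clonogenic cell is the only
        # producer, and the population settles at 1 + L live progeny
        p = RuleParameters(c=6, n_wm0=6, L=35, steady_state=True, T=50)
        run = run_steady_state(p)
        for t in range(51):
            expected = 1 + min(t, 35)
            assert run.snapshot_at(t).n_cells == expected

    def test_lifespan_limits_extent_not_dividing_region(self):
        def extents(L, T):
            run = run_steady_state(
                RuleParameters(c=6, n_wm0=11, L=L, steady_state=True, T=T)
            )
            rec = run.record
            snap = run.snapshot_at(T)
            all_r, m_r = [], []
            for lab, (x, y) in snap.positions.items():
                if lab == 0:
                    continue
                r = math.hypot(x, y)
                all_r.append(r)
                state = classify_age(T - rec.birth_time[lab], rec.generation[lab], run.params)
                if state is CellState.M:
                    m_r.append(r)
            return max(all_r), max(m_r)

        ext_short, div_short = extents(18, 150)
        ext_long, div_long = extents(35, 250)
        assert ext_long > ext_short + 5.0
        assert div_long == pytest.approx(div_short, rel=0.2)


class TestCylinderProjection:
    def test_origin_maps_to_zero_angle_and_height(self, rosette_c6_t12):
        proj = project_cylinder(rosette_c6_t12, 42)
        assert proj[0] == (0.0, 0.0)

    def test_x_is_periodic_in_circumference(self):
        circ = 42
        for x in (-3.5, 0.25, 17.0):
            a1 = 2 * math.pi * ((x % circ) / circ)
            a2 = 2 * math.pi * (((x + circ) % circ) / circ)
            assert a1 == pytest.approx(a2)

    def test_crypt_view_is_collision_free(self, steady_run):
        # the cell-level steady structure (t = 27) fits a 42-cell circumference
        proj = project_cylinder(steady_run, 42, t=27)
        coords = {(round(a, 9), round(h, 6)) for a, h in proj.values()}
        assert len(coords) == len(proj)

    def test_invalid_circumference_rejected(self, rosette_c6_t12):
        with pytest.raises(ValueError):
            project_cylinder(rosette_c6_t12, 0)
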