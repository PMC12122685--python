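"""Properties of the synthetic-data generators."""

import numpy as np
import pytest
from scipy.stats import chisquare

from icbkit.arenas import checking_platform, open_field
from icbkit.checking import build_zone_grid, detect_stops, identify_home_bases
from icbkit.spatial import cell_density
from icbkit.synthetic import (
    AgentParams,
    SectionGenParams,
    StateLogParams,
    TrajectoryParams,
    default_lesion_polygon,
    gen_choices,
    gen_sections,
    gen_state_log,
    gen_trajectory,
)
from icbkit.trajectory import total_distance


class TestTrajectoryGenerator:
    def test_reproducible_byte_for_byte(self, tmp_path):
        from icbkit.io import write_trajectory_csv

        p = TrajectoryParams(duration=120, seed=9, attraction_strength=2.0,
                             home_base_zones=(6,))
        for name in ("a", "b"):
            write_trajectory_csv(gen_trajectory(p), tmp_path / f"{name}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_zero_mobility_zero_distance(self):
        traj = gen_trajectory(TrajectoryParams(duration=60, mobility_fraction=0.0,
                                               seed=1))
        assert total_distance(traj) == 0.0

    def test_positions_inside_arena(self):
        p = TrajectoryParams(duration=300, mean_speed=30, mobility_fraction=0.9,
                             seed=2)
        traj = gen_trajectory(p)
        assert traj.arena.contains(traj.x, traj.y).all()
        assert np.allclose(np.diff(traj.t), 1 / p.sample_rate)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            gen_trajectory(TrajectoryParams(mean_speed=np.nan))
        with pytest.raises(ValueError):
            gen_trajectory(TrajectoryParams(mobility_fraction=1.5))

    def test_unbiased_walk_near_uniform_zone_occupancy(self):
        """Without attraction the walk shows no zone preference: a
        chi-square GOF on decorrelated samples over the interior 3 x 3
        zones passes for nearly all seeds."""
        grid = build_zone_grid()
        interior = [r * 5 + c for r in range(1, 4) for c in range(1, 4)]
        passed = 0
        n_seeds = 25
        for seed in range(n_seeds):
            p = TrajectoryParams(duration=2000, sample_rate=5,
                                 arena=checking_platform(),
                                 mobility_fraction=0.9, mean_speed=20,
                                 attraction_strength=0.0, seed=seed)
            traj = gen_trajectory(p)
            z = grid.zone_of(traj.x[::50], traj.y[::50])  # ~10 s apart
            counts = np.array([(z == k).sum() for k in interior])
            if counts.sum() < 50:
                continue
            if chisquare(counts).pvalue > 0.01:
                passed += 1
        assert passed >= int(0.85 * n_seeds)

    def test_attraction_concentrates_stop_time(self):
        """With strong attraction the planted zone accumulates the
        largest total stop duration (recomputed by brute force)."""
        grid = build_zone_grid()
        p = TrajectoryParams(duration=600, sample_rate=5,
                             arena=checking_platform(), home_base_zones=(6,),
                             attraction_strength=5.0, mobility_fraction=0.5,
                             visit_dwell_mean=3.0, seed=4)
        traj = gen_trajectory(p)
        stops = detect_stops(traj, grid)
        totals = {}
        for s in stops:
            totals[s.zone] = totals.get(s.zone, 0.0) + s.duration
        assert max(totals, key=totals.get) == 6
        assert identify_home_bases(stops, grid)[0] == 6


class TestStateLogGenerator:
    def test_single_state_one_bout_per_window(self):
        p = StateLogParams(states=("rearing",), bout_mean={"rearing": 2.0},
                           n_windows=4, seed=0)
        logs = gen_state_log(p)
        for log in logs:
            assert len(log.events) == 1
            assert log.events[0][2] - log.events[0][1] == pytest.approx(50.0)

    def test_events_tile_each_window(self):
        p = StateLogParams(
            states=("locomoting", "rearing", "grooming"),
            bout_mean={"locomoting": 2.0, "rearing": 1.0, "grooming": 3.0},
            n_windows=6, seed=3,
        )
        for log in gen_state_log(p):
            assert log.events[0][1] == 0.0
            assert log.events[-1][2] == pytest.approx(50.0)
            for (s1, a1, b1), (s2, a2, b2) in zip(log.events, log.events[1:]):
                assert a2 == pytest.approx(b1)
                assert s2 != s1  # merged semi-Markov bouts

    def test_empty_state_list_rejected(self):
        with pytest.raises(ValueError):
            gen_state_log(StateLogParams(states=(), bout_mean={}))

    def test_bad_transition_matrix_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            gen_state_log(StateLogParams(
                states=("rearing", "grooming"),
                bout_mean={"rearing": 1.0, "grooming": 1.0},
                transition_matrix=np.array([[0.5, 0.4], [1.0, 0.0]]),
            ))

    def test_reproducible(self):
        p = StateLogParams(states=("rearing", "grooming"),
                           bout_mean={"rearing": 1.0, "grooming": 2.0}, seed=7)
        a = gen_state_log(p)
        b = gen_state_log(p)
        assert [l.events for l in a] == [l.events for l in b]


class TestChoiceGenerator:
    def test_reproducible(self):
        p = AgentParams(seed=11)
        assert [(r.arm, r.pellets) for r in gen_choices(p)] == [
            (r.arm, r.pellets) for r in gen_choices(p)
        ]

    def test_invalid_learning_rate(self):
        with pytest.raises(ValueError):
            gen_choices(AgentParams(learning_rate=1.5))


class TestSectionGenerator:
    def test_zero_intensity_zero_cells(self):
        secs = gen_sections(SectionGenParams(base_intensity=0.0, n_animals=1,
                                             seed=0))
        assert all(len(s.cells) == 0 for s in secs)

    def test_cells_inside_outline(self):
        secs = gen_sections(SectionGenParams(n_animals=1, seed=1))
        for s in secs:
            assert s.validate_cells(tol_um=5.0) == 0

    def test_poisson_count_scale(self):
        """Homogeneous sections: counts match intensity x area."""
        from shapely.geometry import Polygon

        secs = gen_sections(SectionGenParams(base_intensity=100.0, jitter=0.0,
                                             n_animals=4, seed=2))
        counts = [len(s.cells) for s in secs]
        expected = 100.0 * Polygon(
            SectionGenParams().outline_template).area / 1e6
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)

    def test_homogeneous_pattern_is_csr(self):
        """No pattern weights: quadrat counts are consistent with
        complete spatial randomness for nearly all seeds."""
        from shapely import contains_xy
        from shapely.geometry import Polygon

        passed = 0
        n_seeds = 20
        for seed in range(n_seeds):
            secs = gen_sections(SectionGenParams(
                base_intensity=150.0, jitter=0.0, placement_rotation=0.0,
                placement_scale=0.0, placement_shift=0.0, n_animals=1,
                levels_per_animal=1, hemispheres=1, seed=seed))
            s = secs[0]
            poly = Polygon(s.outline)
            # quadrats fully inside the outline only
            xs = np.linspace(-1500, 1500, 7)
            counts = []
            for i in range(6):
                for j in range(6):
                    x0, x1 = xs[i], xs[i + 1]
                    y0, y1 = xs[j], xs[j + 1]
                    corners_in = contains_xy(
                        poly, [x0, x1, x0, x1], [y0, y0, y1, y1]
                    ).all()
                    if not corners_in:
                        continue
                    inside = (
                        (s.cells[:, 0] >= x0) & (s.cells[:, 0] < x1)
                        & (s.cells[:, 1] >= y0) & (s.cells[:, 1] < y1)
                    )
                    counts.append(inside.sum())
            if len(counts) >= 5 and chisquare(counts).pvalue > 0.01:
                passed += 1
        assert passed >= int(0.85 * n_seeds)

    def test_hotspot_raises_density_inside_lesion(self):
        secs = gen_sections(SectionGenParams(
            pattern_weights={"lesion_hotspot": 1.0},
            lesion_polygon=default_lesion_polygon(), jitter=0.0,
            placement_rotation=0.0, placement_scale=0.0, placement_shift=0.0,
            n_animals=1, levels_per_animal=1, hemispheres=1, seed=3))
        s = secs[0]
        assert cell_density(s, "lesioned") > cell_density(s, "total")

    def test_hemispheres_mirror(self):
        secs = gen_sections(SectionGenParams(n_animals=1, levels_per_animal=1,
                                             jitter=0.0, placement_rotation=0.0,
                                             placement_scale=0.0,
                                             placement_shift=0.0, seed=4))
        left = next(s for s in secs if s.hemisphere == "left")
        right = next(s for s in secs if s.hemisphere == "right")
        assert np.allclose(
            sorted(left.outline[:, 0]), sorted(-right.outline[:, 0])
        )

    def test_degenerate_outline_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="degenerate"):
            gen_sections(SectionGenParams(outline_template=line))
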