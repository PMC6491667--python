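"""Content and structure measures against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from ssgrid import (
    Codebook,
    Dimension,
    Event,
    Trajectory,
    ValidationError,
    Visit,
    VisitSequence,
    axis_profile,
    cell_stats,
    dispersion,
    duration_entropy,
    grid_measures,
    make_state_space,
    measures_frame,
    pooled_measures,
    region_stats,
    share_sd,
    to_visits,
    transition_entropy,
    visit_entropy,
)

import oracles
from factories import make_random_trajectory


def small_space(nx=3, ny=3):
    cb = Codebook(
        (
            Dimension("d1", tuple(f"x{i}" for i in range(nx))),
            Dimension("d2", tuple(f"y{i}" for i in range(ny))),
        )
    )
    return cb, make_state_space(cb, "d1", "d2")


def vs_from_durations(durations, nx=None):
    """A visit sequence visiting distinct cells once with given durations."""
    k = len(durations)
    cb, space = small_space(k, 2)
    visits = []
    t = 0.0
    for i, d in enumerate(durations):
        visits.append(Visit((i, 0), t, float(d), 1))
        t += d
    return VisitSequence(tuple(visits), "synthetic", space)


class TestCellStats:
    def test_worked_example_visit_multiset(self, example_visits):
        """Three cells visited twice, four once, eighteen never."""
        df = cell_stats(example_visits)
        counts = df["visits"].value_counts().to_dict()
        assert counts == {0.0: 18, 1.0: 4, 2.0: 3}
        assert df["event_proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert df["duration_proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_visit_full_proportion(self):
        cb, space = small_space()
        traj = Trajectory("t", cb, [Event(0.0, ("x0", "y0"))], offset=4.0)
        df = cell_stats(to_visits(traj, space))
        assert df.loc[(0, 0), "duration_proportion"] == pytest.approx(1.0)
        assert df.loc[(0, 0), "mean_duration_per_visit"] == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(0, 100, 5))
    def test_matches_event_loop_oracle(self, seed):
        traj, space = make_random_trajectory(seed)
        df = cell_stats(to_visits(traj, space))
        ev, vis, dur = oracles.cell_tallies(traj, space)
        for cell in space.cells():
            assert df.loc[cell, "events"] == ev.get(cell, 0)
            assert df.loc[cell, "visits"] == vis.get(cell, 0)
            assert df.loc[cell, "total_duration"] == pytest.approx(
                dur.get(cell, 0.0), abs=1e-9
            )
        # mean duration consistency where visited
        visited = df[df["visits"] > 0]
        np.testing.assert_allclose(
            visited["mean_duration_per_visit"] * visited["visits"],
            visited["total_duration"],
            atol=1e-9,
        )


class TestRegionStats:
    def test_speaker_column_time_share(self):
        """Speaker holding 30 of 40 s takes 75% of the floor."""
        cb = Codebook(
            (Dimension("speaker", ("A", "B")), Dimension("beh", ("talk", "other")))
        )
        space = make_state_space(cb, "speaker", "beh")
        events = [
            Event(0.0, ("A", "talk")),
            Event(20.0, ("B", "talk")),
            Event(30.0, ("A", "other")),
        ]
        traj = Trajectory("t", cb, events, offset=40.0)
        vs = to_visits(traj, space)
        rs = region_stats(vs, space.column("A"))
        assert rs.total_duration == pytest.approx(30.0)
        assert rs.duration_proportion == pytest.approx(0.75)
        assert rs.events == 2

    def test_equal_shares_have_zero_sd(self):
        cb = Codebook(
            (Dimension("speaker", ("A", "B")), Dimension("beh", ("t1", "t2")))
        )
        space = make_state_space(cb, "speaker", "beh")
        events = [Event(0.0, ("A", "t1")), Event(10.0, ("B", "t2"))]
        traj = Trajectory("t", cb, events, offset=20.0)
        assert share_sd(to_visits(traj, space)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(0, 60, 6))
    def test_column_aggregates_match_oracle(self, seed):
        traj, space = make_random_trajectory(seed)
        vs = to_visits(traj, space)
        profile = axis_profile(vs, "x")
        for i, label in enumerate(space.x_dim.categories):
            want = oracles.region_tallies(traj, space, space.column(i))
            assert profile.loc[label, "events"] == want["events"]
            assert profile.loc[label, "visits"] == want["visits"]
            assert profile.loc[label, "total_duration"] == pytest.approx(
                want["duration"], abs=1e-9
            )
        assert share_sd(vs, "x") == pytest.approx(
            oracles.column_share_sd(traj, space, "x"), abs=1e-9
        )

    def test_rejects_bad_regions(self, example_visits):
        with pytest.raises(ValidationError, match="empty"):
            region_stats(example_visits, [])
        with pytest.raises(ValidationError, match="unknown"):
            region_stats(example_visits, [(99, 0)])


class TestDispersion:
    def test_all_time_in_one_cell_is_zero(self):
        cb, space = small_space(4, 4)
        single = VisitSequence((Visit((1, 2), 0.0, 7.0, 1),), "t", space)
        assert dispersion(single) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_over_all_cells_is_one(self):
        """Time spread evenly over every cell of a 5x5 space."""
        cb, space = small_space(5, 5)
        visits = []
        t = 0.0
        for i, cell in enumerate(space.cells()):
            visits.append(Visit(cell, t, 2.0, 1))
            t += 2.0
        vs = VisitSequence(tuple(visits), "t", space)
        assert dispersion(vs) == pytest.approx(1.0, abs=1e-12)

    def test_thousand_random_vectors_match_formula(self):
        """1 - (n sum p^2 - 1)/(n - 1) on random duration vectors."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 11))
            durations = rng.uniform(0.1, 10.0, size=k)
            vs = vs_from_durations(durations)
            n = vs.space.n_cells
            want = oracles.dispersion_from_durations(durations, n)
            assert dispersion(vs) == pytest.approx(want, abs=1e-9)

    def test_moving_time_to_empty_cell_raises_dispersion(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            durations = list(rng.uniform(1.0, 5.0, size=k)) + [0.0]
            before = oracles.dispersion_from_durations(durations, 2 * (k + 1))
            moved = list(durations)
            top = max(range(k), key=lambda i: moved[i])
            quantum = moved[top] / 2
            moved[top] -= quantum
            moved[-1] += quantum
            after = oracles.dispersion_from_durations(moved, 2 * (k + 1))
            assert after > before


class TestEntropies:
    def test_worked_example_visit_entropy(self, example_visits):
        """Visit proportions {0.2 x3, 0.1 x4} give 1.89 nats."""
        assert visit_entropy(example_visits) == pytest.approx(1.89, abs=0.005)

    def test_single_cell_zero_entropy(self):
        cb, space = small_space()
        traj = Trajectory("t", cb, [Event(0.0, ("x0", "y0"))], offset=3.0)
        vs = to_visits(traj, space)
        assert visit_entropy(vs) == 0.0
        assert duration_entropy(vs) == 0.0

    @pytest.mark.parametrize("k", range(2, 11))
    def test_uniform_visits_reach_ln_k(self, k):
        vs = vs_from_durations([1.0] * k)
        assert visit_entropy(vs) == pytest.approx(math.log(k), abs=1e-12)
        assert duration_entropy(vs) == pytest.approx(math.log(k), abs=1e-12)

    def test_transition_entropy_needs_transitions(self):
        cb, space = small_space()
        traj = Trajectory("t", cb, [Event(0.0, ("x0", "y0"))], offset=3.0)
        with pytest.raises(ValidationError, match="no transitions"):
            transition_entropy(to_visits(traj, space))


class TestGridMeasures:
    def test_worked_example_bundle(self, example_visits):
        gm = grid_measures(example_visits)
        assert gm.cell_range == 7
        assert gm.n_transitions == 9
        assert gm.n_visits == 10
        assert gm.n_events == 10
        space_cells = example_visits.space.n_cells
        assert space_cells - gm.cell_range == 18

    def test_alternating_sequence(self):
        cb, space = small_space(2, 1)
        events = [
            Event(float(i), (f"x{i % 2}", "y0")) for i in range(10)
        ]
        traj = Trajectory("t", cb, events, offset=10.0)
        gm = grid_measures(to_visits(traj, space))
        assert gm.cell_range == 2 and gm.n_transitions == 9

    def test_entropy_bounds(self, random_pool):
        for traj, space in random_pool[:30]:
            gm = grid_measures(to_visits(traj, space))
            assert 0.0 <= gm.dispersion <= 1.0 + 1e-12
            assert gm.visit_entropy <= math.log(gm.cell_range) + 1e-9
            assert gm.duration_entropy <= math.log(gm.cell_range) + 1e-9

    def test_oracle_equivalence_full_pool(self, random_pool):
        """Every structure measure matches the brute-force oracle on 100
        random trajectories."""
        for traj, space in random_pool:
            gm = grid_measures(to_visits(traj, space))
            want = oracles.grid_measures(traj, space)
            assert gm.n_events == want["n_events"]
            assert gm.n_visits == want["n_visits"]
            assert gm.n_transitions == want["n_transitions"]
            assert gm.cell_range == want["cell_range"]
            assert gm.dispersion == pytest.approx(want["dispersion"], abs=1e-9)
            assert gm.visit_entropy == pytest.approx(want["visit_entropy"], abs=1e-9)
            assert gm.duration_entropy == pytest.approx(
                want["duration_entropy"], abs=1e-9
            )
            assert gm.transition_entropy == pytest.approx(
                want["transition_entropy"], abs=1e-9
            )

    def test_axis_permutation_invariance(self):
        """Relabeling both axes by a permutation leaves measures unchanged."""
        traj, space = make_random_trajectory(17)
        gm = grid_measures(to_visits(traj, space))
        rng = np.random.default_rng(0)
        perm_x = rng.permutation(len(space.x_dim.categories))
        perm_y = rng.permutation(len(space.y_dim.categories))
        new_x = tuple(space.x_dim.categories[i] for i in perm_x)
        new_y = tuple(space.y_dim.categories[i] for i in perm_y)
        cb2 = Codebook((Dimension("dimx", new_x), Dimension("dimy", new_y)))
        traj2 = Trajectory(traj.id, cb2, list(traj.events), traj.offset)
        space2 = make_state_space(cb2, "dimx", "dimy")
        gm2 = grid_measures(to_visits(traj2, space2))
        assert gm2.allclose(gm)

    def test_time_translation_and_scaling_invariance(self):
        traj, space = make_random_trajectory(23)
        gm = grid_measures(to_visits(traj, space))
        shifted = Trajectory(
            traj.id,
            traj.codebook,
            [Event(e.onset + 500.0, e.values) for e in traj.events],
            traj.offset + 500.0,
        )
        assert grid_measures(to_visits(shifted, space)).allclose(gm)
        scaled = Trajectory(
            traj.id,
            traj.codebook,
            [Event(e.onset * 3.0, e.values) for e in traj.events],
            traj.offset * 3.0,
        )
        gs = grid_measures(to_visits(scaled, space))
        assert gs.dispersion == pytest.approx(gm.dispersion, abs=1e-9)
        assert gs.duration_entropy == pytest.approx(gm.duration_entropy, abs=1e-9)
        assert (gs.n_events, gs.n_visits, gs.cell_range) == (
            gm.n_events,
            gm.n_visits,
            gm.cell_range,
        )


class TestPooled:
    def test_pool_of_one_equals_single(self):
        traj, space = make_random_trajectory(2)
        vs = to_visits(traj, space)
        pooled, per_traj = pooled_measures([vs])
        assert pooled.allclose(grid_measures(vs))
        assert len(per_traj) == 1

    def test_two_identical_trajectories_keep_proportions(self):
        traj, space = make_random_trajectory(4)
        vs = to_visits(traj, space)
        single = grid_measures(vs)
        pooled, _ = pooled_measures([vs, vs])
        assert pooled.n_visits == 2 * single.n_visits
        assert pooled.n_transitions == 2 * single.n_transitions
        assert pooled.dispersion == pytest.approx(single.dispersion, abs=1e-9)
        assert pooled.visit_entropy == pytest.approx(single.visit_entropy, abs=1e-9)
        assert pooled.duration_entropy == pytest.approx(
            single.duration_entropy, abs=1e-9
        )

    def test_pooled_entropy_matches_concatenated_tallies(self):
        """Pooled entropies equal an oracle run on summed tallies."""
        cb, space = small_space(4, 4)
        from ssgrid import SynthConfig, simulate

        seqs = []
        tallies_v, tallies_d = {}, {}
        n_trans = 0
        for seed in (31, 32):
            traj = simulate(
                SynthConfig(space=space, n_visits=60, seed=seed, dwell_mean=2.0)
            )
            seqs.append(to_visits(traj, space))
            _, vis, dur = oracles.cell_tallies(traj, space)
            for c, v in vis.items():
                tallies_v[c] = tallies_v.get(c, 0) + v
            for c, d in dur.items():
                tallies_d[c] = tallies_d.get(c, 0.0) + d
            n_trans += len(oracles.rle_visits(traj, space)) - 1
        pooled, _ = pooled_measures(seqs)
        assert pooled.n_transitions == n_trans
        assert pooled.visit_entropy == pytest.approx(
            oracles.shannon(tallies_v.values()), abs=1e-9
        )
        assert pooled.duration_entropy == pytest.approx(
            oracles.shannon(tallies_d.values()), abs=1e-9
        )


def test_measures_frame_roundtrips_through_csv(tmp_path, random_pool):
    import pandas as pd

    seqs = [to_visits(t, s) for t, s in random_pool[:5]]
    df = measures_frame(seqs)
    path = tmp_path / "measures.csv"
    df.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert len(back) == 5
    for col in ("dispersion", "visit_entropy", "n_transitions"):
        np.testing.assert_allclose(back[col], df[col], atol=1e-12)
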