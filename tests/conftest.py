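import pytest

from ssgrid import brainstorming_example, team_meeting_fixture, to_visits

from factories import make_random_trajectory


@pytest.fixture(scope="session")
def brainstorm():
    """The 10-event worked-example trajectory and its 5x5 space."""
    return brainstorming_example()


@pytest.fixture(scope="session")
def example_visits(brainstorm):
    traj, space = brainstorm
    return to_visits(traj, space)


@pytest.fixture(scope="session")
def team_meetings():
    """Two synthetic 55-min team meetings (concentrated vs. even floor)."""
    return team_meeting_fixture(seed=0)


@pytest.fixture(scope="session")
def random_pool():
    """100 random synthetic trajectories for oracle-equivalence checks."""
    return [make_random_trajectory(seed) for seed in range(100)]
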