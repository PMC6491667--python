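"""Randomized trajectory factories shared across test modules."""

import numpy as np

from ssgrid import Codebook, Dimension, SynthConfig, make_state_space, simulate


def random_space(rng):
    nx = int(rng.integers(2, 6))
    ny = int(rng.integers(2, 8))
    cb = Codebook(
        (
            Dimension("dimx", tuple(f"x{i}" for i in range(nx))),
            Dimension("dimy", tuple(f"y{i}" for i in range(ny))),
        )
    )
    return make_state_space(cb, "dimx", "dimy")


def make_random_trajectory(seed):
    """One random session: random grid shape, attractor weights, dwell law,
    and a split rate so events outnumber visits."""
    rng = np.random.default_rng(seed)
    space = random_space(rng)
    cells = space.cells()
    n_boost = int(rng.integers(0, min(4, len(cells))))
    picks = rng.choice(len(cells), size=n_boost, replace=False)
    weights = {cells[int(i)]: float(rng.uniform(0.5, 8.0)) for i in picks}
    config = SynthConfig(
        space=space,
        cell_weights=weights,
        dwell_mean=float(rng.uniform(1.5, 8.0)),
        dwell_distribution=str(rng.choice(["exponential", "gamma", "fixed"])),
        n_visits=int(rng.integers(20, 120)),
        split_rate=0.3,
        seed=int(rng.integers(0, 2**31 - 1)),
        trajectory_id=f"rand-{seed}",
    )
    return simulate(config), space
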