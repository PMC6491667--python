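"""Synthetic coded-interaction trajectories with controllable attractors.

Generation follows an embedded Markov chain over grid cells: the visited
cell sequence is drawn from a row-stochastic transition matrix whose
diagonal is zero (a visit ends only by changing cell — self-persistence is
modeled through the dwell-time distribution, not diagonal mass), and each
visit's dwell time is drawn from an exponential (default), gamma, or fixed
distribution. All randomness flows from one explicit seed.

The module also ships two reference fixtures: a 10-event brainstorming
example on a 5x5 talk-by-energy grid whose count-based measures are known
in closed form, and a pair of synthetic ~55-minute team meetings on a
5-speaker x 7-behavior grid (one with a concentrated conversational floor
and sticky relational interaction, one with an evenly shared floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .codebook import Codebook, Dimension
from .errors import ValidationError
from .grid import Cell, StateSpace, make_state_space
from .trajectory import Event, Trajectory, TrajectoryCollection

__all__ = [
    "SynthConfig",
    "simulate",
    "attractor_matrix",
    "stationary_distribution",
    "brainstorming_example",
    "brainstorming_codebook",
    "team_meeting_fixture",
    "team_meeting_codebook",
]


def _space_codebook(space: StateSpace) -> Codebook:
    return Codebook((space.x_dim, space.y_dim))


def attractor_matrix(
    space: StateSpace,
    cell_weights: dict[Cell, float] | None = None,
    row_stickiness: dict[int, float] | None = None,
) -> np.ndarray:
    """Build a row-stochastic transition matrix from attractor weights.

    Every cell gets baseline weight 1 plus any boost from ``cell_weights``;
    the probability of moving to cell *j* is proportional to *j*'s weight
    (never back to the current cell: the diagonal is zero).
    ``row_stickiness`` multiplies the weight of targets sharing the current
    cell's y category, producing within-row runs such as sustained
    relational exchanges.
    """
    cells = space.cells()
    n = len(cells)
    w = np.ones(n)
    for cell, boost in (cell_weights or {}).items():
        w[cells.index(tuple(cell))] += boost
    P = np.tile(w, (n, 1))
    if row_stickiness:
        for i, ci in enumerate(cells):
            factor = row_stickiness.get(ci[1])
            if factor:
                for j, cj in enumerate(cells):
                    if cj[1] == ci[1]:
                        P[i, j] *= factor
    np.fill_diagonal(P, 0.0)
    return P / P.sum(axis=1, keepdims=True)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary visit distribution of the embedded chain (pi = pi P)."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class SynthConfig:
    """Parameters of one simulated observation session.

    Either pass a full ``transition_matrix`` (row-stochastic, zero
    diagonal, indexed in :meth:`StateSpace.cells` order) or describe the
    attractor structure with ``cell_weights``/``row_stickiness`` and let
    :func:`attractor_matrix` build the matrix. The session length is fixed
    by ``n_visits`` or by ``horizon_seconds`` (whichever is given;
    ``n_visits`` wins if both are set).

    ``dwell_mean`` (seconds) may be a scalar or a per-cell mapping;
    ``split_rate`` is the probability that a visit is emitted as two
    consecutive same-cell events rather than one, exercising the
    event/visit distinction downstream.
    """

    space: StateSpace
    transition_matrix: np.ndarray | None = None
    cell_weights: dict[Cell, float] = field(default_factory=dict)
    row_stickiness: dict[int, float] = field(default_factory=dict)
    dwell_mean: float | dict[Cell, float] = 4.5
    dwell_distribution: str = "exponential"  # exponential | gamma | fixed
    gamma_shape: float = 2.0
    n_visits: int | None = None
    horizon_seconds: float | None = None
    split_rate: float = 0.0
    seed: int = 0
    trajectory_id: str = "sim"

    def matrix(self) -> np.ndarray:
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
            n = self.space.n_cells
            if P.shape != (n, n):
                raise ValidationError(
                    f"transition matrix shape {P.shape} does not match {n} cells"
                )
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError("transition matrix rows must sum to 1")
            if np.any(np.diag(P) != 0):
                raise ValidationError(
                    "transition matrix diagonal must be 0 (a visit ends only "
                    "by changing cell)"
                )
            return P
        return attractor_matrix(self.space, self.cell_weights, self.row_stickiness)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        """Load a config from YAML (dimensions inline; weights by labels)."""
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        dims = [Dimension(d["name"], tuple(d["categories"])) for d in doc["dimensions"]]
        cb = Codebook(tuple(dims))
        space = make_state_space(cb, doc.get("x", dims[0].name), doc.get("y", dims[1].name))
        weights = {}
        for entry in doc.get("cell_weights", []):
            cell = space.cell_of(entry["x"], entry["y"])
            weights[cell] = float(entry["weight"])
        stick = {
            space.y_dim.index(k): float(v)
            for k, v in doc.get("row_stickiness", {}).items()
        }
        return cls(
            space=space,
            cell_weights=weights,
            row_stickiness=stick,
            dwell_mean=doc.get("dwell_mean", 4.5),
            dwell_distribution=doc.get("dwell_distribution", "exponential"),
            gamma_shape=doc.get("gamma_shape", 2.0),
            n_visits=doc.get("n_visits"),
            horizon_seconds=doc.get("horizon_seconds"),
            split_rate=doc.get("split_rate", 0.0),
            seed=doc.get("seed", 0),
            trajectory_id=doc.get("trajectory_id", "sim"),
        )


def _dwell(rng: np.random.Generator, config: SynthConfig, cell: Cell) -> float:
    mean = config.dwell_mean
    if isinstance(mean, dict):
        mean = mean.get(cell, 4.5)
    if mean <= 0:
        raise ValidationError("dwell_mean must be positive")
    kind = config.dwell_distribution
    if kind == "exponential":
        d = rng.exponential(mean)
    elif kind == "gamma":
        d = rng.gamma(config.gamma_shape, mean / config.gamma_shape)
    elif kind == "fixed":
        d = mean
    else:
        raise ValidationError(f"unknown dwell distribution {kind!r}")
    return max(d, 1e-6)  # dwell must stay strictly positive


def simulate(config: SynthConfig) -> Trajectory:
    """Draw one trajectory from the configured chain, deterministically
    given ``config.seed``."""
    if config.n_visits is None and config.horizon_seconds is None:
        raise ValidationError("set n_visits or horizon_seconds")
    P = config.matrix()
    cells = config.space.cells()
    rng = np.random.default_rng(config.seed)
    start_w = np.ones(len(cells))
    for cell, boost in config.cell_weights.items():
        start_w[cells.index(tuple(cell))] += boost
    state = int(rng.choice(len(cells), p=start_w / start_w.sum()))

    visit_cells: list[Cell] = []
    dwells: list[float] = []
    total = 0.0
    by_horizon = config.n_visits is None
    while True:
        cell = cells[state]
        d = _dwell(rng, config, cell)
        if by_horizon:
            d = min(d, config.horizon_seconds - total)  # truncate final dwell
        visit_cells.append(cell)
        dwells.append(d)
        total += d
        if config.n_visits is not None and len(visit_cells) >= config.n_visits:
            break
        if by_horizon and total >= config.horizon_seconds:
            break
        state = int(rng.choice(len(cells), p=P[state]))

    cb = _space_codebook(config.space)
    events: list[Event] = []
    t = 0.0
    for cell, d in zip(visit_cells, dwells):
        labels = config.space.labels_of(cell)
        if config.split_rate > 0 and d > 2e-6 and rng.random() < config.split_rate:
            cut = d * rng.uniform(0.25, 0.75)
            events.append(Event(t, labels))
            events.append(Event(t + cut, labels))
        else:
            events.append(Event(t, labels))
        t += d
    return Trajectory(id=config.trajectory_id, codebook=cb, events=events, offset=t)


# ---------------------------------------------------------------------------
# Reference fixtures
# ---------------------------------------------------------------------------

TALK_CODES = ("support", "idea expression", "neutral statement", "idea blocking", "criticism")
ENERGY_CODES = ("high negativity", "low negativity", "neutral", "low positivity", "high positivity")


def brainstorming_codebook() -> Codebook:
    """Coded talk x energy level, five ordered categories each."""
    return Codebook(
        (Dimension("energy", ENERGY_CODES), Dimension("talk", TALK_CODES))
    )


def brainstorming_example() -> tuple[Trajectory, StateSpace]:
    """The 10-event hypothetical brainstorming session on a 5x5 grid.

    Unit-duration events, every event entering a new cell, so events ==
    visits == 10 and transitions == 9. Seven distinct cells are visited
    with visit multiset {2, 2, 2, 1, 1, 1, 1}: visit entropy is
    -(3 * 0.2 ln 0.2 + 4 * 0.1 ln 0.1) ~= 1.89 nats and 18 of the 25
    states stay unvisited. The session opens with a neutral statement in a
    neutral tone, followed by an idea expressed in a low positive tone;
    ideas and support carry positive energy, blocking and criticism
    negative energy.
    """
    cb = brainstorming_codebook()
    space = make_state_space(cb, "energy", "talk")
    seq = [
        ("neutral", "neutral statement"),        # twice-visited cell A
        ("low positivity", "idea expression"),   # once
        ("high positivity", "support"),          # twice-visited cell B
        ("neutral", "neutral statement"),
        ("high positivity", "idea expression"),  # twice-visited cell C
        ("high positivity", "support"),
        ("low negativity", "idea blocking"),     # once
        ("high positivity", "idea expression"),
        ("high negativity", "criticism"),        # once
        ("low negativity", "criticism"),         # once
    ]
    events = [Event(float(i), labels) for i, labels in enumerate(seq)]
    traj = Trajectory(id="brainstorming-example", codebook=cb, events=events, offset=10.0)
    return traj, space


SPEAKERS = ("A", "B", "C", "D", "E")
BEHAVIOR_CODES = ("KnowEx", "ProbSolve", "Struct", "TakeAction", "Relat", "CMB", "Other")


def team_meeting_codebook() -> Codebook:
    """Five speakers x seven functional behavior codes."""
    return Codebook(
        (Dimension("speaker", SPEAKERS), Dimension("behavior", BEHAVIOR_CODES))
    )


def team_meeting_fixture(seed: int = 0) -> tuple[TrajectoryCollection, StateSpace]:
    """Two synthetic ~55-minute team meetings on the 5x7 speaker grid.

    ``concentrated``: speakers C and E dominate the floor and relational
    contributions tend to follow relational contributions (sticky
    relational row). ``even``: uniform transition structure, evenly shared
    floor. Mean dwell 4.5 s (exponential), horizon 55 min; a 10% split
    rate emits some visits as two same-cell events. Both teams remain in
    the flexible-interaction regime (dispersion above 0.9); the
    concentrated team's per-speaker time shares have the larger SD.
    """
    cb = team_meeting_codebook()
    space = make_state_space(cb, "speaker", "behavior")
    relat_row = space.y_dim.index("Relat")
    horizon = 55.0 * 60.0

    concentrated_weights: dict[Cell, float] = {}
    for y in range(len(BEHAVIOR_CODES)):
        concentrated_weights[(space.x_dim.index("C"), y)] = 1.6
        concentrated_weights[(space.x_dim.index("E"), y)] = 1.2
        concentrated_weights[(space.x_dim.index("A"), y)] = -0.5

    teams = []
    for name, weights, stickiness, team_seed in (
        ("concentrated", concentrated_weights, {relat_row: 3.0}, seed * 2 + 1),
        ("even", {}, {}, seed * 2 + 2),
    ):
        config = SynthConfig(
            space=space,
            cell_weights=weights,
            row_stickiness=stickiness,
            dwell_mean=4.5,
            dwell_distribution="exponential",
            horizon_seconds=horizon,
            split_rate=0.1,
            seed=team_seed,
            trajectory_id=name,
        )
        teams.append(simulate(config))
    return TrajectoryCollection(teams), space
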