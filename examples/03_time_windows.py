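"""Time-slider analysis: measures for nested windows of one meeting.

Simulates a ~55-minute session and computes grid measures for the first
5 minutes, the first 20 minutes, and the whole meeting — the protocol for
watching an interaction pattern build up over time.
"""

from ssgrid import (
    SynthConfig,
    grid_measures,
    slice_trajectory,
    to_visits,
)
from ssgrid.synth import team_meeting_codebook
from ssgrid import make_state_space

cb = team_meeting_codebook()
space = make_state_space(cb, "speaker", "behavior")
config = SynthConfig(
    space=space,
    cell_weights={(2, y): 1.5 for y in range(7)},  # speaker C dominates
    dwell_mean=4.5,
    horizon_seconds=55 * 60,
    seed=42,
    trajectory_id="meeting",
)
from ssgrid import simulate

traj = simulate(config)

print(f"{'window':>12} {'events':>7} {'visits':>7} {'cell range':>11} "
      f"{'dispersion':>11} {'visit H':>8}")
for label, t1 in (("first 5 min", 300.0), ("first 20 min", 1200.0),
                  ("full meeting", traj.offset)):
    piece = slice_trajectory(traj, 0.0, t1)
    gm = grid_measures(to_visits(piece, space))
    print(f"{label:>12} {gm.n_events:>7} {gm.n_visits:>7} "
          f"{gm.cell_range:>11} {gm.dispersion:>11.3f} "
          f"{gm.visit_entropy:>8.2f}")

# Cell range and entropy grow as the window widens: early windows show a
# sparse, more predictable grid, while the full meeting explores most of
# the 35 cells. Dispersion stays high throughout because every speaker
# keeps contributing.
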