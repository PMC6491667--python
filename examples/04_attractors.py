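"""Attractor analysis: return statistics and winnowing on a planted attractor.

Simulates a session where one cell holds most of the time, then asks the
two attractor questions: how strongly does the cell pull the system back
(return time / return visits), and does winnowing isolate it bottom-up?
"""

from ssgrid import (
    Codebook,
    Dimension,
    SynthConfig,
    make_state_space,
    return_stats,
    simulate,
    to_visits,
    winnow,
)

cb = Codebook((
    Dimension("speaker", ("A", "B", "C", "D")),
    Dimension("tone", ("negative", "neutral", "positive")),
))
space = make_state_space(cb, "speaker", "tone")
attractor = space.cell_of("B", "neutral")

traj = simulate(SynthConfig(
    space=space,
    cell_weights={attractor: 20.0},
    dwell_mean={attractor: 25.0},
    n_visits=250,
    seed=7,
    trajectory_id="planted",
))
vs = to_visits(traj, space)

rs = return_stats(vs, {attractor})
print(f"excursions away from (B, neutral): {rs.n_excursions} "
      f"({rs.n_censored} censored at session end)")
print(f"mean return time:   {rs.mean_return_time:.1f} s")
print(f"mean return visits: {rs.mean_return_visits:.2f}")

result = winnow(vs, space, stop_ratio=0.3)
print(f"\nwinnowing: {len(result.screens)} screens, "
      f"selected screen {result.selected_screen}")
for i, s in enumerate(result.screens):
    mark = " <- selected" if i == result.selected_screen else ""
    print(f"  screen {i}: {len(s.remaining_cells):>2} cells remain, "
          f"heterogeneity {s.heterogeneity:9.1f}{mark}")
print("attractor candidates:",
      [space.labels_of(c) for c in sorted(result.attractor_cells)])

# A short mean return time and ~1 outside visit per excursion mean the
# system barely strays before being pulled back. With one cell hoarding
# most of the time, heterogeneity declines only a few percent per screen
# until the final removals, so the selection rule's threshold matters:
# stop_ratio=0.3 picks the late screen where the relative drop finally
# exceeds 30%, keeping the planted cell (and its strongest companion).
# The full screen log is always available for applying any other rule.
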