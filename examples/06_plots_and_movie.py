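"""Rendering: the worked-example grid plot and its cumulative frames.

Writes a PNG of the 10-event grid (duration-scaled nodes, order arrows,
highlighted first event, seeded jitter) plus a frame sequence showing the
trajectory building up, and the editable PlotSpec JSON.
"""

from pathlib import Path

from ssgrid import brainstorming_example, plot_grid, render_frames

out = Path("scratch/example06")
out.mkdir(parents=True, exist_ok=True)

traj, space = brainstorming_example()

spec = plot_grid(traj, space, out / "grid.png", jitter_seed=11)
print(f"wrote {out / 'grid.png'}: {len(spec.nodes)} nodes, "
      f"{len(spec.arrows)} arrows, first node highlighted")

spec.to_json(out / "grid.plotspec.json")
print(f"wrote {out / 'grid.plotspec.json'} (edit dx/dy to reposition nodes)")

frames = render_frames(traj, space, step=2.0, out_dir=out / "frames",
                       jitter_seed=11)
print(f"wrote {len(frames)} cumulative frames to {out / 'frames'}")

# Node area is proportional to event duration (all equal here), jitter is
# reproducible from the seed, and frame k shows the first 2k seconds —
# assemble the PNGs into a video with any external tool.
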