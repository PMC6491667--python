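# Methods

## Data model

A **codebook** declares each coded dimension's ordered, mutually
exclusive and exhaustive category list; the order fixes axis order on the
grid. A **trajectory** is one observation session: strictly increasing
event onsets (absolute seconds; the first onset need not be 0), one
category per dimension per event, and a terminal offset. An event lasts
until the next onset (the last until the offset), so durations are
implied, strictly positive, and conserve total time exactly
(Σ durations = offset − first onset). Missing values are rejected, not
imputed: an interaction stream with gaps has no well-defined occupancy,
so validation fails loudly instead. Sub-second durations are legal but
draw a warning, since observational coding below a 1-second grain is
rarely reliable and most annotation tools resolve to seconds.

In the `.trj` dialect the final data row carries only the terminal
onset; category cells on it are ignored when present, because exported
files vary in whether they repeat the last state there. Onsets are
written as the shortest decimal that parses back to the identical float,
making `read ∘ write` the identity both on disk and in memory.

## Grid, visits, transitions

The state space is the Cartesian product of exactly two dimensions
(higher-dimensional grids are out of scope; storage of >2-dimension
codebooks is allowed, grid construction picks two). Maximal runs of
same-cell events collapse into **visits**; transitions are consecutive
visit pairs, so transitions = visits − 1 per trajectory, and pooling
never counts a cross-trajectory transition. Any padding row/column a
display adds around the grid is decoration in the plotting layer only; it
never enters `n_cells` or any measure.

Time windows are half-open `[t0, t1)`. An event straddling `t0` is kept
with its onset clipped to `t0`: the system occupies a state at every
instant, so the window must open inside some cell. This makes adjacent
windows partition per-cell durations exactly and makes prefix slicing
idempotent and composable — both are tested properties.

## Measures

Per-cell content measures (events, visits, total duration, mean duration
per visit, proportions, events/minute) report zeros for unvisited cells.
Region aggregates treat a row or column (e.g., one speaker) as a unit;
region-level visits are maximal runs *inside* the region, so bouncing
between two cells of one column counts as a single regional visit. The
spread of per-category percentage shares along an axis is summarized by
the sample standard deviation (ddof = 1, the convention for reported
SDs in this literature).

Dispersion is `1 − (n·Σp² − 1)/(n − 1)` with `n` the cell count of the
**defined** state space, visited or not — that normalization is what
anchors 0 at single-cell occupancy and 1 at grid-uniform occupancy.
Entropies use the natural logarithm and the `0·ln 0 = 0` convention.
Transition entropy is computed over distinct ordered (from, to) cell
pairs; the measure's original software implementation is not published in
detail, so this operationalization is a documented compatibility caveat.
All values are kept at full precision; rounding is display-only.

The choice of natural logarithm is validated against the worked example:
visit proportions {0.2×3, 0.1×4} give −Σq ln q = 1.8867 ≈ 1.89, matching
the reference value only in nats.

## Attractors

Return statistics scan the visit sequence for excursions: leaving a cell
region starts the clock, re-entering stops it. A trailing excursion that
never returns is **censored** — excluded from the means but counted and
reported, so users can judge the truncation. Means are `None` when no
excursion completed (region never left, or left once without returning).

Winnowing removes the minimal-duration cell(s) per screen — ties removed
together, so the log is permutation-invariant — and scores the remaining
cells' heterogeneity Σ(obs − exp)²/exp against a **uniform** expected
duration (remaining total / remaining count). The procedure is only
sketched in the methodological literature; the uniform-expectation
reading and the stopping rule — select the last screen whose relative
heterogeneity change from its predecessor is ≥ `stop_ratio`
(default 0.5) — are this package's documented operationalizations, and
the full screen log is always returned so any alternative rule can be
applied post hoc. A trajectory whose time sits in a single visited cell
short-circuits to that cell as the sole attractor.

## Visualization

Node **area** is proportional to event duration (a radius floor of 0.05
cell units keeps short events visible); the longest event gets radius
0.33. Within-cell placement is uniform jitter from one seeded generator,
bounded so that jitter + radius never crosses the cell border. The
PlotSpec is pure data (JSON-serializable, manually editable per node);
rendering is a pure function of it. Movie frames subset one full-session
layout, so nodes never move between frames and frame k shows
`[start, start + k·step)` with `ceil(total/step)` frames in all.

## Synthetic generator

Trajectories are drawn from an embedded Markov chain over cells with a
zero diagonal: self-persistence is expressed through the dwell-time
distribution (exponential by default — the memoryless standard for
continuous-time occupancy; gamma for over-dispersed dwells; fixed for
tests), never through diagonal transition mass, which keeps visit
semantics exact. Attractor structure enters through per-cell weight
boosts (transition probability into a cell ∝ its weight), optional
per-row stickiness (within-row runs), and per-cell dwell means. A split
rate emits some visits as two same-cell events to exercise the
event/visit distinction. All randomness flows from one explicit seed.

The **worked-example fixture** reconstructs the published 10-event
brainstorming session from its stated constraints (opening neutral
statement in neutral tone, then an idea in low positivity; ideas/support
with positive energy, blocking/criticism negative; every event entering a
new cell; three cells visited twice and four once). Event durations are
not stated in the source — only circle sizes — so the fixture uses unit
durations: all count-based measures (visits, transitions, cell range,
visit entropy) are exact, while duration-based ones (dispersion 0.875
here) are not comparable to the reference figure and are not claimed.

The **team-meeting fixture** emulates two ~55-minute five-person project
meetings coded with 7 functional behavior categories (knowledge exchange,
problem solving, structuring, taking action, relational, counterproductive,
other): mean dwell 4.5 s (≈ 700–800 coded events per meeting, the order of
magnitude of reported per-speaker event counts), one team with two
dominant speakers plus a sticky relational row, one with a uniform
chain. It emulates floor distribution and within-row persistence, not
content semantics, diurnal drift, or coder disagreement — so passing
tests demonstrate measure correctness and qualitative regime (dispersion
above 0.9, "flexible interaction"), not empirical claims about real
teams.

## Numerical and testing choices

- Comparisons of real-valued measures use 1e-9 absolute tolerance;
  counts are exact. `GridMeasures.allclose` exists because equivalent
  computations may sum in different orders.
- Top-cell ranking breaks ties by total duration, then event count, then
  cell index, making every ranking deterministic.
- The independent oracle suite (`tests/oracles.py`) re-implements every
  measure as plain dictionary/loop scans over raw events and is the
  cross-check for the library implementations on 100 random synthetic
  trajectories per run.
- Simulator parameter recovery is checked on a 2×2 space with a strong
  attractor at 10,000 visits, where every transition-matrix row collects
  thousands of observations and the ±0.02 band sits several standard
  errors out; attractor recovery is checked over 50 seeded plantings
  with ≥80% duration concentration.
- Problem sizes throughout the suite (sessions of tens to a few thousand
  visits; 100-trajectory oracle pools) were chosen as the scale of real
  coded-meeting data; the whole suite runs in about two minutes.

## Known limitations

- Transition-entropy and winnowing operationalizations may differ from
  the original (unpublished) software implementations; both are flagged
  above and exportable screen logs make alternatives computable.
- Dispersion and duration entropy depend on the defined grid size, so
  cross-study comparisons require identical codebooks.
- No statistical inference between teams (export tables and use a stats
  package) and no phase-transition detection.
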