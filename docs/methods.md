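# Methods

`contourfill` simulates how adaptation to flickering contours erases the
visibility of subsequently presented low-contrast shapes.  The model has
three stages on a common pixel grid, integrated on a shared clock over a
stimulus movie, plus a simulated-psychophysics harness on top.

## Model

**Opponent front end.**  Each luminance frame `L in [0,1]` on a mid-gray
background (0.5) is split into rectified opponent channels
`on = max(0, L - 0.5)` and `off = max(0, 0.5 - L)`; the signed surface
signal is `S = on - off`.  Two downstream signals are derived from it:

- *Oriented drive* (to the boundary system): central differences of `S`,
  `vert(r,c) = g |S(r,c+1) - S(r,c-1)|` and the transpose for `horiz`,
  with one-sided differences at the borders and gain `g = 10`.  A vertical
  edge (luminance changing horizontally) drives vertically tuned cells.
- *Surface source* (to the filling-in stage): a center-surround contrast
  signal `S - G_sigma * S` (Gaussian surround, sigma = 3 px), rectified
  back into ON/OFF bands.  Uniform region interiors therefore inject
  nothing; every luminance edge injects a pair of opposite-polarity bands
  on its two sides.  Surface appearance is recovered by diffusion: closed
  boundaries trap a region's inner band so it fills the region, while at
  an erased edge the two bands mix and cancel.  This edge-based source is
  what makes erasure *complete* rather than a partial blur: a full-area
  source would keep pumping brightness into an unbounded region, which
  caps erasure at roughly a third of control visibility no matter how the
  diffusion is tuned.

**Gated-dipole boundary system.**  At every pixel, vertical and horizontal
channels receive `drive + J` (tonic `J = 0.2` in both channels) through a
habituating transmitter gate `z` with mass-action dynamics

    dz/dt = alpha (1 - z) - beta (drive + J) z ,

so sustained drive depletes `z` toward `alpha / (alpha + beta S)` while
recovery pulls it back to 1.  The gated signals
`y_o = (drive_o + J) z_o` compete across orientation; the boundary output
is `max(0, y_o - y_perp - Gamma)` with `Gamma = 0.05`, so at most one
orientation is active per pixel and exact ties yield no boundary.  A drop
in the driven channel's input after adaptation lets the fresher orthogonal
gate win transiently: the orientation-opponent rebound that shows up as
faint boundaries *orthogonal* to an adapted contour.

**Boundary-gated filling-in.**  ON and OFF surface signals diffuse
independently on a 4-neighbor lattice,

    dx_p/dt = -A x_p + sum_q P(p,q)(x_q - x_p) + C s_p ,

with permeability `P(p,q) = D / (1 + E (b_p + b_q))` gated by the boundary
orientation that blocks that flow direction (vertical boundaries block
horizontal flow and vice versa).  Perceived brightness is
`on_fill - off_fill`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `alpha` | 0.05 | 1/s | gate recovery; sets how long erasure outlasts the adaptor (tens of seconds) |
| `beta` | 0.3 | 1/(signal*s) | gate depletion; with `alpha` fixes the adapted equilibrium |
| `tonic` | 0.2 | — | common input; energy source of rebounds |
| `out_threshold` | 0.05 | — | boundary output threshold |
| `drive_gain` | 10 | — | contrast-to-drive scale |
| `decay A` | 0.02 | 1/s | near mass-conserving filling on the seconds scale |
| `couple D` | 800 | 1/s | baseline permeability; erased regions homogenize within a test |
| `block E` | 500 | — | a boundary of strength ~0.4 attenuates flow ~200x |
| `input_gain C` | 5 | 1/s | source gain |
| `source_surround_sigma` | 3 | px | width of the edge bands feeding filling-in |
| `dt` | 0.005 | s | boundary clock; filling-in sub-steps within it |
| `half_period` | 0.25 | s | adaptor flicker (2 Hz full cycle) |
| `test_duration` | 2 | s | test presentation; visibility read at its end |

The parameter set was calibrated in-repo around two closed-form anchors
(the gate equilibrium law and the rebound inequality
`J z_h > (d + J) z_v + Gamma` after adaptation) so that four seconds of
outline flicker erases a 0.05-contrast test at the adapted location while
the same test at an unadapted location, and after a blurred-edge adaptor,
stays visible.  Three regimes had to coexist:

- *Slow recovery* (`alpha = 0.05/s`): with faster recovery the adapted
  contour re-traps the test within a second or two and visibility returns
  before the percept is read.
- *Graded depletion* (`beta = 0.3`): strong outline contours (drive ~5)
  deplete gates ~10x more than blurred-edge gradients (drive ~0.5), which
  is what separates the sharp-adaptor from the blurred-adaptor outcome.
- *Mass-conserving diffusion* (`A << 1/test_duration`, large `D`): closed
  boundary chains accumulate their region's surface signal roughly
  linearly over the test, while regions with even one open side share
  their signal with the far larger background and dilute away.  This is
  the regime in which a single boundary gap makes a region blend into the
  background — deliberately including the model's documented over-erasure
  of the half-square condition, which is reproduced, not patched.

## Visibility and thresholds

A target's visibility is the absolute difference between mean perceived
brightness over the target mask and over an adjacent surround annulus, at
the end of the test presentation.  Because adaptation phases leave
residual filled-in activity, the harness subtracts the response of the
same adapted state to a zero-contrast test, isolating the test's own
contribution.  A target is *visible* when this score exceeds 10% of the
score the same target produces at 0.05 contrast with no adaptation; the
criterion is re-derived per geometry, making the call robust to parameter
rescaling.

Thresholds are found by bisection on test contrast (bounds (0.004, 0.5],
resolved to 1e-3) after verifying on the initial bracket that visibility
grows with contrast; the model is noise-free, so adaptive staircases are
unnecessary and every battery rerun is byte-identical.  Adaptation is
simulated once per adaptor and its end state replayed for each probe
contrast.  Thresholds are reported in the model's own contrast units and
are not fitted to human percent-contrast axes; matched-size model
elevations are much larger than human ones, consistent with the model
lacking any residual cue once filling-in collapses.

## Stimuli and study conditions

All stimuli are generated parametrically: outline/filled crosses and
squares, half-square outlines, vertical lines, square annuli, two-holed
annuli, disks, polar checkerboards, brightness pyramids, bipartite
fields, and illusory-contour inducers (corner bullseyes cut out inside
the test square, leaving line ends along its border).  Adaptors flicker
black/white at 2 Hz for 4 s (outline-adaptation demos) or 6 s (flicker
adaptation: disks, annuli, checkerboards); tests are ±0.05 luminance
increments/decrements presented immediately after.  Rendering uses
10 px/degree (demo movies) and 5 px/degree (threshold batteries); the
battery grids are scaled down purely to keep full factorial sweeps at
desk-scale runtimes, and all size *relations* (matched vs mismatched) are
preserved exactly.  The generator emulates perfect fixation and noise-free
achromatic displays; it does not emulate eye movements, photoreceptor
adaptation, display gamma, or chromatic stimuli, so passing tests
demonstrate the boundary-adaptation/filling-in mechanism, not a
quantitative account of human thresholds.

## Numerical choices

Explicit Euler throughout.  Gates advance on the 5 ms boundary clock with
the stability guard `dt (alpha + beta S_max) < 1`; gate levels are clamped
to (0, 1].  The filling-in lattice obeys the stricter guard
`dt (A + 4D + C) < 1` and therefore sub-steps (18 sub-steps per boundary
step at the defaults).  Oriented drive is constant within a frame and
computed once per frame; permeabilities are recomputed every boundary
step as gates evolve.  The time-stepped filling-in integrator is verified
against a direct sparse solve of `(A I + L) x = C s` on small random
instances to 1e-6 max-norm.  Exact orientation ties produce no boundary;
zero-contrast frames produce exactly zero drive and zero source.

## Known limitations

- **Half-square over-erasure** (documented failure): one open side drains
  the whole region; the unadapted side falls well below its control,
  unlike the human percept.
- **Two orientations only**: diagonal contours split their drive equally
  between the channels and fall inside the opponent tie-break, so curved
  contours (disks, checkerboard sectors) trap weakly even without
  adaptation.  Disk-adaptation effects consequently appear as graded
  contrast reduction rather than full invisibility, and their demo checks
  assert strong reduction (below half of control) rather than the
  sub-criterion invisibility asserted for straight-edged shapes.  The
  threshold *patterns* (matched-size diagonal, checkerboard elevation) are
  unaffected.
- **No brightness contrast**: the erased annulus' hole renders as
  background, with no induced opposite-polarity percept.
- **No illusory-contour formation**: inducer displays adapt only where
  luminance contours exist, which is precisely what grounds the
  no-erasure prediction for illusory adaptors.
- **Bipartite residual**: outer-edge sources keep pumping a weak gradient
  across the merged field, so the adapted side difference collapses to
  ~12% of control rather than to zero; the demo check uses a 20% bound.
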