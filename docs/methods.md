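# Methods

## The measurement being modeled

A bolus of cells (by default 2.5×10⁴, the count in a 50 μL pulse at
5×10⁵ cells/mL) is perfused through a selectin-functionalized microchannel
(2 mm × 100 μm cross-section, 1.3 or 14 cm long) behind a circular settling
feature that brings cells to the substrate before the functionalized region.
A camera watches a field of view (FOV) at the channel end at 25 fps
(500×376 px). Within the FOV a cell's frame-to-frame *instantaneous
velocity* V_inst is measured; from its arrival (*elution*) time the
whole-channel *average velocity* and the *percent binding time* are derived.
Cells are classed as rolling when 0 < V_inst is below a shear-dependent
threshold (125, 250, 375 μm/s at wall shear stresses 0.5, 1.0,
1.5 dyn/cm²); free-flow velocities at those shears are taken as the
calibration constants 529, 1059, 1588 μm/s. Off-grid shears use linear
extension (thresholds) and piecewise-linear interpolation (free-flow
velocities); the printed pairs are exact table entries because they are not
exactly proportional to shear.

## Transit model

Each cell is an independent continuous-time two-state Markov chain:

- *bound* → *free* with release rate k_off (1/s); *free* → *bound* with
  capture rate k_on (1/s); exponential holding times;
- velocity v_roll while bound, v_free_flow while free;
- v_roll is drawn **once per cell** from a lognormal with arithmetic mean
  `v_roll_mean_um_s` and coefficient of variation `v_roll_cv` (redrawn,
  boundedly, if a draw reaches v_free_flow). A single per-cell rolling
  speed is what makes the per-cell *median* V_inst a meaningful summary;
- the settling-feature dwell t_offset is lognormal per cell
  (`t_offset_mean_s`, `t_offset_cv`); analyses of tracked data use only the
  population mean, as an elution-time correction;
- the chain advances until cumulative distance reaches the FOV position;
  arrival defines t_elution, and the time-weighted bound fraction over that
  distance is the ground-truth percent binding time. Motion is continued
  through the FOV (recorded separately) so the cell can be rendered;
- cells whose elution exceeds the acquisition window (default 7,200 s, a
  2 h video) are flagged censored and excluded from elution-based metrics.

Defaults, chosen once as a realistic rolling-adhesion regime and kept
fixed: k_on = 0.2 s⁻¹, k_off = 0.1 s⁻¹ (a cell switches many times over
either channel length), v_roll_mean = 60 μm/s with CV 0.5 (tens of μm/s,
well below every rolling threshold), p_start_bound = 0.5 (the settling
feature delivers cells to the substrate), t_offset_mean = 30 s with CV 0.2.
These are user parameters, not fitted quantities.

**Exactness of the mass balance.** For a transit holding exactly two
velocities (v_roll, v_free_flow), writing t = t_e − t_o and splitting it
into bound and free parts with distance conservation
v_roll·t_b + v_ff·t_f = L gives

  %BT = [v_ff·t − L] / [(v_ff − v_roll)·t] = t_b / t,

an algebraic identity, not an approximation. The test suite and acceptance
script verify it to machine precision with L equal to the inlet→FOV
distance. When analyzing real tracked data the nominal channel length is
used instead (the FOV sits at the channel end, so the difference is at most
fov_length/L ≈ 5% for the short channel, ≈ 0.5% for the long one) and
V_inst is the measured median — both substitutions are approximations the
original analysis shares.

**Stationarity check.** At k_on = k_off the chain's stationary bound
occupancy is 1/2, and the mean bound-time fraction converges to it as the
number of switching cycles grows. A distance-terminated transit oversamples
the final (disproportionately free) interval, biasing the mean down by
O(1/cycles): ≈ 0.01 over the 1.3 cm channel (~20 cycles at 1 s⁻¹ rates)
and < 0.002 over the 14 cm channel (~250 cycles). The stationary-recovery
check therefore runs on the 14 cm preset, where the asymptotic property is
actually in force; the identity and boundary checks use the short channel.

## Rendering

Frames are a uniform background (default 20 counts) plus one isotropic
Gaussian spot per in-FOV cell (amplitude 90, σ = 4 px) plus Gaussian read
noise (σ = 4), rounded and clipped to 8 bit. Pixel size defaults to
1.3 μm/px (plausible for a 10× objective with 2×2 binning; it is not a
printed value and is fully configurable). Rendered videos are trimmed to
start 2 s before the first arrival so short test videos skip the dead time
while still giving the tracker's background model empty warm-up frames.
Transverse (y) positions are uniform-random between margins by default; an
evenly-spaced lane mode exists for tracking benchmarks where ground-truth
cells must stay separated.

What the renderer deliberately omits: cell deformation and rotation,
intensity variation between cells, focus drift, illumination gradients,
cell–cell collisions and secondary capture, and debris. Tracker results on
synthetic stacks therefore validate the *pipeline logic* (background
adaptation, thresholding, size filtering, linking, speed estimation), not
robustness to every artifact of real microscopy.

## Tracker

- Background: exponentially weighted running average,
  acc ← (1−α)·acc + α·frame, α = 0.0005; at 25 fps the e-folding time is
  1/(α·f) = 80 s. From a constant scene F and zero start the accumulator is
  exactly F·(1 − (1−α)ⁿ) after n updates, which the tests check against the
  iteration.
- Detection: both frame and background are smoothed with a 13 px square
  (uniform) kernel; the absolute difference is thresholded at 15 counts;
  8-connected components with equivalent diameter ≤ 5 μm are discarded;
  centroids are difference-intensity weighted. The blur size and threshold
  are configurable because their original units ("a factor of 13/15") admit
  more than one reading; a kernel size in px and an absolute 8-bit
  difference are the dimensionally consistent one used here.
- Linking: greedy per-frame one-to-one assignment to the nearest predicted
  position (last position + last step velocity × Δt), gated at
  `max_link_distance_um` (default 1.2× the free-flow displacement per
  frame, so free-flowing cells remain linkable) and at an upstream
  allowance of one cell diameter (flow moves cells downstream; small
  upstream jitter is measurement noise). A detection whose bounding box
  overlaps a slow track's previous boundary may link regardless of the
  distance gate — the overlap rule that serves large or slow objects. Ties
  break by smallest distance, then earliest track id, making the tracker
  fully deterministic. Tracks unmatched for more than `lookahead_frames`
  (default 3) close; detections in the first 25 frames (1 s) are suppressed
  while the background settles.
- Known limitation: a slow roller dwelling hundreds of frames is partly
  absorbed into the running average and can leave a "ghost" detection after
  it moves on; ghosts appear as short spurious tracks and inflate the track
  count, which is why recovery is assessed by matching tracks to
  ground-truth cells rather than by counting tracks.

## Analysis choices

- Per-cell V_inst is the **median** step speed (the mean is available);
  medians are robust to the single-frame jitter of centroid noise.
- Arrested cells (median speed within one pixel-per-frame of zero, i.e.
  32.5 μm/s at the default pixel size — configurable) are excluded from
  the rolling numerator but kept in the denominator of % rolling; censored
  cells are excluded from both and reported as a separate count.
- Raw %BT values outside [0, 1] (possible under measurement noise, and
  generic for near-free-flow cells whose denominator v_ff − V_inst is
  small) are clamped by default, with the raw value always retained in the
  output. Means of %BT over populations containing near-free-flow cells
  should be read with this in mind; cells with V_inst ≥ v_free_flow have no
  defined %BT and are excluded from its mean.
- t_offset for tracked data is one population constant per run, calibrated
  from a blank (non-functionalized) run as mean(t_elution) − L/v_free_flow
  (floored at zero, standard error sd/√n, minimum 10 cells).
- Elution time origin is pulse injection = acquisition start; when a
  rendered video is trimmed, the trim offset is carried in the run manifest
  and restored during analysis.
- Residence-time distributions are unit-mass histograms of eluted cells
  (default 10 s bins); censored cells are a side count, never binned.
- SEM in a population summary is across cells within one run;
  experiment-level means ± SEM across runs come from the comparisons
  module, which also fits OLS regressions (slope t-test, Pearson's r).
  Multi-factor ANOVA is intentionally out of scope: the dose-response
  tables are tidy input for any standard statistics package.

## Problem sizes

The test suite and acceptance script run everything at desk scale by
choice: transit-model checks use 100–1000 cells; the rendered round-trip
uses 20 simultaneous cells over ~90 s of video; the regression null
calibration uses 1000 replicates of n = 100. The full experiment scale
(2.5×10⁴ cells, 2 h of video) remains the simulator default and runs
through the same code paths.
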