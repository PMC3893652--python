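# Methods

## The question and the measure

`swarmdim` quantifies collective behaviour in a video of an animal group
without tracking individuals.  Each grey-scale frame is treated as a point
`z_i` in pixel space (`d = width x height` coordinates, grey levels in
{0,...,255}); a trial video becomes a cloud of `n` points.  The working
definition of collective behaviour is geometric: coordinated group motion
explores few degrees of freedom, so the frame cloud lies near a
low-dimensional manifold; disordered motion does not.  The measure is the
ISOMAP embedding dimensionality `d-hat` of that cloud.

The estimate proceeds in four steps:

1. **Neighbour graph.**  A nu-nearest-neighbour graph over the frames
   (default nu = 11), edges weighted by ambient Euclidean distance in pixel
   space.  The neighbour relation is symmetrized by union (an edge exists
   if either endpoint ranks the other among its nu closest); distance ties
   break by ascending index so results are reproducible.  Non-edges are set
   to infinity, which prevents shortest paths from jumping between separate
   branches of the underlying manifold.
2. **Geodesics.**  All-pairs shortest paths over the graph approximate
   on-manifold geodesic distances.  Floyd–Warshall is the reference solver;
   per-source Dijkstra is available behind the same contract and is used
   automatically on sparse problems (the two agree to numerical precision).
   If the graph is disconnected, the analysis restricts to the largest
   connected component, provided it retains at least 90 % of the frames
   (configurable); sparser data are rejected as unanalysable.
3. **Classical MDS.**  The squared geodesic matrix is double-centred
   (`B = -1/2 J D^2 J`) and eigendecomposed.  Coordinates are eigenvectors
   scaled by the square root of their (positive) eigenvalues, ordered by
   descending eigenvalue; non-positive directions contribute zeros.  Each
   coordinate column's sign is fixed so its largest-magnitude entry is
   positive, making outputs identical across runs and libraries.
4. **Residual variances and the dimensionality criterion.**  For each
   candidate dimension `d`, `R(d) = 1 - rho^2`, where `rho` is the Pearson
   correlation between upper-triangle geodesic distances and the pairwise
   Euclidean distances of the first `d` embedding coordinates.  `R` is 0
   for a perfect embedding and 1 for the worst; `d-hat` is the smallest
   `d` with `R(d) < 0.05`.  If no `R(d)` falls below the threshold within
   `d_max = 11` candidate dimensions, the trial is *censored* and carries
   the value `d_max + 1 = 12` downstream — deliberately the top of the
   observer scale, so censored (uncoordinated) trials align with the
   "least interaction" rating.

Parameters that matter: `nu = 11` (the estimate is empirically stable for
nu in 7..15 on well-sampled manifolds — verified on the swiss-roll fixture),
`threshold = 0.05`, `d_max = 11`.  The residual scree `R(d)` is typically
but not always non-increasing: adding coordinates beyond the intrinsic
dimension can raise `R` by a few 1e-4 (correlation noise), and closed
manifolds (a circle) show larger bumps past the detection point.
Violations beyond 1e-9 are logged as diagnostics, never raised as errors.
Relatedly, a closed 1-D manifold (circle) is reported at its embedding
dimension 2, not its intrinsic dimension 1 — an inherent property of the
residual criterion, since no 1-D Euclidean embedding preserves circular
geodesics.

## Video ingestion and temporal sampling

Frames are loaded from image directories in lexicographic order, converted
to grey with the broadcast-standard luminance weights (0.299, 0.587, 0.114,
rounded half away from zero; the three RGB channels of such footage are
highly correlated, so any fixed convention works and this one is testable),
and flattened row-major.

Because species move at very different apparent speeds, videos are
subsampled at a period `s` (in frames) inversely proportional to the
species' characteristic pixel speed: `s = round(s_ref * v_ref / v_pix)`,
with the fastest species as reference (`s = 1`).  This equalizes the
inter-frame change across species.  The built-in recording profiles (at
30 fps) all retain exactly 900 frames:

| profile      | T (s) | s (frames) |
|--------------|-------|------------|
| ants         | 390   | 13         |
| fish         | 30    | 1          |
| fish-nostim  | 600   | 20         |
| frogs        | 480   | 16         |
| chickens     | 480   | 16         |
| humans       | 600   | 20         |

Sampling keeps indices `0, s, 2s, ...` (the first frame always retained);
a warning is emitted when a profile yields a non-standard frame count.

## The synthetic swarm and what it does (not) emulate

Real animal videos are not redistributable, so the pipeline is exercised on
a self-propelled-particle system rendered to frames.  Agents move at
constant speed; each step the heading is set to the direction of the summed
unit headings of all neighbours within `interaction_radius` (self
included), plus `stimulus_strength` times the unit vector toward the
nearest attractive stimulus (0, 1 or 2 stimuli), plus uniform angular noise
on `[-noise_eta, +noise_eta]`.  Boundaries are periodic (wrap) or
reflective (specular bounce of position and heading).  Named noise presets
low/moderate/high = 0.1/1.0/2.5 rad span the ordered and disordered
regimes.  Polarization (the magnitude of the mean unit-heading vector)
summarizes order: ~0.99 at the low preset, ~0.17 at the high preset under
the default geometry.

Rendering draws each agent as a dark filled disc (intensity 30, radius 4 at
test scale) on a light background (220), emulating animals filmed against
an arena floor.  The square arena is scaled to fit the frame (side = the
smaller frame dimension) so the whole domain stays visible; a pixel belongs
to a disc when its centre lies within the radius, inclusive.

Two pipeline-level choices deserve emphasis, because without them *every*
synthetic video reads the same:

- **Temporal sampling is essential.**  Rendering every simulation step
  makes consecutive frames each other's nearest neighbours for any noise
  level; the neighbour graph degenerates to a chain along time, geodesics
  become exactly additive along that chain, and `R(1) = 0` — even a fully
  disordered swarm reports a perfect 1-D manifold (the manifold of time
  itself).  `run_trial` therefore simulates `n_frames * s` steps and
  retains every `s`-th (default `s = 20`), so that per-retained-frame
  motion is comparable to the blob size, mirroring the speed-scaled
  sampling used for real footage.
- **Cohesion makes the low-dimensional regime detectable.**  An aligned
  but spatially spread group slowly scrambles its rendered pattern
  (relative positions diffuse), so its frame cloud never cleans up below
  the 0.05 threshold.  With an attractive stimulus the aligned group forms
  a compact, persistently recurring configuration and embeds at d-hat ~
  3-6, while the high-noise group stays censored at 12 regardless of
  condition.  This also reproduces the qualitative condition effect seen
  in schooling species: stimuli induce low-dimensional behaviour that is
  absent at baseline.

Simulated observers map each trial's true dimensionality through an
identity affine map plus Gaussian noise (sd 1 by default), rounded and
clipped to the integer CBM scale 1..12, twice independently per trial.
This emulates raters whose scores track coordination with error; it does
not emulate inter-observer bias structure, learning, or the perceptual
features real observers use.

What passing the synthetic suite does *not* show: robustness to lighting,
occlusion, camera motion, heterogeneous body sizes, or real animal
kinematics.  The synthetic system demonstrates the method's contract —
ordered motion yields low `d-hat`, disorder yields censoring, and the
statistics behave — not field validity.

## The study design and statistics

A full run mimics the study structure: `n_species` synthetic species
(differing in noise preset) x 3 stimulus conditions (0/1/2) x `n_trials`
replicates.  Per species-condition cell, the `k = 3` trials with the
smallest between-observer disagreement `|cbm_a - cbm_b|` are selected
(ties by trial id).  Then:

- Pearson correlation between dimensionality and mean CBM with the t-test
  `t = r sqrt((n-2)/(1-r^2))` on `n-2` degrees of freedom;
- balanced two-way fixed-effects ANOVA (species and condition main
  effects; the interaction is excluded by default and pooled into the
  error, configurable) on dimensionality;
- per-species one-way ANOVAs across conditions;
- Fisher's protected LSD post-hocs: pairwise t-tests sharing the ANOVA
  pooled error mean square and its degrees of freedom, emitted only when
  the parent main effect is significant at 0.05 — otherwise an explicitly
  empty, reasoned table.

Censored trials enter all statistics at 12.  This convention compresses
differences among highly disordered groups and is a known limitation.
The two-way ANOVA requires a balanced design and rejects unbalanced
inputs rather than silently switching to an unbalanced decomposition.

All randomness derives from one master seed through `numpy` seed-sequence
spawning (per species-index, condition, replicate), so identical
configurations reproduce byte-identical trial tables.

## Numerical choices and problem sizes

- Distance ties in neighbour selection and trial selection break by index /
  id; MDS signs are fixed; eigenvalues <= 0 contribute zero coordinates.
- Constant distance vectors make the residual correlation undefined;
  `R(d)` is then reported as 1 with a warning.
- Duplicate frames (distance 0) remain connected in the graph (explicit
  zero-weight edges).
- The default analysis profile is test-scale — 160 x 107 frames (the 3:2
  aspect of 960 x 640), 300 retained frames, 40 agents — chosen so a full
  study runs in minutes on a laptop core; `full_resolution` switches to
  960 x 640 with 900 frames for full-resolution runs.
- The swiss-roll fixture is a one-turn Archimedean spiral (t in
  [1.5pi, 3.5pi], unrolled length ~49) swept over a width of 30: wide
  enough that both intrinsic directions carry appreciable spread (a
  strongly elongated roll is correctly summarized as 1-D by the residual
  criterion), narrow enough that 1000 samples support nu up to 15 without
  between-turn shortcuts.

## Known limitations

- The particle model is a stand-in with Vicsek-family dynamics, not a
  reconstruction of any specific species' interaction rules.
- The censoring value (12) is a convention; means over censored-heavy
  cells are floor/ceiling statistics.
- ISOMAP here assumes a single connected manifold; multimodal behaviour
  (separate clusters of configurations) is reduced to its largest
  component.
- No out-of-sample extension, landmark variant, or alternative embedding
  (LLE, diffusion maps) is provided.
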