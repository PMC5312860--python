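# Methods

This note documents the models, conventions and design choices behind
`nanocapture`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the genuinely open
decisions were made.

## Coordinate frame and surrogate geometry

All in-memory lengths are nm (PDB/XYZ files store Å, the formats'
convention, at 3 decimals; conversion happens at the I/O boundary). The
pore is modelled as a rotationally symmetric surrogate of heptameric αHL:

- the **K8 ring** (7 Cα positions) defines the coordinate origin at its
  centroid; the pore axis is the fixed +z direction, so release points have
  positive axial coordinates and descent into the pore is towards −z. The
  real protein can tilt in a membrane; the surrogate cannot — fixing the
  axis removes an axis-fitting step that no part of the analysis depends
  on.
- the **N17 ring** centroid plane (`capture_plane_z`, default −0.5 nm)
  is the classification surface. The axial K8–N17 separation is a
  surrogate choice, not a measured quantity; it only needs to be below the
  mouth and above the barrel.
- the **vestibule entrance** is a funnel: radius `funnel_entry_radius`
  (default 2.2 nm) at the cap surface (z = 0), narrowing linearly to
  `pore_mouth_radius` (default 1.3 nm) at the capture plane. The funnel is
  what makes an αHL-like cap an efficient collector — a flat surface with
  a bare 1.3 nm hole would swallow far fewer diffusing solutes than the
  study geometry plausibly does.
- `cap_outer_radius` (5.0 nm) bounds the cap top; `barrel_exit_z`
  (−10.0 nm) is the translocation plane.
- a **zone map** assigns each analysable residue number one of
  {vestibule_interior, vestibule_rim, cap_surface, barrel}. Residues named
  in both the vestibule and the entrance-edge interaction sets (T9, D13)
  are assigned `vestibule_interior`, since the captured-run description is
  the stronger localisation; K8 is `vestibule_rim` because it defines the
  mouth ring. All dimensions and assignments are configurable
  (`GeometryConfig`, YAML round-trip).

## Trajectory classification

A frame is `below_all` when *every* solute atom's axial coordinate is
strictly below the capture plane, `above_all` when none are, `straddling`
otherwise. An atom exactly on the plane counts as *above* — the strict
inequality makes "all atoms below" conservative; nothing in the analysis
depends on the measure-zero boundary, but the convention must be fixed.

`inside_pore` requires every below-plane atom to lie within the pore-mouth
radius; frames below the plane but outside the mouth count as above for
labelling and set the `excluded_outside_pore` flag. This automates, as a
radial criterion, the visual screening that normally removes runs where
the nucleotide slipped down *outside* the protein.

Classification is **latched** by default: the first `below_all ∧
inside_pore` frame fixes the label as captured with that frame's time as
the latch time, because no vestibule exit is ever assumed once the solute
is inside (the generator enforces the same absorbing rule). A
`final_frame` mode is retained for sensitivity checks; the two differ only
on re-entrant paths. Translocation is any frame entirely below the barrel
exit plane and implies capture.

## Contact analysis

A residue (all protomer copies pooled, as residue identities are reported
without chain) is in contact in a frame when the minimum solute–residue
heavy-atom distance is ≤ `cutoff`. The cutoff is **0.4 nm** by default — a
standard MD van der Waals contact convention; the underlying VMD-style
scripts in this field rarely state theirs, so it is exposed rather than
hard-coded. Residence events are maximal runs of consecutive in-contact
frames (duration = run length × frame interval, no gap bridging), so the
10 ps default frame interval bounds the resolution of duration classes.

Duration classes use strict inequalities as usually phrased: *transient*
events last < 100 ps, *stable* interactions > 1 ns; a run of exactly
10 frames at 10 ps (100 ps) is therefore not transient. A residue is
*extended* for an outcome group when its mean per-run contact fraction
across that group's runs exceeds 5%; the alternative pooled-frames reading
is available via `ContactConfig(averaging="pooled")`. Hydrogen bonding is
approximated by a tighter 0.35 nm heavy-atom cutoff without angle criteria
(the surrogate pseudo-atoms carry no hydrogens) and reported separately.

## Capture statistics

Per condition, the capture probability is estimated at two bounds: *upper*
= (captured + possible)/n, *lower* = captured/n, with the plain binomial
standard error `sqrt(p(1−p)/n)` and no continuity correction.
Probabilities are fractions internally and percentages in reports and in
the regression module.

## The linear capture-probability model

`p(h, t) [%] = intercept − height_slope·h − translation_slope·t`.

Fitting is two-stage, mirroring the study design:

1. **Height line**: ordinary least squares of the on-axis percentages on
   height (statsmodels OLS). "Least squares" here is unweighted; a
   1/SE²-weighted option exists but is not the default, since no weighting
   scheme is part of the standard procedure.
2. **Translation slope**: the lateral series (taken at one series height,
   default 3.0 nm) is first *anchored* — every percentage shifted by the
   single constant that makes its t = 0 point equal the height line's
   prediction at the series height. The slope is then fitted with the
   intercept pinned to that prediction, which reduces to a regression
   through the origin of the anchored residuals on t. Freeing the
   intercept (`anchor_intercept=False`) is available for sensitivity
   analysis.

On noiseless linear input all coefficients are recovered to machine
precision (closed-form least-squares identity); this is tested. Fits are
made to the upper-bound percentages by default (the bound the model's
"possible capture" label refers to); lower-bound fits are available via
`bound="lower"`. `predict` returns the raw affine value — never clamped —
and warns when the prediction leaves [0, 100]; clamping happens only in
the Bernoulli generator, where a probability is actually needed.

## Synthetic data

### What the Langevin tier emulates

The solute is a rigid vertical stack of three pseudo-atoms (phosphate,
sugar, base; 0.25 nm spacing), sufficient for "all atoms below the plane"
semantics and orientation bookkeeping, undergoing overdamped Langevin
motion of its centre:

    Δx = −v·ẑ·Δt + √(2·D·Δt)·η,   η ~ N(0, I₃)

with defaults `D = 0.4 nm²/ns`, `v = 0.3 nm/ns` plus an
`orientation_drift_bonus = 0.1 nm/ns` for phosphate-down releases (the
charged moiety leads, producing the down-orientation capture advantage),
timestep 1 ps, frames every 10 ps, 5 ns runs. The drift plays the role of
the applied transmembrane field; no quantitative mapping to a field
strength is attempted. Boundaries:

- reflecting cap surface at z = 0 outside the funnel entry;
- reflecting funnel wall (entry radius → mouth radius) inside the neck;
- **absorbing capture**: once all pseudo-atoms are below the capture plane
  inside the mouth, the solute is confined below the plane — the no-exit
  observation implemented as a rule;
- **sticky cap sites**: while in contact with the cap-surface band
  (r between the funnel entry and the cap edge, lowest atom within
  0.12 nm of the surface), each step pauses with probability
  `sticky_site_affinity = 0.2`. This emulates trapping by the cap-surface
  residue triplet (D45/K46/N47): failed runs accumulate their contact mass
  on cap_surface/rim residues while captured runs contact the vestibule
  interior. The affinity value is a modelling choice (the spec of the
  emulated study fixes D, v, bonus and timestep but not this), set so that
  cap pauses are frequent without freezing the solute.

Under these defaults the 360-run grid's upper-bound capture fractions span
roughly 2–80%, declining approximately linearly in height, with
phosphate-down ≥ phosphate-up at every condition in expectation — the
qualitative structure the pipeline is meant to analyse, including the
small non-monotonicity at 0.5 nm translation (releases over the funnel
edge need less lateral diffusion than releases over the centre).

Reproducibility: per-run seeds derive from a master seed via
`numpy.random.SeedSequence`; each run pre-draws its noise (all normals,
then all uniforms), so a run simulated alone is bit-identical to the same
run inside a vectorised batch. The frameless batch evaluator latches
capture at step granularity while the recorded-trajectory path classifies
at frame granularity; because capture is absorbing and confining, the
labels agree (tested), with latch times differing by at most one frame
interval.

### What it does not emulate

No ions, water, electro-osmotic flow, protein flexibility, rotational
solute dynamics, or atomistic energetics; capture inside the vestibule has
no binding-site structure and translocation is rare drift, not a modelled
process. Passing tests on this tier therefore validate the *pipeline* —
classification, contact bookkeeping, statistics, fitting — and the
qualitative geometry of capture, not any quantitative prediction about a
real pore.

### Bernoulli tier

Binary possible-capture outcomes drawn per run from
`clamp(p(h, t)/100, 0, 1)` under a known linear truth model. This tier has
exactly the binomial sampling structure the statistics assume, making it
the right instrument for parameter-recovery tests: at 2000 replicates per
condition the height slope is recovered with a Monte-Carlo SD of ≈ 0.3
%/nm and the translation slope with ≈ 0.7 %/nm (the anchor observation at
t = 0 dominates the latter). Recovery is unbiased; both are exercised in
the test suite at the 3-Monte-Carlo-SE level.

## Numerical and degenerate-input conventions

- Radial reflections rescale x, y to the reflected radius, clamped to
  [0.05 nm, wall] so a large step cannot overshoot through the axis.
- Two-point height fits are exact with zero residual; standard errors are
  then undefined (0/0) and reported as NaN.
- `remove_height_effect` requires an exact t = 0 anchor point (tolerance
  1e−9 nm) and raises otherwise.
- Empty rings, empty frames, zero-run conditions, mixed-condition outcome
  sets, non-monotone or non-uniform time axes, and manifest rows with
  unknown orientation or units all raise typed errors naming the violated
  constraint.

## Problem sizes in the test suite

Tests run the generator at reduced but statistically meaningful sizes
chosen as the smallest designs that make the asserted contrasts visible
above sampling error: 200 replicates per condition for monotonicity and
orientation-dominance checks, ~100 trajectories for the contact
zone-structure check, 25 independent procedure replications to estimate
Monte-Carlo standard errors for recovery tests, and the full 2000
replicates per condition for the headline recovery protocol itself.

## Known limitations

- The Langevin tier's capture fractions depend on surrogate geometry
  (funnel entry radius, drift/diffusion ratio); they are in-range and
  qualitatively correct, not calibrated to any measured pore.
- The anchored translation fit inherits the full sampling noise of the
  t = 0 observation; its variance is markedly larger than the height
  slope's at equal replication.
- Contact analysis pools protomer copies; chain-resolved contacts are not
  reported.
- No nonlinear or saturating capture models; predictions outside the
  fitted grid are extrapolations and are flagged, not prevented.
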