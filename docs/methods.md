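# Methods

## Problem and model

A pencil-beam-scanning proton machine with a fixed range shifter delivers
spots whose lateral fluence carries a long low-intensity halo produced by
large-angle scattering in the shifter.  Fluence-based dose engines model the
single-spot in-air fluence as a weighted sum of two Gaussians,

    phi(r) = A [ (1 - w2) / (2 pi sigma1^2) exp(-r^2 / 2 sigma1^2)
               +      w2  / (2 pi sigma2^2) exp(-r^2 / 2 sigma2^2) ],

with a narrow core (sigma1), a wide halo (sigma2 >= sigma1) and a halo
weight w2 in [0, 1).  sigma1 and sigma2 depend on beam energy and on the
longitudinal plane position z (signed offset from isocenter, positive
downstream); w2 depends on energy only.  The bracketed profile integrates
to 1, so A is the per-spot fluence amplitude; it cancels in every quantity
this package computes.

The measurable handle on these parameters is the **field-size factor
(FSF)**: the central fluence of a uniform square spot field, normalized to
a 10 cm reference field at the same energy and plane.  For a field of side
FS built from spots with isocenter spacing SS, the central fluence is the
lattice sum over the (2N+1)^2 grid with N = FS/(2 SS), evaluated at the
divergence-projected spacings SS_x' = SS (VSAD_x + z)/VSAD_x (likewise in
y), where VSAD is the per-axis virtual source-to-axis distance.  Small
fields (2 cm) respond strongly to sigma1, the largest fields (20 cm) to
sigma2, and both mildly to w2, which is what makes all three parameters
identifiable from a set of FSFs between 2 and 20 cm.

The double Gaussian separates in x and y, so the 2-D lattice sum is
computed as a product of two 1-D sums per component; this equals the naive
double loop to machine precision and is what the test suite cross-checks
against a brute-force oracle.  The full grid (at most 41 x 41 spots) is
always summed; no truncation.

## Measurement design

One delivery per (energy, plane) yields all field sizes: spots are ordered
ring by ring (Chebyshev ring max(|i|,|j|) never decreases) from the center
outward, with control points pausing the beam exactly when each nested
square field (2, 4, 6, 8, 10 cm) is complete.  Cumulative chamber charges
at the pauses, ratioed to the 10 cm reading, are the FSFs.  Within a ring,
spots are ordered by angle from the +x axis counter-clockwise starting at
(ring, 0); only the prefix property (the delivered set at each control
point equals the nested grid) matters for the FSFs, and it is tested.

The default campaign is 10 energies x 5 planes (z = -200, -100, 0, +100,
+200 mm) x field sizes {2, 4, 6, 8, 20} cm against the 10 cm reference:
250 records.  A validation campaign uses 10 held-out energies at the
isocenter plane only: 50 records.

## Fitting

Per energy, the free parameters are (sigma1, sigma2) per plane plus one
shared w2 — 11 parameters from 25 records for the default five-plane
design.  The objective is the unweighted sum of squared relative FSF
differences, matching how agreement is reported (percent).  Stages:

1. **Coarse grid**: sigma1 on 20 log-spaced points in [1, 20] mm,
   sigma2/sigma1 on 10 log-spaced points in [1.5, 10], w2 on 11 points in
   [0, 0.3].  For fixed w2 the planes decouple, so the scan is linear in
   the number of planes.  Ties break toward the smallest sigma1, then the
   smallest w2.
2. **Staged refinement**: the shared-w2 landscape is multimodal at grid
   resolution (a heavier halo can partly mimic a wider core), so each
   candidate w2 gets a cheap bounded Powell polish of every plane's
   (sigma1, sigma2) before the w2 candidates are ranked.  Without this the
   grid can rank a wrong-basin w2 first and a single joint local search
   stays there.
3. **Joint polish**: bounded Powell over all 11 parameters from the best
   staged point, ftol 1e-10.  The returned objective never exceeds the best
   grid candidate (the better of grid and refined points is kept); a
   non-converged polish returns the best-so-far with `converged=False`
   rather than raising.

Bounds: sigma1 in [0.5, 30] mm, sigma2 in [sigma1, 150] mm (the ordering is
enforced inside the objective by evaluating max(sigma2, sigma1)), w2 in
[0, 0.5].  Setting `refine=False` recovers the pure grid answer.

Identifiability guard: each plane needs at least 3 distinct field sizes.

## Interpolation across energy

Machines deliver ~68 energy layers between 80.3 and 175.6 MeV; fits are
made at 10 of them and sigma1(E), sigma2(E) per plane and w2(E) are carried
to the rest with a shape-preserving piecewise cubic (PCHIP) in nominal
energy.  PCHIP passes through the fitted values exactly and does not
overshoot, so interpolated values stay within the bracketing fitted values
and never leave their physical bounds without clipping.  Outside the fitted
range the curve continues linearly with the end-point slope, clipped to
bounds, and a warning is logged.  Energy in MeV (not range) is the
interpolation variable.  The top layer energy is configuration (default
175.6 MeV); the layer list builder is uniform by default but arbitrary
sorted lists are accepted, since real layer lists are non-uniform.

## Sensitivity analysis

`perturb_and_compare` applies one-at-a-time relative perturbations
(defaults sigma1 +-10%, sigma2 +-20%, w2 +-20%) and reports the percent FSF
change per field size.  A perturbation that would make the halo narrower
than the core is recorded as an invalid cell, not raised.  For a
range-shifter-like spot (sigma1 7 mm, sigma2 20 mm, w2 0.1, 5 mm spacing,
parallel beam) a +10% sigma1 change moves the 2 cm FSF by 6.2% while a
+-20% sigma2 change moves the 20 cm FSF far more than sigma1 does — the
identifiability split the fit relies on.  Note the sigma2 response at 2 cm
is asymmetric: +20% changes the FSF by under 0.4%, -20% by about 1.1%, so
"insensitive" holds cleanly only for widening halos.

## Synthetic campaigns

`TruthMachine` generates campaigns with known ground truth.  Defaults:
sigma1 at isocenter falls linearly from 9 mm at 80.3 MeV to 4.5 mm at
175.6 MeV, grows 8% per 100 mm of downstream offset; sigma2 = 3.5 sigma1;
w2 falls linearly from 0.12 to 0.04; measurement noise is multiplicative
Gaussian with 0.2% relative standard deviation (the reproducibility of
repeated chamber-charge ratios), independent per record.  These magnitudes
are plausible for a range-shifter beamline and are declared, not derived
from any real machine; they are fully configurable.  Measured and held-out
energies are picked from the 68-layer grid (10 each, interleaved), since
only deliverable layers can be measured.

Two noise modes exist: `direct` (noise applied to each normalized FSF; the
reference is exact) and `charges` (noise on every raw cumulative reading
including the reference, as in a real delivery, so one reference
fluctuation shifts a whole plane's FSFs coherently).

An optional tail mismatch mixes a unit-normalized areal Lorentzian,
w / (2 pi (r^2 + w^2)^(3/2)) with width w > sigma2, into the *generator's*
fluence only (fraction at most 0.1).  The fitted model stays
double-Gaussian, so residuals become structured — emulating the fact that
real spot tails are not intrinsically double-Gaussian.  The Lorentzian is
never fitted.

What the generator does **not** emulate: chamber volume averaging and
positioning error, drifts between deliveries, energy-dependent tail shapes
beyond the Lorentzian admixture, in-water scatter.  Passing tests therefore
demonstrate the estimator's correctness and noise robustness under the
stated noise model, not agreement with any particular physical machine.

## Numerical choices and problem sizes

- All lengths are millimetres internally; field sizes at the API boundary
  are centimetres (the field's reporting convention).
- Field sizes that are not even multiples of the spot spacing are rejected,
  not rounded (rounding shifts FSFs by more than 0.1%).
- A zero field size denotes the single-spot limit in the central-fluence
  evaluator; the spot-grid enumerator requires a positive size.
- End-to-end runs (250-record campaign, 10 fitted energies, 68-layer
  interpolation, 50-record held-out validation) complete in under a minute
  on one core; these are the problem sizes used in the tests and the
  acceptance script.

## Known limitations

- The fit assumes equal spot weights and a square grid; non-uniform maps
  are out of scope.
- No dose computation: the package characterizes in-air fluence only; dose
  kernels, in-water FSFs and absolute dose live in the treatment planning
  system.
- The smallest-sigma1 tie-break makes grid-only fits deterministic but the
  w2/sigma2 trade-off is genuinely shallow for near-single-Gaussian spots;
  in that regime sigma2 is reported but weakly constrained (w2 ~ 0 makes it
  non-identifiable by construction).
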