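# Methods

This note documents the models and estimators implemented in `porelab`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Coordinate and sign conventions

Coordinates are in ångström, currents in pA, times in ps (trajectories) or s
(recordings), voltages in mV. The pore axis is taken along +z (the membrane
normal), anchored at the x/y centre of mass of the protein (non-water,
non-ion) particles; z = 0 is the lowest protein atom, the "pore bottom", and
all profiles are reported on that scale. Positive applied voltage means a
negative potential on the cis (cap) side, so anions translocate cis→trans at
positive bias. Traces are stored with the acquisition-side sign; event
detection rectifies by the sign of the mean current so one code path serves
both polarities.

## Pore geometry

**Slice/ring radius profile.** The channel volume is sliced into layers of
1 Å along z. Within each layer and frame the local radius starts at a 1 Å
seed and grows in 0.5 Å rings: the annulus (r, r+0.5] is accepted while the
water/non-water atom-count ratio inside it exceeds 0.25. An annulus holding
water but no non-water atoms passes; a fully empty annulus stops the
iteration (and is counted in the profile metadata); a hard ceiling of
min(Lx, Ly)/2 prevents unbounded growth in layers outside the protein. The
profile reports mean ± sd across the selected frames, and the per-frame
radii (always on the 0.5 Å grid) are retained. The ratio can alternatively
be computed as the water fraction w/(w+p) via `ratio_mode`; on densely
water-filled phantoms the two readings give identical results, which is why
the cylinder oracle cannot distinguish them — the flag exists for real
trajectories where they may differ.

**Frame selection.** The default drops the first 25% of stored frames
(equilibration) and strides the remainder down to at most 16 frames,
mirroring the common practice of profiling the tail of a production run at a
coarse stride. Any explicit frame list overrides it.

**Region diameters.** Named landmarks default to the aerolysin sensing
residues — R282 ≈ 88.5 Å and R220 ≈ 73.5 Å (cap), K238 ≈ 22.5 Å and
K242 ≈ 10.5 Å (stem) on the pore-bottom scale — and the diameter is the mean
of 2r over layers within ±1.5 Å (a 3 Å window), pooling per-frame values for
the dispersion. The landmark map is a plain dict argument.

**RMSF.** Each selected frame is superposed onto the running mean structure
by the Kabsch algorithm (two passes: align to the first frame, average,
realign), then RMSF per residue is the root mean square displacement over
frames and the residue's atoms. A static trajectory gives exactly zero;
isotropic per-coordinate jitter σ gives √3·σ.

## Ion transport

**Charge-displacement current.** Between consecutive stored frames,
`I_inst = (e/(Δt·L_z))·Σᵢ qᵢ·Δzᵢ` over the ions in the analysis region, with
Δz unwrapped by minimum image in z. Minimum-image unwrapping is exact while
no ion moves more than L_z/2 between stored frames; the drift–diffusion
generator enforces that bound on its step (drift plus a 5σ diffusion margin),
which is stricter than merely requiring the step to be shorter than the
channel. The conversion is 1 e/ps = 1.602176634 × 10⁵ pA. Per-species sums
give I_K and I_Cl; the total is defined as their sum, so additivity holds by
construction and is asserted on every estimate. The default analysis region
is the full periodic box; an optional z-window restricts to a slab and
normalises by the slab height instead of L_z.

**Uncertainty.** The instantaneous-current series is split into 5 equal
blocks and the sd of block means is reported. Five blocks is a pragmatic
stand-in — the upstream experimental literature reports mean ± sd without
fixing the estimator — and is exposed as a parameter.

**Densities.** Per 1 Å layer, particles of the species with radial distance
≤ the layer's local radius are counted and divided by the cylindrical layer
volume πr²Δz; frames are sampled every 100 ps by default (nearest stored-
frame stride). Layers with zero/undefined radius are skipped and flagged.
For a uniform solution the density is independent of the radius profile used,
which is the volume-normalisation check in the tests; 1 mol/L corresponds to
6.022 × 10⁻⁴ particles/Å³.

**Open-current histograms.** Gaussian location/scale by least squares on the
binned histogram, with the sample moments always reported alongside as the
maximum-likelihood fallback. The reduced χ² against Poisson bin errors flags
poor fits (χ²/dof > 5 by default), e.g. bimodal mixtures; constant samples
return sd = 0 with a degenerate flag. Note that force-field KCl conductivity
is known to overestimate absolute currents by tens of percent, so absolute
agreement with experiment is not a meaningful target; the estimator is
validated against phantoms with closed-form currents instead.

## Event analysis

**Baseline.** I₀ and the baseline noise come from the dominant mode of the
sample histogram: the peak bin seeds the mode, the FWHM seeds the sd, and
mean/sd are refined on the samples within ±3σ of the mode. A trace without a
dominant mode raises rather than guessing.

**Detection.** An event opens when the rectified current drops below
I₀ − k·σ (default k = 4; the recovery benchmarks use k = 5) and closes on
re-crossing; events shorter than `min_dwell` (default 0.05 ms, i.e. 5
samples at 100 kHz) are discarded as the detector's dead time. These are
operational defaults — vendor software performs this step in the lab — and
all are exposed as parameters. Sensitivity of the detector is defined over
*detectable* ground-truth events (dwell ≥ dead time), since shorter events
are unobservable by construction; at 50% blockades with 2% relative noise
and k = 5, sensitivity exceeds 98% with zero false positives (the 5-sample
minimum also suppresses single-sample noise excursions, whose per-sample
probability at 5σ times ~10⁶ samples would otherwise produce a handful).

**Dwell times.** The default estimator is the censoring-corrected MLE:
τ = mean(dwell) − min_dwell, exact for an exponential by memorylessness. The
histogram method fits A·e^(−t/τ) to the binned distribution (the
falling-exponential presentation customary in the field) and agrees with the
MLE within 10% on clean samples of n ≥ 1000. Confidence intervals are
seeded bootstrap percentiles (1000 resamples by default).

**Capture rate.** τ_on is the mean of inter-event intervals
(startᵢ₊₁ − endᵢ) and f = 1/τ_on, with the exact χ² interval for an
exponential mean. Because Poisson arrivals are memoryless, these gaps remain
exponential in the arrival rate even when overlapping events are merged, so
f estimates the true arrival rate rather than the (lower) observed event
rate — the reason the field defines f through τ_on in the first place.

**Translocation classification.** ln(τ) is regressed on |V| across a voltage
series (≥3 voltages spanning ≥40 mV). If the 95% CI of the slope lies below
zero the series is labelled `translocation` (dwell decays exponentially with
driving force); if the CI contains zero and the relative spread of τ is
below 25% it is `no_translocation` (voltage-independent bumping); anything
else is `indeterminate`. Under the null the translocation label fires in
~2.5% of series, consistent with the ≥9/10 accuracy requirement per mode.

## Synthetic generators — what they emulate, and what they don't

All generators are deterministic given their seed.

**Channel phantoms** place wall pseudo-atoms on the surface r(z) of a
piecewise-linear radius profile (rings every `wall_atom_spacing`, staggered)
and fill the interior with water uniformly in 3-D at a set number density.
The default density is 3.0 particles/Å³ — deliberately much denser than real
water's ~0.1 atoms/Å³ — so that the innermost 0.5 Å annulus of a 1 Å layer
(area ≈ 3.9 Å²) is reliably populated in a single frame; the phantom is a
geometric oracle for the ring algorithm, not a water model. Layers left
without water are flagged in the metadata.

**Drift–diffusion trajectories** move K⁺/Cl⁻ ions along z by Euler–Maruyama
steps Δz = q·μ·E·Δt + √(2DΔt)·N(0,1) with periodic wrap in z and lateral
reflection at r(z); per-species mobilities allow asymmetric (selective)
transport. The closed-form steady current, I_s = n_s·q_s²·μ_s·E·e/L_z, makes
the estimator exactly testable: with D = 0 the match is to floating-point
precision; with D > 0 it holds within block standard errors. Defaults
(50 ions/species, D = 0.02 Å²/ps, 20 ps between stored frames) keep the
min-image bound satisfied with wide margin. What is *not* modelled: explicit
protein flexibility and electrostatics, water polarisation, ion–ion
interactions, access resistance — so passing tests validate the estimators,
not absolute channel conductance.

**Two-state traces** superimpose Gaussian noise on an open level I₀ with
Poisson event arrivals dropping the current to I₀(1 − depth) for exponential
dwells; overlapping events are merged and flagged, because no detector can
distinguish them. The benchmark conditions follow the experimental setup
(100 kHz sampling, ~61.5 pA open current at +100 mV, thousands of events)
with dilute arrivals (rate × dwell = 0.02 for the 5000-event dwell
benchmark; a 520 s trace at 10 s⁻¹) so that merging stays a sub-percent
correction and the ground-truth dwell distribution is the exponential being
estimated. What is not modelled: 1/f and instrument noise, filter rise
times, sub-states within events, baseline drift.

**Voltage series** draw exponential dwell ensembles with mean
τ(V) = τ₀·e^(−|V|/V_d) (translocating, default V_d = 40 mV over
80–160 mV) or constant τ₀ (non-translocating), the ground truth for the
classifier.

## Numerical choices and degenerate inputs

Text formats carry 6 significant digits for data values; trace timestamps
are written at 10 significant digits so the 1 ppm uniform-sampling invariant
survives a write/read round trip on long recordings. Readers reject — never
repair — invariant violations (duplicate ids, missing particles, non-monotone
frames, non-uniform sampling, missing metadata), naming the offending line
where applicable. Degenerate cases are explicit: constant samples give
sd = 0 with a flag, all-censored dwell sets are flagged rather than fitted,
single events raise on capture-rate estimation, and empty annuli terminate
ring growth with a metadata counter.

`build_report` regenerates the full table bundle deterministically: reruns
with the same seed are byte-identical (fixed float formatting), and a
different seed changes values but not schemas.

## Problem sizes

The test suite and the acceptance script run everything at desk scale: eight
cylinder phantoms of radii 3–10 Å (~40 layers each, one frame), drift
phantoms of 100 ions × 100–5000 stored frames (five seeds for the stochastic
benchmark), one 520 s and one 20 s recording at 100 kHz, and 20 classifier
series of 5 voltages × 1000 events. The full suite completes in well under a
minute of CPU time.

## Known limitations

* The ring-growth radius is quantized to 0.5 Å and systematically reads the
  wall position to within one increment; it is not a substitute for
  surface-based pore profilers on real structures.
* The drift–diffusion phantom is 1-D in its physics; it exercises exactly
  the observables the estimators consume (axial charge displacement, layer
  occupancy) and nothing else.
* The dwell censoring correction assumes a single-exponential distribution;
  multi-state kinetics would need mixture fits that are out of scope.
* Event detection is single-level threshold crossing; sub-state segmentation
  (CUSUM-style) is deliberately not implemented.
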