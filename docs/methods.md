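# Methods

## Tissue model

The simulated specimen is a rectangular block of neuropil, dimensions
`(x, y, z)` in micrometres. The y axis is cortical depth, partitioned into
layer bands I, II, III, V, VI (agranular cortex — no layer IV); the z axis
is the sectioning axis. Three object populations are laid down as
independent Poisson point processes within each band:

| population | geometry | default intensity (n/μm³) |
|---|---|---|
| asymmetric (Type I) synaptic junctions | circular disk, isotropic normal | 5.5 whole-block mean, graded 6.3 (I–II) → 4.7 (VI) |
| symmetric (Type II) synaptic junctions | circular disk, isotropic normal | 0.5, uniform across layers |
| myelinated axons | z-aligned cylinder segment, height = diameter | 0.47 whole-block mean, graded 0.05 (I) → 0.95 (VI) |

Layer depth fractions default to 0.10/0.15/0.25/0.25/0.25; the per-layer
intensities are scaled so the depth-weighted whole-block means equal the
configured truths exactly. Disk diameters are lognormal with CV 0.20;
asymmetric synapses carry a `perforated` flag at rate 7.5% (perforated
profiles are counted as single synapses but excluded from type-specific
length means). Positions are drawn in a domain dilated by 1 μm
(`edge_padding_um`) so the observed block sees the stationary profile
intensity right up to its faces; without this the truncated point process
produces a ~1–2% profile deficit near block edges.

## Virtual sectioning

Ultrathin sections are 60-nm z-slabs indexed along the serial series. The
default sectioning model treats the thin section as its mid-plane: a disk
yields a profile iff the mid-plane intersects it, and the recorded synaptic
junction length is the chord of the disk at that plane. For a disk of
diameter D hit by a uniformly random plane the mean chord is πD/4, and with
isotropic normals the pooled (hit-weighted) trace mean is
(π/4)·E[D²]/E[D] = (π/4)·μ_D·(1+CV²). The stock models invert this to
calibrate μ_D from the target trace mean of 207 nm. An alternative
`section_model="slab"` includes any disk overlapping the slab (chord taken
at the nearest in-slab plane), which adds grazing profiles and a
thickness-dependent overprojection bias; it exists for sensitivity checks
and is off by default.

Terminal membrane traces are not sectioned geometry: each synapse object
carries a terminal extent (lognormal, CV 0.35), and a profile's terminal
trace is the chord of a virtual disk of that extent at a uniform random
offset, giving a pooled trace mean of (π/4)·E[extent], calibrated to 489 nm.

Myelinated axons are z-aligned cylinder segments whose height equals their
diameter, so the sectional profile is a circle and the caliper height along
z equals the diameter — making the size-frequency size term (mean profile
diameter) the correct divisor for this population.

## Sampling hierarchy

Sections are selected as an arithmetic progression with period 5 and a
uniformly random start (systematic-uniform-random sampling), 10 sections per
animal by default. Within each layer band of each section, frames are
placed on one sampling line: a random height inside the band, equal pitch
along x, random phase — non-overlapping by construction, 10 fields per
layer per section by default. The counting frame is 3.87 μm × 3.87 μm
(area 14.9769 μm², the exact product). The counting rule: a profile is
counted iff its trace (segment for synapses, circle for axons) meets the
closed frame and does not touch the left or bottom (exclusion) edge;
corners belong to the exclusion edges. Segment–rectangle intersection uses
Liang–Barsky clipping; the implementation agrees exactly with a
computational-geometry oracle in tests.

## Estimators

**Size-frequency.** `N_V = N_A / d̄` with `N_A = Σcounts / Σframe areas`
and `d̄` the pooled per-animal mean trace of the type. For isotropically
oriented disks this estimator has expectation `N_V · E[D]²/E[D²] =
N_V/(1+CV²)`: the hit-weighting of larger profiles inflates `d̄` by exactly
the factor by which dispersion inflates the expected trace. At the default
CV of 0.20 the bias is −3.8%, which is why recovery tests and the
acceptance run report means near 5.29 for a configured truth of 5.5. The
`all`-synapse density is defined as the sum of the asymmetric and symmetric
estimates, making the additivity identity exact. Whole-block densities
combine per-layer estimates weighted by layer depth fractions (the correct
pooling when every layer contributes the same number of frames regardless
of thickness).

**Disector.** `N_V = Q⁻/(A·h)` with tops counted between a reference and a
look-up section. Pairs use adjacent ultrathin sections (h = 60 nm): with
isotropic disks, any h larger than the smallest caliper height misses
objects lying wholly between the planes; at 60 nm about 3% of disks fall
below the plane spacing, keeping the disector within the 10% concordance
band against size-frequency.

**Cavalieri.** `V = Σ areas × thickness × period`, converted exactly with
1 mm³ = 10⁹ μm³. Averaged over a uniform random grid phase the estimator is
exactly unbiased; tests verify <0.5% error on an analytic sphere and <0.1%
on a polynomial area profile. Volumes are reported in three layer bins
(I, II, III–VI — deep layers are hard to delimit from one another and are
measured as one bin, ~65% of the total), densities in five bins.

**Totals.** `total = N_V × V × 10⁹`, reported at 3 significant digits in
scientific notation.

## Terminal census

The per-frame axon-terminal tally is a statistical overlay, not sectioned
geometry: terminals per frame are Poisson with mean `n_synapses/1.163`, and
the summary computes the synapse/terminal ratio assuming 2.207 synapse
profiles per synapse-bearing terminal. This calibration reproduces the two
ratio statistics (≈52.7% of terminals bearing a synapse; ≈116.3 synapse
profiles per 100 terminals) without committing to a geometric terminal
model; the printed per-frame terminal tallies of the emulated study are not
mutually consistent with its printed densities, so no attempt is made to
force both.

## Statistics

Unpaired pooled-variance Student *t* (one-tailed for directional
hypotheses — stress reduces synapse totals and volume — two-tailed for axon
totals). The two-way ANOVA is the balanced fixed-effects closed form
(SS_A + SS_B + SS_AB + SS_within = SS_total, verified to 1e-9), which keeps
one-level designs well defined (F = t² for two groups) and rejects
unbalanced tables explicitly; statsmodels `anova_lm` serves as an
independent cross-check in the test suite. Post hoc comparisons test the
two groups within each level of the second factor using the pooled
within-cell mean square, with Sidak (`1−(1−p)^m`) or Bonferroni (`min(1,
m·p)`) adjustment over the m levels. Exact p-values are kept in machine
output; the text report renders thresholds (<0.05, <0.01, <0.001).

The sucrose generator produces a baseline week plus nine stress weeks:
control intake 11 g drifting +0.4 g/week, stressed intake losing 1.5 g/week
relative to control from week 2, residual SD 1.0 g. Under the Bonferroni
family over post-baseline weeks, the first significant separation lands at
week 4, matching the designed anhedonia onset.

## Problem sizes and numerical choices

The default block is 42 × 45 × 3.2 μm (≈39,000 objects); recovery
experiments use single-band compact blocks (e.g. 16 × 4.5 × 2.1 μm) with
6–10 sections and 4–25 fields so that 200-replicate experiments complete in
minutes on one CPU. Sparse populations (symmetric synapses, axons) use
wider sampled areas so per-replicate counting noise stays well inside the
recovery bands. All randomness flows through `numpy.random.Generator`
seeded from explicit seeds (spawned per replicate/animal); a fixed seed
reproduces every output byte for byte. Degenerate inputs are rejected with
explicit errors (zero block volume, negative densities, empty Cavalieri
series, unbalanced ANOVA, too-short section series) rather than silently
propagated; a type with zero counted profiles yields density 0 with the
size term flagged missing.

## What the synthetic data does and does not show

The simulator emulates the study design (two groups × 4 animals, the same
section/frame geometry, densities and trace lengths matching the reported
whole-cortex values, a deep-layer volume reduction of ≈13% under stress)
but not real EM material: there is no raster imagery, no
fixation/shrinkage artifact, no misclassification between synapse types,
no spatial clustering of synapses, and disk orientation is isotropic by
assumption (the emulated study does not report obliquity). Passing recovery
tests therefore validates the estimators and the sampling logic under the
stated geometric model — not the histology. The per-animal summary table
shipped with the package is a transcription of printed values; statistics
recomputed from it can only match the printed group values to within the
rounding of those inputs, which is the tolerance the tests use.

## Known limitations

- The size-frequency diameter-dispersion bias (−1/(1+CV²)) is inherent to
  the method; the package reports it rather than correcting for it, since
  the emulated analysis applies no correction either.
- The disector undercounts by the fraction of disks whose caliper height is
  below the section spacing (~3% at 60 nm, CV 0.2).
- The finite exclusion-edge convention (edges, not infinite exclusion
  lines) can over-count traces threading the corner regions; the effect is
  second order in trace length / frame side (<0.3% here).
- The sucrose ANOVA treats animal × week cells as independent replicates
  (ordinary two-factor ANOVA); no repeated-measures correlation structure
  is modelled.
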