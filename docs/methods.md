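# Methods

This note records the scientific model behind `pulsemorph`, the conventions
and defaults the implementation commits to, what the simulator does and does
not emulate, and the known limitations.

## Signal model

A particle transiting the laser produces, per channel, an ordered sequence
of non-negative intensities (arbitrary units) — the pulse shape. The spatial
calibration `um_per_sample` (μm per sample) converts sample counts to
lengths; it is instrument-specific and therefore mandatory metadata with no
built-in default (the simulator uses 2 μm/sample, giving pulse lengths of a
few tens to a few hundred samples for realistic element sizes). Detector
values are clipped at acquisition at `saturation_level` (default 10⁴ a.u.);
on the forward scatter this clipping is informative — dense pellet cores
saturate, loose structures do not.

Conventions used everywhere: sample indices are 0-based; sample intervals
are half-open `[start, end)`; "above trigger" is strict (`value > trigger`);
all gate inequalities are strict, so a value exactly on a threshold falls on
the complementary side. The trigger level defaults to 0 because the
instrument's internal trigger is not knowable from exported data; it is a
configuration field, not a hidden constant.

## Curve parameters

Per channel: `maximum`; `total` as the plain sum of samples (unit sample
width — the gate thresholds for totals are in arbitrary units, so no μm
weighting); `length` = number of recorded samples × `um_per_sample`;
`sample_length` = extent of the contiguous envelope between the first and
last above-trigger samples (interior dips below trigger stay inside — this
makes the size measure robust to noise dips); `fill_factor` = mean of the
above-trigger samples divided by the maximum, clipped to [0, 1]. The fill
factor is 1 exactly for a rectangular pulse and decreases as the pulse
deviates from a block; the mean/maximum form is the simplest normalized
statistic with that endpoint behaviour. A pulse entirely at or below
trigger reports sample length 0 and fill factor 0.

The gating ratios are FWS maximum / FWS fill factor and SWS total / sample
length. Zero denominators flag the ratio as NaN and route the particle to
`unclassified` — such degenerate pulses carry no usable shape information.

Which channel's sample length feeds the gates is configurable and defaults
to SWS (the size-vs-total gate pairs sample length with SWS total, and SWS
is the size parameter used for the size distributions).

## Gating tree

The decision tree and its default thresholds are listed in the README. Two
genuinely open points were resolved as follows:

* **Hyphae/small-clump overlap.** The hyphae rule (SWS total < 4·10⁴) and
  the small-clump rule (1.8·10⁴–9·10⁴) overlap; the small-clump gate takes
  precedence, and small elements matching neither gate go to a configurable
  fallback. The default fallback is `unclassified` rather than `hyphae`:
  the explicit hyphae bounds would otherwise be dead letters. Setting
  `fallback_small: hyphae` restores the alternative reading in which every
  unmatched small element is a hypha.
* **Gate geometry.** The published large-vs-small and small-clump gates are
  drawn as polygons that were never printed numerically; the defaults here
  are the rectangular envelopes implied by the threshold table, and both
  gates accept user-supplied polygons (ordered vertex lists in axis units)
  to emulate instrument-specific gate shapes.

The viability prefilter (green-fluorescence total strictly above 30 a.u.)
runs before gating; particles failing it are `background` and never enter
class counts. If the green channel is missing, `require_fl` decides between
treating the particle as background (default) or viable.

Cluster-assisted gate refinement standardizes the chosen features —
log10-transformed by default, since scatter totals and lengths are roughly
log-normal and span decades — and clusters with k-means (k-means++, 10
restarts, explicit seed) or average-linkage Euclidean hierarchical
clustering. Only 2–5 clusters are accepted: more were never morphologically
interpretable. The report is a cluster-vs-class contingency table; the
concordance score matches clusters to classes by maximum-weight assignment.

## Pellet descriptors

`detect_core` finds the above-trigger envelope of the FWS pulse, then the
first and last saturated samples; the core is the half-open interval between
them and the flanks are the annulus. Interior unsaturated dips belong to the
core: a degraded (vacuolized) centre only becomes annular area after the
pellet physically breaks there, at which point each fragment's RAD rises —
a behaviour the tests assert on constructed pulses. Saturation is tested as
`value ≥ saturation_level − ε` with ε = 0 by default (values are clipped at
acquisition); ε is exposed for re-scaled exports.

Particle length for RAD is the above-trigger envelope, not the full record,
so both descriptors are invariant to sub-trigger padding. RAD lies in
[0, 1) (0 for an end-to-end saturated pulse) and compactness in (0, 1] (a
core exists by precondition — callers must not request pellet metrics for
particles not gated as pellets; doing so raises an error rather than
returning a fabricated value).

## Summaries

Concentration = count / (pump speed × duration, in ml) × dilution factor.
Defaults mirror a typical protocol: 15 μl/s pump, 60–120 s measurements,
1:1000 dilution. Replicates pool by volume-weighted mean (equivalent to
pooling counts over the summed volume) with the between-replicate SD
reported; replicate error reports mean, sample SD (ddof = 1) and %CV.

SWS fractions divide by the summed SWS total of all *classified* viable
elements by default; a flag includes `unclassified` particles in the
denominator, since whether "all elements" includes them is a matter of
convention. Fractions over the four classes sum to 100 exactly when all
viable particles are classified.

Size distributions are relative-frequency histograms of SWS sample length
(configurable to FWS length), with 20 equal-width bins from 0 to the 99.5th
percentile by default; fixed bin edges should be passed when comparing runs.
The class unions "hyphal aggregates" (small clumps + large clumps + pellets)
and "large elements" (large clumps + pellets) are predefined.

## Microscopy metrics

Area is the foreground pixel count × pixel area. The perimeter is the
marching-squares boundary polygon at level 0.5 with two rounds of B-spline
corner cutting: the raw staircase overestimates a smooth boundary by ~5%
(which squares to ~11% in roughness), and the smoothing brings a rasterized
disk's roughness to within ~7% of the ideal 1.0 while changing a filled
square's by < 1%. Smoothing operates at the pixel scale, so roughness is
consistent across rasterization resolutions for smooth shapes; literal
pixel-replication upscaling preserves the blocky boundary and legitimately
reports it as rougher.

The convex area is the hull of the foreground pixel *corners* (centers
± 0.5 px). Corners rather than centers guarantee `area ≤ convex_area` for
every mask — the union of pixel squares is contained in the hull of their
corners — hence fullness ≤ 1 always, single pixels included.

Skeleton loops are detected from the Euler number of the topological
skeleton (components − Euler = holes). Dark-core detection needs graylevel
input (largest connected sub-threshold region inside the eroded mask); a
pure binary mask never reports a core, because the core threshold is
exactly the kind of illumination-dependent setting that made perimeter
measurements fragile in practice, and it is therefore exposed rather than
defaulted silently.

## Simulator

The generator is phenomenological, not optical: each channel's pulse is a
half-sine hump over the particle's transit, scaled to a class-conditional
target, padded with sub-trigger zeros; pellets get a ramp–plateau–ramp FWS
trapezoid whose plateau is generated *above* saturation and clipped down to
it (so plateaus sit exactly at the saturation level, as in acquisition),
with an optional interior dip emulating a degraded core. Multiplicative
log-normal noise (σ = 0.05) is applied before clipping; the annular ramps
and the dip are afterwards capped just below saturation so that the stored
sample-unit geometry — envelope length, annular fraction, saturated core
fraction — remains exactly recoverable, which is what makes the
one-sample-width recovery bounds of the tests meaningful.

Default class priors (uniform ranges) place every particle at least 10%
(relative) inside its gate: hyphae 20–80 μm with SWS totals below the
small-clump interval; small clumps 30–90 μm inside the 1.8·10⁴–9·10⁴ band;
large clumps 130–250 μm below the pellet total threshold and below FWS
saturation; pellets 150–350 μm with 1.0–1.5·10³ a.u./μm of SWS total per
sample length, annular fractions 0.15–0.45 and a 30% chance of a
0.1–0.5-deep core dip. The default mixture (45% hyphae, 25% small clumps,
15% large clumps, 10% pellets, 5% background) represents a mid-fed-batch
population where dispersed forms dominate counts. `validate_against`
rejects prior/gate combinations violating the margin, so closure tests
cannot silently degrade.

What the simulator does **not** emulate: real pulse-shape texture
(multi-lobe clump signatures, asymmetric transits), channel cross-talk,
coincident particles, size-dependent optical saturation of large-pellet
annuli, or any growth kinetics. Passing closure tests therefore demonstrate
that the analyzers invert the generator's geometry and that the gates
partition feature space as documented — not that the default thresholds are
correct for any particular strain or instrument, which is why every
threshold is configuration.

Determinism: one `numpy` PCG64 generator seeded from `seed` drives a run;
time-course runs derive per-timepoint seeds as `seed·1000 + i` (kept below
2³¹). Fixed seeds reproduce datasets bit-identically, and the csv_long
writer emits floats via `repr` so write→read round trips are bit-exact.

## Problem sizes

The test suite uses 400–10 000 particles per simulated run and masks up to
~300 px across; the acceptance script uses a 10⁴-particle mixture, 2 000
particles for the O(n²) average-linkage clustering, 8-timepoint scenarios
of 600 particles, and completes in well under a minute on one CPU. The
generator itself sustains ~10⁵ particles per minute.

## Known limitations

* The vendor's native acquisition format is not parsed; data must be
  exported to the documented dialects.
* FCS export of scalar feature tables is not implemented; CSV is.
* Gate polygons default to rectangles; published polygon gates exist only
  graphically and must be supplied via configuration if needed.
* RAD and compactness are one-dimensional transects of a three-dimensional
  structure; large pellets saturate more easily across the annulus, biasing
  RAD low — an instrument physics effect no pulse-level correction can
  undo.
* Orange/red fluorescence channels are stored and round-tripped but not
  analyzed.
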