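# Methods

`octlayers` segments the eleven macular retinal boundaries (ILM, o-NFL,
o-GCL, o-IPL, o-INL, o-OPL, o-ONL, o-IS, o-OSJ, o-OS, o-RPE — "o-X"
denoting the outer boundary of layer X) in OCT B-scans with an
edge-detection pipeline built on the classical Canny recipe, modified
for layered, near-horizontal anatomy. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
phantom does and does not establish.

## Segmentation model

**Enhancement.** The B-scan (intensities in [0, 1], rows axial) is
denoised with a 3×3 binomial Gaussian. Two polarity-specific gradient
images are computed by correlating each A-scan with a 4×1 template:
`[-1, -1, 1, 1]ᵀ` responds to dark→bright interfaces (ILM, o-GCL,
o-INL, o-ONL, o-IS, o-OS), `[1, 1, -1, -1]ᵀ` to bright→dark ones
(o-NFL, o-IPL, o-OPL, o-OSJ, o-RPE). Only axial steps respond, so the
vertical edges cast by vessel shadows are invisible by construction.
The template is anchored at its third tap (offsets −2…+1), so an
intensity step between rows r−1 and r peaks exactly at row r; negative
responses are clipped to zero so each polarity channel sees only its
own interfaces. The gradient is multiplied point-to-point with a
large-scale box-smoothed copy of the image (default 9×9, a config
field), which damps responses where the local mean intensity is low —
speckle in the vitreous and the faint posterior vitreous face line.
Per A-scan non-maximum suppression (window 3, one flag per plateau at
its topmost row, floor 5% of the channel maximum) yields the peak
point map.

**Boundary search.** Peak points inside two 30 px lateral bands seed
paths. A path grows column by column in both directions until it spans
the image; at each step the candidate set is the 3 (healthy) or 5
(diseased, steeper slopes) pixels of the adjacent column centred on
the current row, and the candidate whose boundary-enhanced value is
closest to the *origin seed's* value is chosen. Three refinements
matter in practice:

* *Frozen reference.* Comparing to the running current-pixel value
  (the alternative reading of the search rule) turns the path into an
  absorbing random walk under multiplicative speckle: one off-ridge
  step re-anchors the comparison to background and the path never
  returns (a measured 16 px drift on a single path at speckle level
  0.2). With the reference frozen at the seed's value, an off-ridge
  step is corrected at the next column. `value_reference="running"`
  restores the alternative.
* *Near-tie direction keeping.* Exact value ties are measure-zero on
  continuous data, yet the tie rule (keep the previous step's
  direction) is precisely what carries a path straight across a vessel
  shadow. Candidates within 1% of the signal maximum of the best
  count as tied.
* *Signal-lost straight extension.* When even the best candidate is
  below one third of the reference value the interface is locally
  absent (shadow, destroyed boundary) and the path extends straight
  ahead, resuming value tracking where signal returns. Lost columns
  are recorded per path.

Seed selection filters the band peaks twice: a lateral-coherence vote
(a seed row must carry a peak within ±1 row in ≥ 60% of its band's
columns — real interfaces are continuous ridges, speckle peaks are
scattered) and a per-column greedy minimum axial separation of 8 px
(below the closest same-polarity interface spacing the generator
produces, 10 px). Without these, speckle satellite seeds form path
bundles that bridge adjacent boundaries.

**Superposition and selection.** The N paths of a channel are
superposed; each pixel's probability is `100 · (paths through the
pixel) / N`. Because every path contributes exactly one pixel per
column, each column sums to exactly 100. True boundaries collect far
more paths than anywhere else, but note the ceiling: a channel hosts
five or six boundaries, so even unanimous agreement on one of them
tops out near 100/6 ≈ 16.7%. The dual thresholds must therefore sit
well below that plateau; the defaults are low = 2, high = 8 (percent),
i.e. a strong pixel carries at least half of one boundary's unanimity
share. Selection is standard hysteresis: strong pixels kept, weak
pixels kept iff 8-connected to a strong one.

**Candidate curves.** The mask is reduced to full-width candidate
curves by per-column run tracking rather than plain component
labelling, for a geometric reason: an 8-connected mask cannot follow
an interface steeper than one row per column, so steep disease domes
fragment it. Pixels carried mostly by signal-lost paths are dropped
first (the probability map itself is untouched). Each column's pixel
runs (probability-weighted centroids) are associated across columns to
tracks by slope-extrapolated prediction (tolerance 2.5 px + 0.5 px per
gap column, capped at 8 px, below the inter-boundary spacing);
established tracks match first, and a bright track never extends onto
a run far dimmer than its running brightness (stray-path streaks lie
on dark background). Tracking runs in both lateral directions — a
track that loses a steep descending flank is recovered by the opposite
scan, for which the same flank is a well-anchored ascent — and the
resulting pieces are merged when they agree on their overlap (median
distance ≤ 1.5 px) or when their trimmed-end extrapolations meet
between them. Curves that genuinely cross (above on one side, below
on the other) are segment-swapped hybrids of two interfaces and are
replaced by their element-wise min and max; near-duplicates are
dropped; a curve must be lit (≥ 5% of the channel maximum) along
≥ 75% of its length and span ≥ 90% of the width (lateral extent, with
≥ 70% measured support).

**Identification.** Names are assigned in a fixed order driven by
per-curve statistics: ILM = per-column shallowest dark→bright
interface (majority vote); o-IS = brightest remaining dark→bright
interface; o-ONL and o-OS = its nearest neighbours above and below;
o-INL above o-ONL; o-RPE = brightest bright→dark interface below o-OS;
o-OSJ = the bright→dark interface between o-IS and o-OS (strictly in
the mean and per-column in ≥ 75% of columns — the flanking curves are
themselves noisy estimates, so a literal every-column test would
reject the true interface for a single grazing column); o-OPL and
o-IPL above o-ONL and o-INL; o-NFL = first bright→dark interface under
the ILM (majority vote); o-GCL — the faintest interface — last,
between o-NFL and o-IPL. Candidates dimmer than 10% of the channel's
median candidate brightness are discarded beforehand. Unassignable
boundaries raise an error naming the first failure. Finally the eleven
curves are smoothed with a 1-D Gaussian along the columns (σ = 3
columns by default) and strict depth ordering is enforced with a
minimal 1 px separation.

**Evaluation.** The mean unsigned positioning error between two curves
L₁, L₂ over N A-scans is `MUE = (1/N) Σⱼ |L₁(j) − L₂(j)|`, reported in
μm via the axial pixel pitch (3.9 μm/px by default); columns where
either curve is undefined are excluded from N and counted. Thickness
maps are per-column boundary differences in μm; the conventional spans
are ILM→o-IPL (superficial vascular complex), o-IPL→o-OPL (deep),
ILM→o-OPL (inner retina) and o-OPL→o-RPE (outer retina — the last
span is a package convention, config-overridable). Volumes may be
segmented every k-th slice with linear interpolation of the boundary
surfaces across skipped slices.

## Synthetic phantom

The generator renders a stylised macula: twelve axial compartments
(vitreous, ten retinal bands, sub-RPE background) with reflectivities
chosen to honour the dark/bright alternation of the eleven interfaces
(vitreous 0.05; NFL 0.75; GCL 0.35; IPL 0.60; INL 0.30; OPL 0.60; ONL
0.10; IS 0.30; IS/OS 0.95; OS 0.45; RPE 0.95; background 0.12) and
band thicknesses of 12, 14, 14, 12, 10, 28, 10, 8, 10, 12 px at a
3.9 μm axial pitch on a 512×480 canvas. Boundary curves are sums of
two low-frequency cosines (default amplitude 2 px, seeded random
phases) plus a Gaussian foveal dip (25 px deep, 140 px wide) applied
to the inner boundaries with decaying weights, and an optional
AMD-like dome (default 45 px tall, σ = 15 px) elevating the outer
boundaries fully and the inner ones partially (edema-like), so the
truth ordering never self-intersects. The dome's maximum slope is
≈ 1.8 px/column: deliberately beyond 3-neighbourhood path continuity
and within the 5-neighbourhood search. Degradations: a single-row
posterior vitreous face line at 15% of the ILM contrast, vessel
shadows multiplying all rows below the ILM by an attenuation factor,
and multiplicative speckle (pixel-wise gamma with unit mean and
variance = level², the standard OCT speckle surrogate; spatially
uncorrelated). Each column of a noise-free phantom is an exact step
function whose steps sit at the first pixel row at or below the
(possibly fractional) truth rows; detectors are therefore quantised to
that rasterised boundary, and sub-pixel comparisons against the
fractional truth carry an irreducible ≈ 0.5 px bias.

What the phantom does *not* emulate: physically accurate speckle
statistics (no lateral correlation, no log compression), motion
artefacts, curved Bruch's membrane geometry, choroidal texture, or
real pathology beyond the single dome. Passing tests on the phantom
establishes that the pipeline implements the intended mechanisms and
tolerates the modelled degradations — not clinical-grade performance
on patient scans.

## Measured operating envelope

Numbers below are computed by this repository's test suite at the
stated problem sizes (512×480 phantoms; 20-phantom healthy corpus,
10-phantom dome corpus — sizes chosen to exercise every mechanism at
desk scale).

* Healthy conditions (speckle 0.2, one vessel shadow, PVF line,
  3-neighbourhood): 20/20 phantoms segment; per-boundary mean MUE
  0.35–0.73 px (worst single boundary ≤ 1.7 px).
* Dome alone (no speckle, 5-neighbourhood): 10/10 segment, worst
  boundary 0.65 px.
* Dome + speckle 0.2 (+ shadow + PVF): only 3–4/10 segment. The
  lateral smearing of a slope-1.8 interface dims its enhanced ridge by
  roughly 60%, which at 20% multiplicative noise falls into the
  background-noise band; the dominant path bundles then defect on
  every descent, and the deep-interface masks decompose into
  directional halves that cannot always be reassembled. This is the
  known weak spot of the approach for steeply fluctuating boundaries;
  the corresponding acceptance check is left failing rather than
  weakened.
* Robustness at fixed geometry: adding a vessel shadow (attenuation
  0.3, width 8) to a clean phantom moves every detected boundary by
  ≤ 1 px in 100% of columns. Raising speckle to 0.3 exceeds the
  envelope: the NFL band's in-band noise stays above the signal-lost
  threshold, trapping defected o-NFL paths, and the o-NFL mask
  vanishes across the foveal dip. No single lost-threshold setting
  satisfies both the dome corpus and the 0.3-speckle comparison; the
  defaults favour overall fidelity and the 0.3-speckle check is also
  left failing.

## Defaults at a glance

| parameter | default | meaning |
| --- | --- | --- |
| denoise kernel | 3×3 binomial | pre-smoothing of the B-scan |
| gradient template | 4×1, anchor at 3rd tap | polarity-specific axial step detector |
| smoothing window | 9×9 box | large-scale image for the enhancement product |
| NMS floor | 5% of channel max | suppresses vitreous speckle peaks |
| seed bands | 30 px each side | lateral regions providing seed points |
| seed coherence | 60% of band columns | lateral-continuity vote on seed rows |
| seed separation | 8 px | one seed per interface per column |
| neighbourhood | 3 (healthy) / 5 (disease) | per-step candidate span |
| value reference | seed, frozen | comparison value for path growth |
| tie tolerance | 1% of signal max | near-ties keep the previous direction |
| lost threshold | 1/3 of reference | below it the path extends straight |
| dual thresholds | low 2, high 8 (%) | hysteresis on path probability |
| candidate span | ≥ 90% extent, ≥ 70% support | minimum width of a boundary curve |
| curve smoothing | σ = 3 columns | final Gaussian smoothing |
| axial pitch | 3.9 μm/px | pixel-to-micrometre conversion |
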