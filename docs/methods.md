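# Methods

## The quantification problem

In a scratch (wound-healing) assay, a gap is scraped into a confluent cell
monolayer and its re-population by migrating cells is photographed over
time, typically at 0, 24 and 48 h. The quantity of interest is the fraction
of the initial wound still open at each timepoint. scratchquant measures
this from phase-contrast micrographs without any learned model, using a
single texture statistic: local Shannon entropy.

## Local-entropy segmentation

For every pixel, the 256-bin intensity histogram of a disk-shaped
neighborhood of radius *r* ("disc size") is formed and its Shannon entropy

    H = − Σ_{p_i > 0} p_i · log2(p_i)        [bits]

is computed, with out-of-frame positions filled by reflect padding
(numpy-style reflection without edge duplication; this avoids the spurious
low-entropy rim at frame edges that zero padding would create, which a
below-threshold rule would misread as wound). A cell-covered region in
phase contrast is texture-rich — its neighborhood histogram is spread over
many intensity levels and H is high — while a cell-free scratch is nearly
flat and H is close to zero. H is bounded by min(8, log2 n) for a disk of
n pixels, and depends only on the histogram multiset, so it is invariant
under any intensity relabeling that is injective on the values present.

The pipeline is, in order:

1. **Entropy map** over the disk of radius `disc_size` (interpreted as a
   radius, the dominant rank-filter convention; a `disc_is_diameter` flag
   is provided because the convention is ambiguous in general usage).
2. **8-bit rescale** so an integer threshold applies. Default
   `per_image_max` maps the image's own maximum entropy to 255; a
   `fixed_8bit` mode (0–8 bits → 0–255) is kept for cross-image
   comparability. The default threshold 92 then sits at ≈36 % of the
   per-image maximum, i.e. ≈2.9 bits on a fully textured 8-bit frame.
3. **Threshold**: candidate wound = rescaled entropy **below** the
   threshold (the scratch is the texture-poor side).
4. **Morphological cleanup**: closing then opening with a disk of radius
   `cleanup_radius` (default ⌈disc_size/4⌉, tying the cleanup to the
   texture scale). Closing first bridges debris speckle inside the wound;
   opening then removes monolayer-side noise.
5. **Component filter**: connected components (8-connectivity default)
   smaller than `min_component_frac` (default 0.5 %) of the frame are
   dropped; **all** surviving components are kept, not only the largest,
   because a nearly closed wound fragments into several openings and a
   largest-only rule would bias late timepoints downward. No positional
   prior (e.g. a central-band assumption) is used: hand-made scratches are
   not guaranteed central, and the size filter suffices.

Per-cell-line presets carry the (disc size, threshold) pairs 20/92
(TOV-21G) and 50/92 (SK-OV-3). The degenerate case of a constant image —
zero entropy everywhere, rescaling to all-zero — yields a full-frame wound
mask, which is the correct cell-free-field limit. Entropy values below
1e−12 bits are snapped to exact zero so this limit is reached despite
floating-point residue in the sliding update.

A `apply_override` operation lets a human supervisor replace, intersect or
union the automatic mask with a raster mask or polygon; the result is
flagged `overridden` and its areas recomputed. This mirrors supervised use,
where automatic output is reviewed per image.

### Implementation and numerics

The filter is a numba-compiled sliding-histogram pass: moving the window
one pixel right updates one entering and one leaving pixel per disk row
(O(disk diameter) per pixel), together with a running Σ c·log2 c
maintained from a precomputed table. The histogram itself is exact integer
bookkeeping; the running sum is re-initialized at each row, so float drift
is bounded by one row of updates and the map agrees with a brute-force
per-pixel histogram oracle to better than 1e−9 everywhere we test.
scikit-image's rank-entropy filter — an independent implementation of the
same statistic — is used as a second cross-check on frame interiors.

### Known bias and validity regime

The entropy transition at a wound edge spans about one disk radius: a
pixel just inside the wound still sees textured pixels through its disk,
so its entropy exceeds the cutoff and the detected wound is narrower than
the true one by ≈0.75·r per edge. The estimate is therefore accurate in
*relative* terms only when the band is wide compared to r (the generator
tests enforce band ≥ 5·disc size), and the absolute area-fraction error
scales as ≈1.5·r / frame-width. Because the bias is nearly constant across
timepoints it largely cancels in the T0-relative closure percentage, but
it does not cancel exactly: the last timepoints of a nearly closed wound
are the least reliable, which is also where the original workflow used
human supervision.

## Closure kinetics

For a series of masks of one well, open_pct(t) = 100 · area(t) / area(T0).
T0 is exactly 100 by definition; closure_pct = 100 − open_pct. Values
above 100 (apparent wound expansion — detachment or segmentation artifact)
are reported uncapped with an `EXPANDED` flag rather than clipped, so the
evidence reaches the supervisor. Frames are assumed to be re-located fields
of the same well; no registration is attempted (a frame-size mismatch is a
hard error). A zero wound area at T0 is an error ("no initial wound
detected"), with manual override as the suggested remedy.
`compare_conditions` tabulates mean, sample SD (0 when n = 1) and n per
condition and timepoint.

## Dose–response (MTT) metrics

Viability % = 100 · (T − Tc)/(C − Cc), with T/C the 570 nm absorbances of
treated/control wells and Tc/Cc their 630 nm backgrounds; the ratio is
computed before scaling so the analytic identities (T=C gives 100, T=Tc
gives 0) are exact in floating point. Growth inhibition is 100 − viability,
and GI50/GI25/GI10 are the concentrations giving 50/25/10 % inhibition.
These are found by **linear interpolation in log10(concentration)** on the
measured curve, not by 4PL fitting: interpolation is assumption-free,
deterministic, and exact at curve nodes. The first adjacent pair bracketing
the target viability on a locally *decreasing* segment is used; explicit
statuses cover targets above or below the tested range and curves that
cross the target only while locally increasing (`non_monotone_ambiguous`).
For a potent compound the GI10/GI25 concentrations can legitimately fall
below the lowest tested dilution — `below_range` is the correct result
there, not a failure.

## Fluorescence ratios

`fluorescence_ratio` encodes the three stain conventions: AO/PI returns
green/orange (viability proxy), JC-1 returns orange/green (mitochondrial
membrane potential proxy), and NAO passes mean green fluorescence through
unchanged (total mitochondrial mass proxy). A zero denominator raises an
`undefined_ratio` error rather than returning infinity.

## ΔΔCq fold change

Replicate Cq values are averaged arithmetically (the standard practice;
averaging 2^−Cq instead would weight outlier replicates multiplicatively),
ΔCq = Cq(target) − Cq(reference, default HPRT1) per sample, ΔΔCq =
ΔCq(treated) − ΔCq(control), fold = 2^−ΔΔCq. Amplification efficiency is
assumed to be 100 % (base 2); no efficiency calibration is implemented.

## Synthetic data: what it emulates and what it does not

`make_scratch_image` renders a monolayer as i.i.d. uniform 8-bit noise —
the maximum-entropy texture, making the wound/monolayer entropy contrast a
property of the geometry rather than of a particular texture model — with
an optional two-level speckle alternative. The wound band has a known
width (round(wound_frac · frame extent)), a flat intensity of
`wound_level` = 128 plus Gaussian noise of `wound_noise_sd` = 1.0 gray
levels (the scale of flat-field camera noise; with ~1-level noise the band
carries ≈2.1 bits of local entropy, clearly below the ≈2.9-bit cutoff that
threshold 92 implies, which is the premise of the method), and edges
perturbed by seeded ±1 random walks of amplitude `edge_roughness` = 3 px,
mimicking a ragged pipette scratch. The returned truth mask is the realized
band, exact by construction. Closure series reuse the texture seed and
scale the band width, so timepoints share their background.

What the generator does **not** emulate: optics (PSF, shading,
vignetting), cell-scale structure (lamellipodia, partially migrated single
cells inside the wound, debris), illumination drift between timepoints,
and stage misalignment. Passing tests therefore demonstrate that the
pipeline recovers known geometry under ideal texture contrast, not that
it handles every pathology of real phase-contrast imaging — that is what
the manual-override path is for.

`make_plate` draws absorbances from a four-parameter logistic
v(c) = bottom + (top − bottom)/(1 + (c/GI50)^hill), by default hill 1,
top 100, bottom 0, eight 2-fold dilutions from 200 µM (matching the common
serial-dilution design), blank 0.05 AU, control signal 1.0 AU, three
replicates. `make_cq_table` holds the reference gene at Cq 20 in both
samples, draws each target's control ΔCq uniformly from [2, 8] cycles, and
sets the treated ΔCq to control − log2(fold), so the noiseless table
inverts exactly.

## Problem sizes used in the checks

Segmentation-recovery checks run both presets on frames of height 4·r and
width 80·r (1600×80 and 4000×200 px) so that the band is ≥ 5·disc size at
every tested fraction while the edge-bias contribution (≈1.5·r/width ≈
0.019) stays inside the ±0.03 recovery tolerance — i.e. inside the
method's stated validity regime. The closure-kinetics and monotonicity
simulations use disc size 8 on 2680×120 px frames: the smallest simulated
band (closure fraction 0.1 of a 0.3-fraction wound, ≈80 px) is then 10·r,
whereas the 20/50 presets would need frames several thousand pixels wider
to keep the final band inside the validity regime. The GI and ΔΔCq checks
use the generator defaults; noisy ΔΔCq recovery is summarized as the
median over 100 seeds at 0.2-cycle replicate noise.

## Limitations

- The threshold semantics depend on the rescale mode; per-image-max
  normalization makes 92 adaptive per frame but means the threshold is not
  comparable across frames with very different texture content. The
  fixed-8-bit mode trades this the other way.
- No auto-tuning of presets is provided; "precision adjustment" for a new
  cell line means choosing disc size and threshold by supervised
  inspection.
- Wounds narrower than ~5 disc radii are systematically under-measured
  (transition-zone bias above); near-closure estimates should be reviewed.
- One field per well; no averaging of multiple fields, no registration,
  no statistical testing across conditions.
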