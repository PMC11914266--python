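# Methods

## Model and procedure

`vennloc` quantifies area-based colocalization among k ≥ 2 fluorescence
channels. The pipeline is: binarize each channel inside the ROI → partition
the ROI pixels into the 2^k − 1 exclusive Venn regions → score each region
of interest with a Colocalization Factor (CF) against a random-placement
null → aggregate CFs across cells and, for three channels, infer the
scaffold.

**Venn partition.** Each ROI pixel receives a k-bit membership code; region
areas are integer bin counts of these codes. Integer arithmetic makes two
conservation identities exact, and they are asserted in tests: the
exclusive areas sum to the union area, and for each channel the patterns
containing it sum to that channel's marginal mask area.

**Null model and CF.** The null assumes each channel's pixels are placed
independently and uniformly. For a region "all of `include`, none of
`exclude`" the expected ROI fraction is
∏_{i∈include} p_i · ∏_{j∈exclude} (1 − p_j), with p_i the channel's
observed area fraction; CF is the observed region fraction over this
expectation. Two conventions are exposed because the phrase "multiply the
channel percentages" is ambiguous for exclusive regions: `exclusion_aware`
(default) keeps the (1 − p_j) factors and is the exact independence null
for an exclusive region; `paper_literal` multiplies only the included
fractions, matching the simpler "product of the channel percentages" rule
as it is usually stated in figure legends. The two
coincide whenever `exclude` is empty — in particular for the all-channel
overlap region. The convention used is recorded in every CF record. Since
p_j is a few percent in the sparse-droplet regime, the conventions differ
by only a few percent for pair regions.

A CF of 0/0 (an included channel with an empty mask) is flagged
`undefined` and carried as NaN — never an exception and never silently
dropped; cohort summaries exclude flagged records and report the exclusion
count. An expected fraction of zero with a nonzero observed area is
impossible (the observed region fraction is bounded by every included
p_i), and the code asserts this rather than handling it.

**Cohort inference.** Cells are the replicate unit; no within-cell pixel
correlation model is attempted. Per region we report mean CF, SEM and n
over cells with defined CFs. Across regions we run a one-way ANOVA (cells
as replicates) and compare each region against a reference region using
Welch t tests with Holm familywise correction — Welch because cohorts are
small (typically 5 cells) and equal variances across regions are
implausible when one region is strongly enriched; Dunnett would be an
acceptable alternative, so the test and correction names are recorded in
the output rather than assumed. Degenerate inputs take their analytic
limits instead of raising: all values identical ⇒ F = 0, p = 1; zero
within-group variance with distinct means ⇒ p = 0.

**Scaffold call.** For three channels the candidate scaffold is the
channel *excluded* from the exclusive-pair region with the minimum mean
CF; the call is significant only if both other pair regions reject against
that minimum region (Welch t, Holm) at the configured alpha (default
0.05). Minimum-CF ties (relative difference below 1e−9, a pure
floating-point guard) yield no call with the ordering reported. The call
is equivariant under channel relabeling.

## Synthetic droplet generator

The simulator emulates sparse superresolution fields of ~100-nm protein
microdroplets: per channel, `droplets_per_channel` spots rendered as
isotropic Gaussians (width `psf_sigma`, amplitude `peak_intensity`) on a
constant `background_level` with additive Gaussian read noise
(`noise_sd`). Placement and rendering are **toroidal** (wrap-around), so
every channel's mask distribution is exactly translation-stationary; this
makes the independence null exact rather than edge-biased, which is what
lets the CF = 1 control hold to Monte-Carlo precision.

A designated `scaffold_channel` can tether `round(tether_fraction × n)` of
each other channel's droplets to uniformly chosen scaffold droplets, the
center displaced by an isotropic Gaussian of sd `tether_distance_sd`
(wrapped). `tether_fraction = 0` is the null condition. Droplet radii are
drawn (`droplet_radius_mean/sd`) and stored in the ground truth but do not
modulate rendering — every spot uses the single `psf_sigma`; the radius
parameters are retained so a future version can couple them without a
config break.

Defaults define the study conditions and were fixed once: 256×256 px at
30 nm/px, 150 droplets/channel, psf_sigma 60 nm (2 px), peak 1000 on
background 100 with noise sd 10, tether_distance_sd 40 nm. These put each
channel's Otsu-binarized fraction near 4–7%, the sparse regime typical of
SIM droplet fields; no published droplet density or intensity statistics
exist for the motivating experiment, so these are calibration choices, not
measured values. Reproducibility: a cell is a pure function of (config,
seed); cohort cells use per-cell seeds taken from numpy's
`SeedSequence(cohort_seed)` counter stream (masked to 31 bits), so a
cohort's first m cells coincide with the m-cell cohort of the same seed.

**What the generator does not emulate:** 3D structure, drift or chromatic
aberration, Poisson (shot) noise, intensity heterogeneity between droplets,
within-channel droplet clustering, and cell-shaped ROIs (the simulated ROI
is the full frame). Passing calibration therefore shows the statistics are
correct under stationary, independent-or-tethered placement — not that
Otsu is the right threshold for any particular microscope, nor that real
cells lack confounding spatial structure (e.g. organelle exclusion zones
would violate the independence null for *all* channels jointly and inflate
every CF).

## Binarization

Default method is Otsu per channel, computed from ROI pixels only, mask =
plane > threshold. The acquisition literature this models specifies only
"binarize in ImageJ/Fiji", so the method is configurable (`fixed`,
`quantile`) and the threshold actually used is stored with every mask and
in the per-cell CSV for audit. A constant-intensity plane makes Otsu
degenerate and raises an error suggesting a fixed threshold. The ROI
defaults to the whole frame; cell segmentation is out of scope and ROI
masks are accepted as files (nonzero = inside).

## Numerical choices

- Areas are integers end to end; fractions enter only at the CF division.
- Pixels are unit areas; row-major 0-based indices; physical conversion via
  `pixel_size` (nm/px) when known.
- CSV output uses full double precision (`%.17g`) for byte-stable
  regression diffs; reruns with the same seed are byte-identical.
- The toroidal-shift Monte-Carlo estimate used in tests (random wrap-around
  translations of all but one channel) is an independent oracle for the
  analytic expected fraction: it preserves within-channel structure while
  destroying cross-channel association.

## Problem sizes used in the test and calibration suites

Chosen as the package's own validation design: the CF = 1 control uses
1000 simulated cells (the triple region's per-cell CF has sd ≈ 0.7 in this
geometry, so 1000 cells give SEM ≈ 0.02, comfortably resolving the ±0.05
acceptance band); conservation checks use 50 random mask triples from 8×8
to 512×512; the Monte-Carlo oracle comparison uses 20 cells × 500 shifts
at 3 SE; scaffold recovery uses 100 tethered and 100 null cohorts of 5
cells; ANOVA type-I calibration uses 1000 synthetic null cohorts.

## Known limitations

- Area-based only: no intensity-weighted coefficients (Pearson, Manders),
  no Costes scrambling, no object-based nearest-neighbor analysis.
- The independence null treats the whole ROI as exchangeable; real
  cytoplasm is not spatially homogeneous, and a shared excluded volume
  inflates CFs for all regions. Comparisons *between* regions (the
  scaffold logic) are more robust to this than absolute CF values.
- The empirical p_i used in the CF denominator makes CF a ratio of
  estimates; its per-cell distribution is skewed when expected areas are
  a few pixels. Cohort means remain unbiased under the null (verified by
  the calibration suite) but single-cell CFs at tiny expected areas are
  noisy.
- The scaffold call assumes exactly one bridging protein among three; it
  does not model simultaneous or higher-order scaffolding.
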