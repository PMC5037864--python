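# Methods

## The measurement model

The quantity of interest is the signed axial distance between fluorescent
nanoparticles and the apical surface of an epithelial monolayer, estimated
from two-channel confocal z-stacks.  The package fixes one axis convention in
`stack_io` and nowhere else: z grows from the apical (lumen-facing) side
toward the basal side, so a particle below the membrane — inside the cell —
has a *negative* distance.  All coordinates are voxel-centre based, 0-based,
and converted to µm exactly once, at measurement time.

The per-stack chain is: (optional) iterative maximum-likelihood
deconvolution → channel-specific lateral smoothing → axial membrane
thinning → Otsu segmentation with volume/intensity filters and watershed
splitting → surface extraction → centre-of-mass-to-surface distances.  Pooled
distances across stacks are histogrammed and fitted with a Gaussian; the peak
position x_c and its standard error carry the biological verdict
("penetrating" when x_c + 2·SE < 0).

The distance is deliberately computed as the z-component of the vector to the
*3D-nearest* surface voxel, not as a vertical ray-cast: over an undulating
surface these differ, and the 3D-nearest reading matches how object-analysis
tools report reference-object distances.  Exhaustive brute-force search over
all surface voxels is cheap enough that the implementation *is* the oracle
definition (and is tested against an independently coded one).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `spacing` (dx, dy, dz) | 0.06, 0.06, 0.2 µm | voxel size; lateral sampling must be isotropic.  60 nm lateral avoids undersampling at high NA; 0.2 µm is a typical confocal axial step and resolves sub-µm depths |
| `psf_sigma_um` | (0.12, 0.35) | lateral/axial Gaussian PSF widths, plausible for NA 1.4 oil immersion at visible wavelengths |
| `deconvolve`, `deconv_iterations` | on, 40 | Richardson–Lucy against the theoretical PSF.  The pipeline passes all recovery tests with deconvolution off; organelle sizing needs it on (below) |
| `qd_smooth_sigma_px` | 2 | lateral noise suppression on the particle channel |
| `membrane_smooth_sigma_px` | 30 | heavy lateral smoothing for a homogeneous membrane segmentation |
| `membrane_shift_px` | 2 | axial thinning shift; the retained band is the apical membrane edge |
| `membrane_min_voxels` | 10⁵ | keeps only the main apical sheet (inclusive ≥) |
| `qd_min_voxels` | 450 | minimal volume of a credible particle object (inclusive ≥) |
| `qd_rel_intensity_min` | 0.05 | peak-intensity floor as a fraction of the threshold-to-maximum range |
| `watershed_sigma_um` | 0.1 | pre-watershed smoothing, converted anisotropically to voxels |
| `seed_min_distance_px` | 7 | minimum seed separation; one FWHM of the *smoothed* spot profile (σ_eff = √(2²+2²) px), which suppresses noise-driven oversplitting while still separating spots ≥ 0.6 µm apart |
| `bin_width_um` | 0.2 | depth-histogram bin width (≈ the axial sampling) |
| `se_factor` | 2.0 | significance multiple for the penetrating/membrane-associated call |

The 5 % intensity filter is applied to each object's *maximum* intensity:
among the candidate statistics (mean, max, seed intensity) the maximum is the
most robust against volume-dependent dilution and is the one that keeps a
dim-but-large blob out.

Volume thresholds are inclusive (objects *below* the floor are discarded;
exactly-at survives).  Connectivity is the full 26-neighbourhood.  Watershed
markers are numbered in lexicographic voxel order and flooding runs on the
inverted smoothed intensity, so the labelling is deterministic; components
without a detected seed are seeded at their own maximum so no component is
ever lost.  Particle filtering runs *after* watershed splitting, so a genuine
single particle split off an agglomerate is judged on its own volume.

## Numerical choices

**Otsu on an exact lattice.**  The threshold maximises between-class variance
over a 256-bin min–max histogram.  Whenever the optimal split falls in an
empty histogram gap the variance curve has an exact plateau and float noise
would make the argmax platform-dependent; the implementation therefore
maximises in exact integer arithmetic over bin indices (the argmax is
invariant under the affine map from indices to intensities) with a
first-maximum tie-break.  Foreground is `intensity > threshold`.

**Richardson–Lucy.**  The blur operator is a normalised Gaussian with
reflective (symmetric) boundaries and generous kernel truncation (6σ —
iteration amplifies kernel-tail error).  A symmetric kernel under symmetric
padding has unit column sums, so the multiplicative update conserves total
intensity (verified to relative 1e-6) and preserves non-negativity.  An
all-zero stack is returned unchanged with a warning; a zero-width PSF is an
identity kernel and a fixed point.

**Membrane thinning at the boundary.**  `out = stack − shift_basal(stack, s)`
clamped at zero, with the shifted copy edge-replicated at the apical border.
Without the edge fill the first `s` planes would keep their full background
level, which empirically hijacks the Otsu threshold of the thinned channel
and corrupts surface extraction; with it, a uniform background cancels
everywhere while any slab ≥ s voxels from the border behaves exactly as the
plain subtraction.  Negative values are clamped because negative intensities
are meaningless to the subsequent thresholding.

**Histogram fit.**  The Gaussian is fitted to histogram *counts* (matching how
depth histograms are reported), initialised at the sample mean/SD, with the
plain sample estimates reported alongside.  A Shapiro–Wilk screen at α = 0.01
gates adoption of the fit: clearly non-Gaussian pools report the median
instead.  Pools of fewer than 20 distances are refused.  When the pooled
sample spans fewer than six bins at the configured width — synthetic
flat-membrane data are orders of magnitude tighter than real data — the
histogram is re-binned at range/12 so the fit has a resolvable peak; the
effective width is reported in the result.  All-equal samples short-circuit
to a degenerate result (x_c = the value, σ = 0, flagged).  Distances are
sorted on entry, making every downstream quantity order-invariant.

## The synthetic generator

`scenes.render_scene` emulates a labelled monolayer: a bright membrane sheet
of configurable thickness whose *upper* boundary is the ground-truth surface,
sub-resolution particle emitters rendered as anisotropic Gaussian PSFs
(quantum dots at ~13 nm are far below the diffraction limit, so the PSF is
the only observable shape), agglomerates as clusters of emitters jittered in
a lateral disc, optional PSF-blurred spherical organelles, and
Poisson-plus-Gaussian detection noise applied after blur (defaults give
SNR ≈ 10 at a default spot peak; `poisson_scale` is a photon gain with 0
disabling shot noise).  Membrane roughness is a band-limited sum of
low-frequency sinusoids — a smooth stand-in for microvillated surfaces,
sufficient to exercise surface extraction but not a model of individual
microvilli.

Two independent seeds separate concerns: `geometry_seed` drives roughness
phases and agglomerate jitter, `seed` drives only noise.  Specs equal up to
`seed` therefore produce identical noiseless renders, and identical specs
render bit-identically.

**What the generator idealises.**  The membrane sheet is rendered with sharp
(sub-voxel anti-aliased) axial edges rather than PSF-blurred ones (an
optional `blur_membrane` flag exists).  An axially blurred sheet thresholded
at Otsu level would shift the extracted surface ~0.3 µm apically — a bias
that in real data is counteracted by deconvolution before segmentation, but
that would contaminate every synthetic benchmark run without deconvolution.
With sharp edges and a grid-aligned membrane depth the extracted surface is
exact, so recovery tests score the measurement chain, not the generator's
optics.  Consequently, passing tests demonstrate correctness of the
*measurement* given a well-localised membrane; they do not quantify the
surface-localisation error of blurred, noisy, microvillated real membranes.
Other idealisations: no spectral bleed-through, no depth-dependent
aberration, no autofluorescence, noise parameters asserted rather than fitted
to any instrument.

**Canonical exposure scenes.**  `monolayer_scene` places particle
*agglomerates* — clusters of 5 emitters jittered in a 0.3 µm disc — rather
than isolated single emitters.  This mirrors the imaging reality the default
filters encode: at exposure-level concentrations particles agglomerate, and
at 0.2 µm axial sampling an isolated PSF-sized spot peaks near ~430
supra-threshold voxels, right at the 450-voxel single-particle floor (the
Otsu threshold lands scale-freely at a fixed fraction of the spot peak, so no
amplitude choice changes this).  Clusters widen the footprint well past the
floor while keeping every emitter's true offset exact; all cluster members
share the condition's offset, so the pooled peak position is unbiased.

## Problem sizes used in validation

End-to-end recovery runs ten 128×256×256-voxel stacks (dz = 0.2 µm) per
condition, four agglomerates of five spots each (200 spots per condition), at
true offsets −1.3, −0.5, 0.0 and +0.5 µm, with default noise and
deconvolution off; recovered peaks agree with truth to < 0.01 µm and the two
extreme conditions classify as penetrating / membrane-associated.  Organelle
sizing uses six 0.6 µm and six 0.9 µm spheres in 48×160×160 stacks with the
default chain (deconvolution on): measured 0.69 µm and 0.93 µm.  Without
deconvolution the PSF inflates a 0.6 µm sphere to ≈ 0.94 µm at Otsu level,
which is why the default chain deconvolves first.  Smaller grid-based scenes
back the unit and property tests.

## Known limitations

- The deconvolution is textbook Richardson–Lucy with a Gaussian PSF; it is
  not expected to match any proprietary implementation bit-for-bit, and no
  measured-PSF or regularised variant is provided.
- Surface extraction reports the apical-most supra-threshold voxel per
  column: axial quantisation of the surface is one voxel (0.2 µm default),
  and distances are measured against the *thinned* membrane band (thinning
  exists precisely to sharpen this reference).
- Equivalent-sphere diameters retain a residual PSF inflation of
  ~0.05–0.1 µm after 40 deconvolution iterations.
- The classification threshold (x_c + 2·SE < 0) treats only the fitted peak;
  it makes no claim about population fractions or tails.
- Proprietary microscope formats (LIF, CZI) are out of scope; convert to
  TIFF/OME-TIFF upstream.  Lateral sampling must be isotropic.
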