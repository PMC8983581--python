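# Methods

This note records the models, estimators, defaults and numerical choices
behind punctaquant, and what the synthetic-data validation does and does
not demonstrate about real microscopy data.

## Conventions

All distances are micrometres, all coordinates voxel-centred and 0-based,
and in-memory stacks are ordered (channel, z, y, x) with per-axis physical
voxel sizes carried alongside the data. Every filter scale, separation and
cutoff in the public interface is specified in μm and converted per axis to
voxel units internally, so anisotropic stacks (e.g. 0.2 μm z × 0.1 μm
lateral) are handled without special-casing.

## Nucleus segmentation

Each z-layer of the DNA channel is Gaussian-smoothed (default σ = 0.25 μm
laterally), thresholded, closed (disk radius 0.3 μm, to heal boundary dents
where dim chromatin texture dips below threshold), hole-filled and cleaned
of sub-μm² specks; the per-layer masks are then combined into 3-D
connected components, and components below a minimum volume (default
50 μm³) are discarded as debris. Nuclei touching the stack boundary are
retained but flagged, since downstream metrics normalize by nuclear volume.

The threshold is a single Otsu value computed on the whole smoothed DNA
volume and applied layer by layer. A per-layer Otsu variant is available
(`threshold_method="layer_otsu"`) but not the default: in the dim cap
layers at a nucleus' top and bottom a per-layer threshold turns generous
and inflates the apparent volume by 4–8% on noiseless test ellipsoids,
whereas the volume-wide threshold stays within ~3% (well under 1% for
mid-sized nuclei).

## Punctum detection

Detection is scale-normalized multi-scale LoG filtering (σ ladder 0.1–0.5
μm by default, each response multiplied by σ², per-voxel maximum over the
ladder), thresholding, and watershed on the inverted response seeded at
response maxima separated by at least 0.3 μm (≈ the lateral resolution;
exact physical spacing is enforced by a greedy pass with lexicographic tie
breaking, so results are deterministic).

Several robustness measures matter in practice:

- **Noise whitening across scales.** Small LoG scales pass far more camera
  noise than large ones, so a plain maximum lets the noisiest channel bury
  faint blobs. When robust high-frequency differences indicate the image
  carries noise, each scale's response is standardized by its own robust
  fluctuation level (1.4826·MAD) before the maximum. Noise-free images
  skip this step, so matched-scale selectivity of the σ²-normalized
  response is exact there.
- **Threshold estimation region.** Otsu runs on the positive response of
  the nuclear interior (0.25 μm below the surface); the nuclear envelope is
  itself a strong intensity step whose edge response would otherwise
  contaminate the statistics. A noise floor — median + 5 × the
  median-to-84th-percentile half-width of the response in cytoplasm more
  than 0.5 μm from any nucleus — prevents Otsu from splitting the noise
  distribution when blobs occupy a tiny voxel fraction, and an absolute
  floor of 10⁻⁶ × the image intensity scale ignores numerically faint
  structure such as blur tails.
- **Detection region.** DNA-stain masks systematically under-cover the
  protein-defined nuclear space, so the detection region is the nucleus
  mask dilated by 0.25 μm, and puncta whose centroid falls within 0.3 μm
  outside the mask are still assigned to the nearest nucleus.
- **Half-maximum refinement.** Each watershed region is refined to the
  voxels (of a lightly denoised copy, σ = 0.08 μm) above
  background + 0.5 × (region peak − background). The LoG support of a blob
  extends well beyond the object, so unrefined labels overestimate punctum
  volume by 20–90%; the half-maximum isosurface of a blurred sphere sits
  close to the true boundary, bringing median volume errors to ~10–15%.
  Candidate regions whose peak does not rise 15% above the local
  background are rejected as envelope-edge artifacts.

On noise-free synthetic scenes (50 puncta, radius 0.30 ± 0.04 μm) this
chain achieves recall and precision ≥ 0.96 with median volume error
~12%; at a dense/light contrast of 10 and Gaussian noise giving SNR 5 the
count error stays within ~10%.

## Per-cell metrics

For each nucleus: puncta density = 1000 × count / nuclear volume (μm³);
*V*ₚ = mean punctum volume; total concentration = calibrated mean protein
intensity over the nuclear interior; PCC = Pearson correlation of protein
vs DNA intensities over the nucleus mask; periphery fraction = fraction of
puncta whose centroid lies within 0.5 μm of the nuclear surface
(anisotropy-aware Euclidean distance transform).

Concentration metrics exclude a 0.3 μm shell at the nuclear envelope,
where the signal blends into the cytoplasm under the PSF (including it
depresses [LP] by ~10% on synthetic scenes). [LP] additionally excludes a
0.3 μm halo around each punctum so PSF bleed does not inflate the light
phase.

**Dense-phase estimation.** A punctum comparable in size to the PSF loses
peak intensity to blur and gains a dim skirt, so the pooled mean over
segmented punctum voxels understates [DP] — by 20–60% across realistic
radius/PSF combinations in our numerical study — and *K*ₚ inherits that
bias. The default estimator (`dp_method="peak_corrected"`) instead models
each punctum as a uniform sphere imaged through a Gaussian PSF: the
punctum's equivalent radius comes from its refined volume, the centre
attenuation of such a sphere under the stated PSF is computed numerically
on a half-voxel grid (cached), and [DP] = [LP] + (peak − [LP])/attenuation,
pooled volume-weighted across the nucleus' puncta. Validation on isolated
blurred spheres shows ≤ 7% error for radii 0.25–0.5 μm and PSF σ up to
(0.25, 0.1, 0.1) μm; full-pipeline *K*ₚ recovery is within 10% for true
values 2–20 with noise off. The uncorrected pooled mean remains available
as `dp_method="voxel_mean"`. If no PSF is supplied the correction
degenerates to the raw peak.

Intensity→concentration calibration is a linear map with user-supplied
slope and offset; the identity default reports arbitrary units. *K*ₚ — and
ΔG_Tr whenever the offset is 0 — is a ratio and therefore
calibration-independent. ΔG_Tr = −RT ln *K*ₚ uses R = 1.987 × 10⁻³
kcal·mol⁻¹·K⁻¹ and T = 310.15 K by default (live-cell imaging at 37 °C);
negative values mean partitioning into the dense phase is favorable.

Zero-punctum nuclei have a defined density (0) and total concentration but
undefined *V*ₚ, [DP], *K*ₚ and ΔG_Tr — encoded as missing, never as 0.
Pipeline outputs keep these cells in density tables and exclude them from
*V*ₚ/*K*ₚ tables; per-construct summaries report mean ± standard error
under the same convention.

## FRAP

Traces are normalized by background subtraction and division by an
unbleached reference (cancelling acquisition photobleaching), then rescaled
so the pre-bleach level maps to 1. The recovery model is the canonical
single exponential I(t) = I₀ + A·(1 − 2^(−t/T₁/₂)); T₁/₂ is the half-time
of the fitted rise by construction, and the mobile fraction is
M_f = A/(1 − I₀). Fitting is bounded least squares with the rate
initialized from a log-linear fit of the residual decay; non-convergence,
a collapsed amplitude (immobile trace), or M_f outside (0, 1.05] are
reported honestly via `converged=False` with a diagnostic message — never
a silent fallback.

The floor I₀ can be pinned (`fix_floor`) when the bleach depth is set by
the protocol — the full-scale normalization convention. This matters
quantitatively: with a free floor, the information bound for T₁/₂ at noise
sd 0.05 on 50 points spanning six half-lives is ~5.8% median error, while
pinning the floor brings it to ~4.3%; the Monte-Carlo recovery study in the
test suite fits full-bleach traces with the floor pinned at 0 and achieves
~4% median error on both parameters.

## In vitro assays

Dilution-series fields are reduced by per-pixel maximum-intensity
projection over z. Condensates are counted as connected bright components
above an Otsu threshold with area ≥ 0.05 μm² (submicron objects); a noise
guard rejects fields whose candidate foreground does not rise 3 SD above
the background. A field is condensate-positive when it holds at least 3
objects (resisting single-speck false positives — presence/absence by eye
is not algorithmic, so the count threshold is an explicit choice). C_sat
is reported as a bracket: the highest condensate-free concentration below
the lowest condensate-positive one, with 0 / +∞ at the ends of the ladder
and a warning on non-monotone detection patterns. Turbidity series are
summarized as mean ± SD of buffer-subtracted A340 per concentration; SD is
left undefined below two replicates and the three-replicate convention is
noted in the log.

## Sequence features

FG valence is the number of FG dipeptide occurrences in a region (scanned
with overlap-safe lookahead, case-insensitive); GLFG tetrapeptides are
counted separately and contribute exactly one FG each. Mutation specs
(F→A, FG→AA) name the 1-based position of the F of each targeted motif and
are validated against the parent sequence, so a spec that drifts out of
register fails loudly with the offending position. Coordinates in the
public interface are 1-based inclusive, matching protein-literature
convention. Composition fractions support whole-region values and
stride-1 sliding-window profiles.

## Synthetic data: what it emulates, and what it does not

The scene generator renders an ellipsoidal nucleus (soft-edged indicator,
default semi-axes 2.2 × 3.6 × 3.6 μm — a deliberately scaled-down nucleus
that keeps default stacks at ~31 × 89 × 89 voxels) containing
non-overlapping spherical puncta painted with supersampled partial-volume
coverage (3× per axis; total intensity matches the analytic scene integral
to ~0.1%), a DNA channel of smoothed random texture (correlation length
0.4 μm, contrast 0.5), anisotropic Gaussian PSF blur (σ = 0.25, 0.10,
0.10 μm — typical spinning-disk values), Poisson photon noise (1 photon
per intensity unit) and additive Gaussian read noise (sd 2). Punctum
placement can be biased onto DNA-dense or DNA-poor texture
(`dna_overlap`), which spans the observed colocalization contrast; puncta
may optionally be placed in the cytoplasm to emulate constructs that
localize to both compartments. Voxel size defaults to (0.2, 0.1, 0.1) μm,
matching 0.2 μm plane spacing. All randomness flows from a single seed;
identical parameters and seed give bit-identical stacks.

FRAP traces come from the same recovery model the fitter uses, with
configurable bleach depth, optional exponential acquisition-photobleaching
drift applied to ROI and reference alike, and Gaussian noise. Dilution
series paint diffraction-limited spots only at concentrations at or above
the set saturation threshold, with counts growing logarithmically above
it. Construct sequences interleave FG/GLFG motifs with spacers drawn from
an F- and G-free alphabet, so emitted motif counts are exact by
construction.

Passing parameter-recovery tests on these scenes demonstrates that the
measurement chain is unbiased under its own forward model: correct
geometry and unit handling, calibrated segmentation, and a dense-phase
estimator that inverts the blur it models. It does not demonstrate
robustness to what the generator omits: spatially varying background and
illumination, non-Gaussian PSF tails and spectral bleed-through,
chromatin-correlated protein background, aspherical or touching puncta,
punctum motion during acquisition, and touching nuclei (no watershed
splitting of nuclei is attempted). Real-data use should treat the defaults
as starting points and the config surface (smoothing, scale ladder,
thresholds, separations, calibration) as the place to adapt.

## Numerical choices and degenerate inputs

- Watershed seeds are deduplicated deterministically (strongest first,
  lexicographic tie-break); reruns with one config and seed are
  byte-identical, and output tables embed a config hash, package and numpy
  versions, and the seed.
- Blank inputs are valid: an all-background DNA channel yields an empty
  label volume with a warning; a punctum-free protein channel yields zero
  detections; an empty record list writes a header-only table only when
  explicitly allowed.
- Group comparisons default to the two-sided Mann–Whitney U test (per-cell
  metrics are skewed); Welch's t test is available and the choice is
  recorded in the output. Constant groups are flagged as degenerate.
  Linear trends are descriptive OLS fits with pointwise 95% bands and an
  optional log₁₀ response.
- The sphere-centre attenuation used by the dense-phase correction is
  evaluated on a half-voxel grid with 4σ support and cached by rounded
  (radius, PSF, voxel) triples.
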