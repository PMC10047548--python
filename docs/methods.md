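# Methods

## The assay

`carrierscope` quantifies cell expansion on spherical hydrogel microcarriers
from multi-channel 3D lightsheet volumes.  Three measurements feed every
downstream statistic:

1. **Cell number** from the nuclear-stain channel.  Nuclei are detected as
   bright blobs with an anisotropy-aware Laplacian-of-Gaussian at scale
   σ = d/(2√3) for an expected nucleus diameter d (default 10 μm; the
   per-axis voxel σ is d/(2√3) divided by the axis pitch).  Candidate
   maxima below a high-pass intensity threshold are discarded — this is
   what rejects debris, which is both smaller (so its peak is strongly
   attenuated at the 10 μm detection scale) and dimmer than nuclei — and
   maxima closer than 0.7 × d are merged keeping the brighter.  Centroids
   are refined to sub-voxel precision by a local centre of mass of the blob
   response.
2. **Cell volume** from either the cytoplasmic-stain channel or the
   label-free elastic-scattering channel.  Voxels above a high-pass
   threshold are grouped into 26-connected components; components smaller
   than a minimum volume (default 400 μm³, well below a cell) are removed
   as debris.  Object volume is exactly voxel count × voxel volume.  In
   scattering contrast the nucleus scatters little and appears as a cavity
   inside the bright cytoplasm; since that cavity is a contrast artifact
   and not missing cell volume, each object is hole-filled by default so
   scattering-derived and fluorescence-derived volumes are directly
   comparable.
3. **Microcarrier number** from the scattering channel.  The hydrogel
   interior scatters below both cells and medium, so the *medium* is
   identified as the border-connected region of intermediate intensity
   (between the low-pass threshold and, optionally, the cell high-pass
   threshold); everything else — carrier interiors, bright cells bridging
   them, enclosed pockets — forms solid bodies.  A small morphological
   closing (4 μm) repairs the thin intermediate-intensity lens the PSF
   leaves between an attached cell and the carrier interior.  The Euclidean
   distance transform of the solid mask peaks at sphere centres; peaks are
   found with minimum separation equal to the minimum carrier diameter
   (default 90 μm, against a true diameter of 120 ± 6.2 μm), which splits
   touching spheres inside aggregates.  Each peak's centre is refined by
   the centroid of the near-apex region of the distance cone.  The radius
   is estimated as the 25th percentile of the centre-to-boundary distance
   distribution (plus half a voxel for the inner-boundary offset): the
   distance-transform value itself is a *minimum* over thousands of noisy
   boundary directions and is biased low by extreme-value statistics,
   while cell bumps and contact necks only populate the upper tail of the
   distance distribution and leave a low quantile untouched.  Detections
   with diameter below the size filter are discarded.

All detection parameters are expressed in μm and converted through the voxel
geometry, so the pipeline is resolution-agnostic.  Thresholds are explicit
recorded values by default (Otsu and percentile auto-thresholds exist as a
convenience); the defaults shipped in `PipelineConfig` are matched to the
synthetic generator's default optics and must be re-chosen for other data,
exactly as one would set a manual threshold in a commercial package.

## Cells-per-microcarrier statistics

Each detected nucleus is assigned to the microcarrier with the nearest
surface (signed distance |centroid − centre| − radius), if within a maximum
attachment distance (default 15 μm — the height at which a nucleus sits
inside a spread cell above the surface; ties break toward the lower carrier
id).  Microcarriers are clustered into aggregates when centre distance is
below contact_factor × (rᵢ + rⱼ) (default 1.05).  The CPM histogram is taken
over populated microcarriers only, and aggregate members can be excluded so
the histogram is not weighted against single carriers; cluster-size strata
are reported alongside.

Because empty microcarriers are excluded by construction, CPM data are
modelled with a zero-truncated Poisson, P(k; λ) = e^(−λ)λ^k / (k!(1−e^(−λ)))
for k ≥ 1.  The MLE solves λ/(1 − e^(−λ)) = sample mean by Brent's method on
the bracket [10⁻⁶, 50] (tolerance 10⁻⁸; the bracket covers any plausible CPM
— the densest cultures reach ~19 cells/carrier).  The standard error comes
from the observed Fisher information,
−ℓ″(λ) = n(mean/λ² − e^(−λ)/(1−e^(−λ))²).  A sample mean ≤ 1 lies on the
boundary (all counts 1) and is reported at the bracket's lower bound with
`converged=False`.  `sampling_adequacy` bootstrap-resamples the CPM data to
find the smallest number of populated carriers whose 95% CI half-width for
the mean CPM meets a target fraction of the mean; one rng drives all
subsample sizes so a tighter target can never need fewer carriers.

The growth correlation is ordinary least squares of total cell volume on
cell number (volume is the response, matching how such trends are plotted),
with R² = 1 − SS_res/SS_tot; total least squares was deliberately not used.

Mean single-cell volume uses the per-object mean while each cell is its own
segmented object; in confluent cultures, where cells merge into networks
that cannot be instance-segmented, it falls back to total volume / nucleus
count and the output records which estimator was used.

Morphology: sphericity = π^{1/3}(6V)^{2/3}/A with the area A from a
marching-cubes mesh of the object mask at the 0.5 isolevel.  The mask is
smoothed with σ = 0.6 voxel before meshing — meshing the raw binary
staircase overestimates the area of smooth objects by ~10% and would bias
sphericity low, while heavier smoothing erodes genuine corners (with 0.6 a
rasterized sphere measures ≈ 0.98 and a cube ≈ 0.85 against the closed form
(π/6)^{1/3} ≈ 0.806).  The nuclear-to-cytoplasmic ratio V_nuc/(V_cell −
V_nuc) matches nuclei to cells by containment of the nucleus centroid.  Both
are meaningful only at low confluency where cells do not overlap.

## The synthetic generator

The generator is the validation substrate: it emulates the features the
assay exploits, with defaults that describe a mid-culture sample.

Scene model: microcarriers with diameter N(120, 6.2²) μm placed either
dispersed (centre distance ≥ 1.15 × (rᵢ+rⱼ), so a dispersed scene never
trips the 1.05 contact criterion) or as a connected touching cluster grown
sphere by sphere (aggregates).  Per-carrier cell counts are drawn from a
zero-truncated Poisson (default λ = 2) or given explicitly.  A cell is a
spherical-shell cap conforming to its host sphere (spread morphology;
default height 8 μm above the surface), with its cap angle solved from a
target volume drawn from N(1800, 300²) μm³; caps on one carrier are placed
with non-overlapping angular separation.  Each cell contains one 10 μm
nucleus centred at mid-shell.  Debris are 1–4 μm spheres in the medium.  An
optional "infiltration" flag adds a thin process extending into the carrier
core (a visualization phenomenon, not used in quantification tests).  The
recorded true volume of every object is *defined* as its rasterized mask
voxel count × voxel volume, so volume recovery is measured against an exact
discrete truth.

Rendering: four channels — nuclear (nuclei only), cytoplasm (whole cell
body, nucleus region at 0.7×), membrane (1-voxel boundary shell), and
scattering with the contrast ordering the assay requires: cytoplasm (1000)
> medium (300) > carrier interior (150), nucleus cavity (80) < cytoplasm,
debris at 600 (dimmer and smaller than cells, so both debris filters are
exercisable).  The rendered cavity is the nucleus restricted to the cell
body eroded by a cortical cytoplasm layer (default 3.5 μm): a real nucleus
is wrapped in cytoplasm, and the layer must be thick enough to survive the
PSF blur or the cavity would leak into the medium and stop being a closable
hole.  No quantitative scattering ratios are published for cell vs agarose
vs gelMA; these intensities are free parameters of the generator and are
documented as such.

Optics: Gaussian PSF (σ lateral 1 μm, axial 2 μm), then optional depth
attenuation, optional stripe artifacts (attenuated y-rows running along the
illumination x-axis), then noise: Poisson shot noise on the scaled
intensity plus Gaussian read noise (sd 5), clipped at 0 — the standard
sCMOS model.  The fluorescence gain default (0.025 photons/unit) gives
SNR 5 at the nominal nuclear peak; the scattering channel uses gain 0.1
(SNR 10 at the cytoplasm peak) because elastic scattering is photon-rich —
in practice the illumination must be attenuated orders of magnitude to
avoid detector saturation, so scattering images are not shot-limited the
way dim fluorescence is.

Determinism: one master seed; per-stage sub-seeds (placement, counts, cell
geometry, debris, stripes, noise) are derived from it, so identical
parameters give bit-identical volumes and tables.

Desk-scale geometry: tests and presets use 2 μm isotropic voxels rather
than an acquisition-scale 0.2 × 0.2 × 0.45 μm grid (a full-resolution
150 μm cube is ~10⁸ voxels); since every filter is specified in μm the
pipeline is unchanged by resolution.  Preset problem sizes (1–20 carriers
per scene, ten 100-nucleus benchmark scenes, an 8-sample growth series)
were chosen as the smallest scenes that still exercise each failure mode
(touching spheres, debris confusion, confluency growth range).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: textured cytoplasm and non-cap cell shapes, spatially
varying background, uneven illumination and photobleaching, refractive
light propagation (the refractive-index physics appears only
phenomenologically as the contrast ordering), cell overlap at high
confluency, and motion.  Threshold defaults transfer to real data only as a
procedure (choose and record), not as numbers.

## Numerical choices and edge cases

* Axis order (c, z, y, x) in memory, (z, c, y, x) on disk; 0-based voxel
  indices with physical coordinate (i + 0.5) × pitch; intensities uint16 on
  disk (camera convention; acquisition bit depth was assumed 16-bit),
  float in memory.
* Connectivity is 26-neighbourhood everywhere; spot merging separation is
  0.7 × object size; both fixed for reproducible tie-breaking.
* A detection threshold above the channel maximum yields an empty result
  with a warning finding, not an exception; zero populated microcarriers
  yields a defined empty summary.
* Carrier detection pre-smooths the scattering channel (σ = 2 μm, small
  against the 90 μm size filter) so shot noise inside the dim hydrogel
  interior cannot punch holes in the solid body; cell segmentation applies
  no preprocessing by default, and stripe removal (a 1-D median across the
  stripe-normal direction, since filtering along the stripe cannot remove a
  uniformly attenuated line) is opt-in.  Stripes wider than the filter
  half-width are only partially removed.
* `ztp_rvs` samples by inverting the conditional CDF (exact, no rejection).
* The packing samplers abort with a clear error after a bounded number of
  rejection trials when the domain is too small.

## Limitations

* No watershed/learned instance segmentation: overlapping cells at high
  confluency are quantified only via the volume-per-nucleus fallback.
* Microcarriers touching the volume border are not handled specially; the
  generator keeps a margin, and real acquisitions should crop accordingly.
* The carrier radius estimate assumes most of the sphere surface is bare or
  thinly covered; a carrier fully wrapped in cells would read ~a cell-height
  large.
* Multi-view fusion, stitching, CZI/LIF readers and on-line hardware
  integration are out of scope; input is TIFF/OME-TIFF.
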