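# Methods

## Coordinate conventions

All arrays are ordered `(z, y, x)`. Voxel indices are 0-based and a
voxel's physical position is its center, at `index × spacing` µm, so
µm↔voxel conversion is a pure scaling even for anisotropic stacks.
Every quantity downstream of I/O is in µm; converting an image to a
different but consistent spacing (with correspondingly rescaled
annotations) leaves all physical-unit results unchanged to
discretization tolerance. The in-plane pixel size is never inferred
from file metadata — it depends on camera and objective and must be
supplied by the user; only the z-step (0.2 µm in the default geometry)
has a conventional value.

Annotations travel in a JSON sidecar per embryo (outline and membrane
polylines in pixel units, converted on read; nuclear mask as an 8-bit
TIFF; stage = nuclei count and condition as operator-supplied
metadata). The uppermost and lowermost annotated slices are excluded
from quantification by default, because cells there are flattened
against the slide or coverslip; molecules in excluded slices are
dropped from counts *and* the corresponding voxels from shell volumes,
keeping the normalization consistent.

## Spot detection

The LoG kernel samples −∇²G analytically on a `size³` voxel grid
(default size 5, σ 1 voxel), sign-flipped so blobs respond positive and
shifted to zero sum so constant images give zero response. Anisotropy
is deliberately not compensated in filtering — the detection parameters
are conventional pixel-unit settings — while the subsequent Gaussian
fit estimates σ_z and σ_xy separately in µm.

Pre-detection returns strict 26-neighborhood local maxima with positive
response, ranked by response; plateaus of equal-valued adjacent maxima
keep the lexicographically smallest voxel. An optional response floor
and candidate cap exist purely for throughput: weak noise maxima are
fitted and rejected anyway, at real cost on large stacks.

Each candidate is fitted with a 7-parameter anisotropic 3D Gaussian
(amplitude, center, σ_z, σ_xy, constant offset) over the ±2 px (x, y) /
±3 px (z) sub-region window by bounded least squares. Fits that fail,
produce non-positive amplitude or σ, or drift out of the window are
dropped; windows clipped by the image border are fitted on the clipped
window and flagged. Two candidates converging onto the same voxel keep
only the stronger. **Quality** is defined as 1 − RSS/TSS of the fit,
clipped to [0, 1] — the underlying notion of a quality score is left
open in the conventional tooling, so a reproducible goodness-of-fit
surrogate is used. Intensity and quality thresholds are image-set-level
configuration, set manually per probe set as is standard; the CLI
offers an elbow-point suggestion that is logged but never applied
silently.

## Reference molecule and dense-region decomposition

Isolated spots (nearest neighbor > 1.5 µm, at least 20 by default)
define the reference single-molecule signature as the *median*
amplitude, σ_z, σ_xy and integrated intensity — robust to unrecognized
doublets in the bright tail. Integrated intensity uses the closed-form
Gaussian integral `A·(2π)^{3/2}·σ_xy²·σ_z / voxel volume`.

A spot is flagged dense when its integrated intensity exceeds 1.5× the
reference or either fitted σ exceeds 1.3× the reference. Each dense
spot defines a window of ~3 fitted σ plus reference tails; overlapping
windows merge, and any *non-dense* spot whose center falls inside a
dense window is absorbed into that region — its signal is part of the
merged blob, and leaving it "isolated" would count its molecules twice
(absorption grows the window and iterates to a fixpoint).

Within a region, the model is a k-component mixture of identical
reference Gaussians: only the k centers and a shared constant
background are free, directly encoding "a predicted RNA of average
intensity and size". The candidate range for k is the intensity
estimate `round(I_total / I_ref)` ± 3 (clipped to [1, K_max = 50]);
scanning every k from 1 to 50 with a full joint fit would be
intractable at realistic region sizes while adding nothing: counts
outside the intensity-compatible range are excluded by conservation of
flux. The background-subtracted region total uses a *plain* sum
(clipping negatives would rectify the noise and inflate the total on
large windows); the background is the median of the window's border
voxels.

Initialization is matching pursuit — repeatedly subtract the reference
Gaussian at the residual maximum, with sub-voxel centroid refinement —
whose RSS trajectory also supplies the model-selection curve. k is
chosen by a BIC-style criterion, `n·ln(RSS/n) + (3k+1)·ln n`, and the
selected mixture is refined by bounded least squares with an analytic
Jacobian; up to 3 seeded jittered restarts run, stopping early once the
joint fit beats its initialization. If refinement fails at every k the
intensity-ratio count is used with the matching-pursuit centers and the
molecules are flagged `fallback` in provenance. Everything is
deterministic for a fixed configuration seed.

Measured behavior (see the acceptance suite): on rendered clusters of
2–20 molecules at peak SNR 8 the mean absolute count error stays below
5%, comfortably within the 15% target; for noiseless reference-shaped
regions the count matches the intensity ratio within 1.

## DBSCAN clustering and per-embryo metrics

Decomposed coordinates are clustered with DBSCAN in Euclidean µm space.
No principled values for ε/minPts exist a priori; the defaults
ε = 0.75 µm and minPts = 2 declare a "cluster" to be any ≥ 2 resolvable
molecules within a granule-scale radius (granule diameters are of order
1 µm), and both parameters are echoed into every output file. The four
per-embryo metrics are: total RNAs; number of clusters; fraction of
RNAs inside clusters (Σ cluster sizes / total, using *decomposed*
molecule counts); and mean molecules per cluster, reported as missing —
never 0 — when no cluster exists. Stage aggregation uses the
conventional six groupings (1–2, 4, 8, 16–24, 26–48, > 48 nuclei;
configurable) and reports mean ± population s.d. per transcript × stage.

## Radial enrichment

Membrane distance is the 3D Euclidean distance to the nearest point on
any annotated membrane polyline across slices, with polylines densified
to ≤ 0.1 µm segments (bounded discretization error; an embryo without
internal membrane annotation uses its cortex, i.e. the outline).
Nuclear distance is measured to the nuclear *surface* (mask voxels with
a non-mask 6-neighbor), negated inside the mask; molecules outside the
embryo outline are excluded, the outline acting as the upper bound on
distance-to-nucleus.

Shell volumes implement the "concentric spheres" normalization as
distance-transform iso-shells of the actual annotated geometry rather
than literal spheres: only the iso-shell reading preserves the defining
property that uniform placement normalizes to 1 for non-spherical
embryos. The embryo domain is voxelized and each voxel's distance to
the reference geometry histogrammed. For the membrane reference the
distances come from a Euclidean distance transform of the rasterized
polyline cloud; because rounding cloud points to voxel centers biases
the minimum distance low by up to half a voxel diagonal, voxels whose
coarse distance lies within 0.55 diagonals of a bin edge are refined
with an exact nearest-point query (sklearn's KD-tree, which handles
far-from-surface queries much faster than scipy's). This keeps the
spherical-embryo shell volumes within 2% of the closed form while the
full-scale computation stays under half a minute on one CPU.

Default bin width is 10 µm; finer readouts (e.g. 5 µm shells) are a
configurable sub-bin split, with bin edges fully user-controllable.
At the calibration conditions (20,000 molecules, full-scale embryo,
10 µm bins) the innermost distance bin holds only ~6% of the embryo
volume, so its binomial s.e. is ~3% — the ±0.05 uniform-null band is
therefore a ~1.7 s.d. check, and the bin farthest from 1 is the honest
summary statistic.

## Granule co-localization

Granules are detected by multi-scale LoG blob detection (default σ
range 0.25–2.5 µm, anisotropy-aware via per-axis voxel sigmas; the
response threshold is mandatory configuration echoed to outputs) and
modeled as spheres of radius √3·σ — the scale at which a solid sphere
maximizes the LoG response; the radius convention is configurable. An
RNA cluster occupies the convex hull of its member positions; sets that
cannot span a 3D hull (< 4 points, collinear or coplanar) fall back to
a union of balls of radius ε/2 and are flagged. Overlap is exact
any-contact: nearest-point-on-hull distance to the granule center
≤ radius, with the convex projection solved by a penalized NNLS
formulation of the simplex-constrained least-squares problem.
Per-embryo statistics count overlapping clusters and occupied granules
(each granule once, however many clusters touch it); condition
contrasts use Welch's t-test on per-embryo percentages.

## Statistics

Welch's two-sample t statistic with Satterthwaite degrees of freedom;
two identical zero-variance samples get p = 1 with a degeneracy flag
(no evidence either way rather than a spurious rejection). Comparisons
against the control transcript are adjusted across the whole
figure-equivalent family; the method (Benjamini–Hochberg default, Holm
and Bonferroni selectable) is stamped into every output, the adjustment
is order-invariant and adjusted p never falls below raw p. Stars follow
NS > 0.05 > * > 0.005 > ** > 0.0005 > *** > 0.00005 > ****, with
boundary values taking the stronger label.

## Synthetic embryos

The generator emulates the statistical regimes the analysis measures,
not the appearance of any particular micrograph. Geometry: an
axis-aligned ellipsoidal embryo (default half-axes 15 × 15 × 25 µm,
i.e. ~50 µm long axis; the `desk` preset at 6 × 7.5 × 12.5 µm keeps
suite runtimes in minutes), cells laid out along the long axis with
planar membranes, spherical nuclei at cell centers, voxel spacing
(0.2, 0.1, 0.1) µm. Molecule models: `uniform`; `membrane_enriched`
and `nuclear_peripheral` (density ratio ρ inside a shell of stated
width, realized by weighted rejection against the *same* annotated
geometry the pipeline measures, so ρ is exactly the quantity the radial
profile estimates); `clustered` (uniform centers, isotropic Gaussian
members, σ 0.3 µm default); `granule_associated` (a fraction f of
cluster centers placed at granule centers — distinct granules when
enough exist, since co-located clusters merge under DBSCAN and are no
longer countable separately).

Rendering: each molecule is an anisotropic Gaussian at its sub-voxel
position with σ_xy = 0.13 µm and σ_z = 0.35 µm (typical 60×/high-NA
widefield scale), amplitude ~ Normal(100, 10) truncated positive over a
constant background; granules are solid spheres softened by a 1-voxel
Gaussian in the marker channel. Noise is Poisson shot noise followed by
additive Gaussian read noise (σ 2), the standard fluorescence model.
Peak SNR is defined as amplitude / √(background + σ_read²);
`background_for_snr` inverts this (SNR 8 with amplitude 100 gives
background ≈ 152). Outline polygons carry ~1 µm vertex spacing — chord
error a few nm at embryo curvature — because rasterization cost scales
with vertex count; distance computations re-densify to 0.1 µm.

What the generator does *not* emulate: optical aberrations and
depth-dependent PSF variation, autofluorescence structure, probe
labeling stochasticity, chromatic misregistration between channels, and
irregular (non-ellipsoidal) cell shapes. Passing tests therefore
demonstrate the correctness and calibration of the *quantification*
given spots that match the assumed PSF model — not robustness to every
real-microscope artifact; on real data the manual intensity/quality
thresholds absorb much of that gap, which is exactly why they are
per-image-set configuration.

## Problem sizes in the test suite

The suite runs the full-scale embryo only where the check demands it
(uniform-null calibration, 5 µm enrichment shell); detection accuracy
uses an intermediate embryo sized so that 210 spots at 2 µm exclusion
sit below the random-packing limit; decomposition recovery uses 50
rendered clusters per size in individual small windows; everything else
runs on the quarter-volume desk preset. Fixtures are generated at test
time; nothing binary ships with the package.
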