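# Methods

This note documents the models, parameter choices and numerical decisions
behind `rollfish`, in the spirit of a methods appendix: what each stage
assumes, what the simulators do and do not emulate, and where design
freedom existed.

## Synthetic data model (`simgen`)

**Tissue images.** A field (default 150 µm at 0.325 µm/px, the scale of a
20× widefield scan) carries three channels. Nuclei are filled ellipses of
two classes — tumor: equivalent diameter ~N(18, 2) µm, axis ratio
~U(0.7, 1.0); stromal: ~N(7, 1.5) µm, axis ratio ~U(0.2, 0.5) — placed by
rejection sampling with per-cell collision radii so nuclei do not
overlap. The tumor diameter default was chosen so that the default shape
cutoffs (ratio 4.08 µm, roundness 0.46) actually separate the classes: a
disk's area/perimeter ratio is r/2, so nuclei must exceed ~16.3 µm
diameter to clear the 4.08 µm cutoff. Cytoplasmic autofluorescence is a
uniform disk (nucleus radius + 4 µm) around each nucleus. Each
rolling-circle product is an isotropic 2-D Gaussian (σ = 1.3 px ≈ 0.42
µm, a realistic diffraction-limited PSF at 20×/NA ≈ 0.8) of peak
amplitude 500 over constant background 100 with additive Gaussian read
noise (sd 10); per-cell spot counts are Poisson with the class mean,
positions uniform in the cytoplasmic disk. There is no photon-physics
(shot noise), no z-dependent PSF, no illumination gradient, and no
nucleus texture — so passing tests demonstrate correctness of the
algorithms under the stated model, not robustness to every real-world
artifact.

**Two-color assay.** Each of n molecules (uniform in a 1000 µm field,
i.e. low enough density that chance matches within the 1 µm matching
radius are rare) is detected in each channel independently with
probability q; observed positions get isotropic Gaussian jitter (default
sd 0.2 µm, sub-pixel localization error). Real assays add spectral
crosstalk and chromatic offset, which are not modelled.

**TMA counts.** Per-cell counts are negative-binomial — FFPE tissue
counts are overdispersed and no distributional family is established for
them, so NB with dispersion (shape) 2 is a standard conservative choice;
dispersion → ∞ recovers Poisson. Group means default to
norm/0: 0.1, 1+: 0.3, 2+: 1.5, 3+: 4.0 spots/cell, reflecting high
transcript abundance only in the IHC 2+/3+ groups. Sample-level
biological variability is a lognormal multiplier (sd 0.4 on the log
scale) on the group mean, shared between replicate sections of the same
sample so replicates correlate as real consecutive sections do.

**Shape measurements.** Ratio and roundness are drawn from normals
(tumor: 5.0 ± 0.3 µm and 0.70 ± 0.08; stromal: 2.0 ± 0.5 and
0.55 ± 0.12), roundness clipped to [0, 1]. These emulate manual
measurement of putative tumor nuclei used to calibrate cutoffs.

## Spot calling (`imageproc`)

Projection is a plain per-pixel maximum over z. Stitching assumes the
acquisition grid is known (position + overlap fraction, default 10%);
overlapping pixels keep the maximum. No registration search is performed
— tile placement from stage coordinates is deterministic.

The caller runs: white top-hat with a disk (default radius 5 px — small
enough to pass ~3 px-σ spots, large enough to flatten cell-scale
background), threshold, seeds, watershed. The default threshold is
relative: median + 5·1.4826·MAD of the top-hat image. The MAD rule makes
the caller invariant to multiplicative intensity rescaling (camera gain,
exposure); an absolute threshold is available. Seeds are local maxima at
least `min_separation_px` (default 3) apart; seed labels are assigned in
row-major order of the peak coordinates, which fixes plateau ties
deterministically. The watershed floods the inverted top-hat image
restricted to the thresholded foreground, so each foreground pixel
belongs to at most one spot. Centroids are intensity-weighted (on the
top-hat image) and reported in µm with the pixel-center convention
`x_um = col · pixel_size`. Peak and integrated intensities are measured
on the background-suppressed image.

Per-spot SNR is (peak − median of an annulus) / (1.4826·MAD of the
annulus), annulus radii 5–10 px by default. A constant annulus yields an
infinite SNR (flagged, not an error); an annulus fully outside the image
yields NaN.

## Cell segmentation and classification (`cellseg`)

Segmentation is deliberately classical and deterministic: Gaussian
smoothing (σ = 2 px) → Otsu threshold (override available) → hole filling
→ removal of objects under 10 µm² → watershed on the Euclidean distance
transform. Seeds are the connected plateaus of the local-maximum mask of
a smoothed distance transform: elongated nuclei have an exactly flat
distance ridge (the nearest boundary is purely lateral), and treating the
connected plateau as one seed prevents spurious splitting while still
separating genuinely touching nuclei.

Perimeter uses the Crofton estimator. Naive pixel-edge counting
overestimates perimeter by up to ~27% on smooth shapes, which would bias
circularity of a perfect disk to ~0.6; the Crofton estimate keeps a
rasterized disk's circularity ≥ 0.95. Roundness is circularity 4πA/P²
clipped to [0, 1] (an alternative axis-ratio definition of "roundness"
exists in some tools; circularity was chosen because it is
estimator-defined and dimensionless). Note the geometric fact that
circularity of a b/a = 1/4 ellipse is ≈ 0.54: only quite elongated nuclei
(beyond ~5.5:1) fall under the 0.46 default cutoff, so in practice the
ratio cutoff does most of the discrimination and roundness removes
extreme fragments.

Calibration is median − 3·sample sd (ddof = 1) per descriptor over a
reference set of ≥ 2 putative tumor nuclei; it is scale-equivariant. The
defaults (4.08 µm, 0.46) are the shipped calibration. The tumor rule is
the conjunction (both cutoffs must pass): the calibration logic — set a
floor under tumor-typical values of each descriptor — implies both
conditions characterize tumors, and the conjunction is the conservative
combination. The ratio cutoff is interpreted in µm (area µm² / perimeter
µm).

Territories: when an autofluorescence channel is given and its Otsu
foreground touches a nucleus, territories are watershed basins of the
inverted autofluorescence restricted to foreground ∪ nuclei, seeded by
the nucleus labels. Otherwise (or when the stain is unusable) each
nucleus claims all pixels within a fixed distance (default 10 µm — the
fallback radius is a free parameter; 10 µm is a typical epithelial
cytoplasm width), contested pixels going to the nearest nucleus, which
partitions space along Voronoi midlines. Territories are disjoint by
construction and contain their seed.

## Quantification (`quantify`)

Territory expansion for spot assignment uses the same nearest-label
Euclidean expansion (margin default 9.75 µm). Expansion and conflict
resolution are a single operation — a pixel within the margin of several
territories belongs to the nearest one — so counts are conserved exactly:
assigned + outside = total, asserted in tests on every fixture.

Colocalization matching is greedy by ascending pair distance with each
spot used at most once, restricted to pairs within 1 µm (default; the
criterion is centroid distance — real pipelines sometimes use pixel
overlap, but centroid distance is well-defined across magnifications).
Greedy-by-distance is exactly iterated mutual-nearest-neighbor matching
and is deterministic; tests verify it agrees with brute-force optimal
matching on small instances at assay-realistic densities. The
colocalization fraction uses the union denominator (Jaccard form):
c = matched/(n_A + n_B − matched). Under this convention the independent
equal-efficiency model gives E[c] ≈ q²/(2q − q²) = q/(2 − q), whose
inverse q = 2c/(1+c) is the efficiency estimator; c and q are mutual
inverses on [0, 1] to machine precision. The union convention is the one
under which a measured c ≈ 0.5 corresponds to q ≈ 2/3 (~70%), consistent
with published smFISH colocalization benchmarks (~67.5%).

Zero-signal cells are flagged (`included = False`) rather than dropped;
the exclusion applies to per-cell distribution displays only. Sample
means fed to the ROC screen include zero-count cells.

## Statistics (`stats`)

Percentiles use linear interpolation between closest order statistics
(NumPy's default), documented because percentile conventions differ
across tools; box-plot summaries report the 2.5/25/50/75/97.5 points.
Replicate correlation is the Pearson product-moment r with R² = r² (the
squared correlation, not a regression R² — the two coincide for simple
linear regression) and a t-based two-sided p-value with n − 2 df.

The ROC screen evaluates cutoffs start + k·step for k = 0..n−1 (default
0.05 to 5.00, 100 cutoffs); prediction is positive at mean ≥ cutoff
(inclusive — the strictness is not standardized, and the inclusive rule
means the grid's first cutoff can still call a sample at exactly 0.05).
AUC is the trapezoid rule over (1 − specificity, sensitivity) with the
(0,0) and (1,1) corners appended. The operating point maximizes Youden's
J = sens + spec − 1, ties going to the smaller cutoff (higher
sensitivity at equal J). Monotonicity of sensitivity/specificity along
the cutoff grid and AUC ∈ [0, 1] are enforced invariants of the result
object.

## Probe design (`probedesign`)

Tiling scans the transcript 5′→3′ and greedily accepts 30 nt windows
passing GC (default 0.3–0.7 for tiles) and optional nearest-neighbor Tm
filters, with ≥ 2 nt gaps; this is deterministic and reports the
achievable count when the request cannot be met. Docking sequences are
random 46-mers screened for: no shared k-mer (default k = 15 — short
enough that a hit plausibly seeds hybridization, long enough that a
random 46-mer passes against a transcriptome-scale index) with either
strand of the screening sequence set, GC 0.4–0.6, homopolymers ≤ 4.
The Tm filter uses Biopython's nearest-neighbor model with its default
parameter table and is only a filter, not a thermodynamic prediction.

The padlock's two terminal arms are the reverse complement of the
docking sequence split 23/23 (arm lengths are a free choice; an even
split balances the two hybridization arms), arranged so the 3′ arm binds
the 5′ half of the docking sequence and the two probe ends abut —
ligatable. The barcode (default 20 nt) sits between fixed backbone
linkers; the detection oligo equals the barcode, because the
rolling-circle product contains the barcode's reverse complement in
hundreds of tandem copies. All ODNs of a set share one docking sequence,
so one padlock species serves the whole set. RNA is handled as DNA
(U→T).

The validator re-derives every invariant from scratch: segment lengths
and alphabet, shared docking, exact reverse-complement mapping of each
arm onto its stated transcript coordinates, global uniqueness of each
30-mer target window across the supplied transcriptome (substring scan),
brute-force k-mer-set orthogonality of the docking sequence, the padlock
junction identity, and barcode/detection equality.

## Problem sizes and determinism

Test and acceptance runs use scaled study conditions chosen to keep the
whole suite fast while leaving the estimators in their asymptotic regime:
two-color assays at n = 10,000 molecules; spot-calling benchmarks at 200
spots per 512² px field (SNR 50, separation ≥ 6σ); TMAs with 68 samples
(36 positive / 32 negative, emulating the class ratio of a 75-case array)
× 200 cells; docking screens against 10 kb random transcriptomes; probe
sets of 12–48 ODNs on 1–2 kb random transcripts. Every stochastic
component takes an explicit integer seed and is bit-reproducible given
(parameters, seed).

## Known limitations

* The simulators are models of convenience: constant background, ellipse
  nuclei, uniform spot placement. They validate algorithm correctness,
  not performance on real FFPE autofluorescence or RNA degradation.
* Spot assignment is 2-D; overlapping cells in z are not represented.
* The greedy matcher can in principle differ from optimal bipartite
  matching in pathological geometries (chains of near-equidistant spots);
  at assay densities this does not occur in practice.
* `segment_nuclei` assumes nuclei are brighter than background with a
  roughly bimodal histogram (Otsu); dim or textured nuclei need an
  explicit threshold.
* No off-target alignment search beyond exact k-mer/substring screening;
  no secondary-structure prediction for oligos.
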