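# Methods

## Scope and model

`tjquant` measures the fragmentation of a junction-marker network (ZO-1
immunofluorescence of an epithelial monolayer) as the distribution of
continuous membrane segment lengths, and provides the synthetic data needed
to validate every stage. The pipeline is a faithful re-implementation of a
classical ImageJ-style macro chain — maximum projection, Hessian ridge
filtering, thresholding, thinning, branch-point subtraction, particle
measurement — as a tested, scriptable library.

## Ridge enhancement

The response at scale σ is `max(0, −λ_min)` where λ_min is the smaller
eigenvalue of the 2×2 Hessian of the Gaussian-smoothed image. Bright thin
lines give λ_min strongly negative across the line, so the clipped negative
eigenvalue is a signed-correct line detector; the raw smallest-eigenvalue
map produced by common plugins is signed, and the clip at zero is our
explicit convention for bright-on-dark staining.

**Numerical choice.** Derivatives use separable sampled Gaussian-derivative
kernels (truncated at 4σ) rather than smoothing followed by finite central
differences: the central-difference route biases the peak response on a
Gaussian line of width w down by a factor `1/(4(w²+σ²))` — about 5% at
w = 2, σ = 1 — while the sampled-kernel route reproduces the closed form
`A·w/(w²+σ²)^{3/2}` to better than 0.1%. Two kernel corrections make the
filter exact on the relevant polynomial space: the second-derivative
kernel is shifted to zero DC gain (zero response to constants, hence exact
invariance to intensity offsets) and rescaled to unit response on x²/2;
responses below 10⁻¹⁰ of the image scale are flushed to zero. The default
σ = 1.5 px matches junction lines 2–4 px wide; it is a CLI flag (`--scale`)
because acquisition pixel sizes vary.

## Binarization

Otsu's method over a 256-bin histogram of the response range, foreground
strictly above the threshold. Candidate splits are canonicalized to bins
with at least one observation — splits inside a run of empty bins induce
the identical partition of the data, so each distinct partition is
evaluated once and arg-max ties are broken deterministically toward the
lowest threshold. A constant response map has no separating threshold and
raises a degenerate-input error. A fixed threshold (`--threshold-method
fixed`) is available for reproducibility studies.

## Skeleton analysis

Thinning uses the standard connectivity-preserving morphological
skeletonization (scikit-image). A skeleton pixel is a **branch point** when
its 8-neighbourhood contains ≥3 skeleton pixels. This is the ImageJ
skeleton-analysis convention, and it is deliberate: at a crossing, the
pixels orthogonally adjacent to the centre touch the other arms diagonally,
so they must be subtracted together with the centre or the branches remain
8-connected and the network under-segments (on simulated monolayers a
centre-only rule merges ~4× too few segments). Consequence worth knowing: a
4-armed cross loses a 5-pixel junction cluster and each arm is shortened by
one pixel.

Detection is implemented as a binary hit-or-miss union over the catalogue
of all 3×3 templates with ≥3 foreground neighbours (219 of 256 neighbour
configurations), compiled to a 512-entry lookup table applied in a single
bit-encoding convolution. A literal per-template `binary_hit_or_miss` union
and a direct neighbour count are kept as alternative implementations; the
three are exhaustively identical over all 512 neighbourhoods and on random
skeletons (part of the acceptance suite).

Segments are the 8-connected components after subtraction, labelled in
raster order of each component's first pixel (byte-identical outputs across
runs). Two lengths are reported per segment:

* `length_um = pixel_count × pixel_size` — the primary metric, mirroring
  particle-size measurement on a 1-px skeleton. It carries a known ~−10%
  orientation bias on Euclidean length (a digital line of length L contains
  `L·max(|cosθ|,|sinθ|)` pixels; the orientation average is 0.90).
* `geodesic_length_um` — orthogonal steps count 1, diagonal steps √2. This
  is the unbiased estimator of physical length and the one used when
  recovered length is compared with generator ground truth.

Branches shorter than `min_branch_px` (default 3) are discarded:
skeletonization of a noisy band produces 1–2 px spurs that are artefacts,
not membrane. The discarded pixel total is retained, so the conservation
law `|skeleton| = |junctions| + Σ pixel_count + discarded` holds exactly on
every input (tested).

## Group comparison

The per-image count of large segments — strictly inside the window
(x, y) µm, defaults x = 5, y = 100 — is the sampling unit, because the
biological claim is about culture conditions, not about individual
segments (a pooled per-segment mode exists behind `pooled=True` but is
pseudo-replication and is documented as such). Two-sided Mann-Whitney U:
exact null distribution whenever n_a + n_b ≤ 20 and the pooled values are
tie-free, otherwise the normal approximation with tie and continuity
correction; the choice is recorded in the output. The full length histogram
is always emitted so any other window can be checked after the fact.

## Synthetic monolayers

Geometry: cell centres drawn uniformly with a hard-core minimum spacing
(8 px) on a periodic domain, Voronoi-tessellated by 3×3 tiling; each ridge
is kept iff its midpoint falls in the central copy, so the boundary is
partitioned exactly once. On the torus, generic tessellations satisfy
E = 3N (six edges per cell on average) — used as a structural test.

Fragmentation: `floor(f·L/gap)` non-overlapping gaps of fixed length
(default 20 px) are placed uniformly at random along the concatenated
boundary arclength, so retained length equals (1−f)·L to within one gap.
The gap length is a detector-physics compromise: gaps much shorter than
~3–4 blur-plus-scale widths are partially bridged by the ridge filter
(the above-threshold band protrudes 2–3 px into each gap end), which at
10 px gaps inflates recovered length by tens of percent at f = 0.5. At the
default pixel size a 20 px gap is 8 µm — comparable to the dark runs seen
in heavily stressed monolayers.

Rendering: intensity `background + A·exp(−d²/2w²)` with d the distance to
the nearest retained arc (arcs sampled at 0.3 px, distances by Euclidean
distance transform, so d is quantized to pixel centres — sub-pixel error
that the PSF blur dominates), then Gaussian PSF blur and per-frame Gaussian
or Poisson noise. One experiment seed derives geometry, fragmentation and
noise seeds by fixed offsets, so each stage is independently reproducible.

Default study conditions (chosen once, as a realistic mid-magnification
RPE acquisition): 384×384 px at 0.4 µm/px (154 µm field), 80 cells
(≈ 17 µm across, mean cell-edge ≈ 11 µm), line width w = 1.5 px (≈ 0.9 µm
FWHM), amplitude 100 over background 10, PSF σ = 0.8 px, noise sd 10
(SNR 10), 3 frames per stack. Cell size matters qualitatively: if mean
edge length falls below the 5 µm large-segment cutoff, moderate
fragmentation *increases* the large count (removing a branch of a
three-way junction merges the two remaining edges), inverting the
phenotype; at the defaults the intact condition robustly has more large
segments, as in real monolayers.

**What the simulator does not model:** photobleaching, uneven
illumination, 3-D sectioning, cell-size heterogeneity beyond hard-core
Voronoi, curved membranes (edges are straight), and biologically clustered
(non-uniform) fragmentation. Passing recovery tests therefore demonstrates
correctness of the measurement chain under the stated optics, not
robustness to every real-world artefact; at SNR ≤ 2 recovery degrades and
no claim is made.

## Validation summary (computed by the test suite / acceptance script)

* Ridge peak on the analytic Gaussian line within 2% of the closed form.
* Otsu equals an exhaustive 256-candidate search exactly.
* Branch-point implementations exhaustively equivalent (512 patterns).
* Pixel conservation exact on every input.
* Geodesic recovered length within 15% of (1−f)·L for f ∈ {0, 0.25, 0.5}
  at the study conditions (6 seeds per level); median segment length
  strictly decreasing in f.
* Intact vs 40%-fragmented (6 images per group) separated at p ≤ 0.01 in
  ≥95 of 100 seed replicates.
* Exact rank-sum p equals full permutation enumeration (n ≤ 7 per group);
  empirical type-I error at α = 0.05 within [0.03, 0.07] under the null.
* Reference-gene fold change identically 1; ΔΔCt = −1 → 2.0, +3 → 0.125;
  per-sample Ct shifts cancel.

## qPCR quantification

Comparative method only: ΔCt = mean Ct(target) − mean Ct(reference) over
replicate wells (arithmetic mean, no outlier rejection, SD reported for
QC); fold change = 2^−(ΔCt_sample − ΔCt_control) with the control ΔCt taken
as the mean over control-condition samples, because results are reported
per treatment group. No amplification-efficiency (standard-curve or Pfaffl)
correction is applied — the printed comparative equation is the contract.
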