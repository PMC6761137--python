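# tjquant

Quantification of tight-junction fragmentation in fluorescence microscopy.

Epithelial barriers — the retinal pigment epithelium (RPE) in particular —
depend on continuous tight junctions. Immunostaining of the scaffold protein
ZO-1 outlines each cell as a thin bright polygonal network; under oxidative
stress (e.g. the lipid-peroxidation product 4-HNE) that network breaks into
short fragments. `tjquant` turns images of such networks into a quantitative
readout: the lengths of the continuous membrane segments, the abundance of
*large* segments, and a non-parametric comparison between culture
conditions. It also ships a synthetic-monolayer simulator with full ground
truth, and a comparative (2^−ΔΔCt) qPCR calculator for the accompanying
expression measurements.

## Method

For each image stack the pipeline runs:

1. **Maximum-intensity projection** of the z-stack.
2. **Ridge enhancement** — at each pixel the 2×2 Hessian of the
   Gaussian-smoothed image (scale σ, default 1.5 px) is evaluated and the
   response is `max(0, −λ_min)`, the clipped smallest eigenvalue: bright
   lines have strongly negative curvature across the line. For a line of
   Gaussian cross-section `A·exp(−x²/2w²)` the peak response is
   `A·w/(w²+σ²)^{3/2}`, which the test-suite verifies to 2%.
3. **Binarization** — Otsu's threshold (256 bins, between-class variance)
   by default, or a fixed threshold.
4. **Skeletonization** to 1-px-wide medial curves.
5. **Branch-point subtraction** — skeleton pixels with ≥3 skeleton
   neighbours (detected by a binary hit-or-miss template catalogue) are
   removed, disconnecting the network at cell-boundary junctions.
6. **Branch measurement** — remaining 8-connected components become
   segments with `length_um = pixel_count × pixel_size` (plus a geodesic
   length weighting diagonal steps by √2); branches under `--min-branch-px`
   (default 3) are discarded as skeletonization artefacts.
7. **Comparison** — per-image counts of large segments
   (`x µm < length < y µm`, default 5–100 µm) from two conditions are
   compared with a two-sided Mann-Whitney U test (exact null distribution
   for ≤20 tie-free observations).

## Worked example

Simulate two conditions — an intact monolayer and one with 40% of the
junction network erased — then quantify and compare them:

```sh
tjquant simulate -f 0.0 --n-images 3 --seed 1 --out-dir sim_intact
tjquant simulate -f 0.4 --n-images 3 --seed 100 --out-dir sim_stressed
tjquant quantify sim_intact/*.tif \
    --group-b sim_stressed/sim_f0.4_000.tif \
    --group-b sim_stressed/sim_f0.4_001.tif \
    --group-b sim_stressed/sim_f0.4_002.tif \
    --out-dir quantified
```

`quantified/summary.json` then contains (numbers from this exact run):

```json
"comparison": {
  "metric": "large_segment_count",
  "group_a": [168.0, 167.0, 167.0],
  "group_b": [125.0, 127.0, 124.0],
  "u_statistic": 9.0,
  "p_value": 0.0765,
  "method": "normal-approx",
  "large_window_um": [5.0, 100.0]
}
```

Every intact image has more large (>5 µm) segments than every fragmented
image (U = 9 = n_a·n_b, complete separation). Two intact images tie at 167
counts, so the test falls back to the tie-corrected normal approximation;
and with only 3 images per group even complete separation cannot reach
p < 0.05 — the simulator's acceptance checks use 6 images per group, where
complete separation gives exact p ≈ 0.002. Per-image segment tables and
length histograms are written alongside.

The same from Python:

```python
from tjquant import simulate_experiment, quantify_stack

stack, fragmented, network = simulate_experiment(f=0.25, seed=7)
segments = quantify_stack(stack).segments
print(len(segments))                                  # 206 segments
print(round(segments.geodesic_lengths_um.sum(), 1))   # 2035.4 µm recovered
print(round(fragmented.true_segment_lengths_um.sum(), 1))  # truth: 2093.4 µm
```

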