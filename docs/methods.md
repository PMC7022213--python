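# Methods

## Detection model

A pixel at (r, c) is signal when I(r, c) > μ_w(r, c) + k·σ_w(r, c), where
μ_w and σ_w are the mean and *population* standard deviation of the
intensities in the local window w containing the pixel. The inequality is
strict, so a constant image yields an empty mask for every k ≥ 0 and the
mask is invariant under multiplicative rescaling of the image. Two window
schemes are provided:

* **block** (default): the image is partitioned into non-overlapping
  w×w tiles; edge tiles are truncated and use only in-image pixels. Every
  pixel inherits its tile's statistics.
* **sliding**: per-pixel statistics over a centered w×w window with
  replicate (edge-clamped) padding, computed with a uniform filter.

Supra-threshold pixels are grouped into connected components
(8-connectivity by default; 4 available) and filtered:

| regime | window | k | area | eccentricity |
|---|---|---|---|---|
| cell bodies (DAPI) | 200 px | 0.75, valid range [0.5, 1] | > 500 px (strict) | ≤ 0.9 |
| RNA clusters | 15 px | 2.5 | 7–200 px (inclusive) | configurable, see below |

Eccentricity is that of the ellipse sharing the region's second central
moments: √(1 − λ_min/λ_max) for the eigenvalues of the pixel-coordinate
covariance; single-pixel and collinear regions score 0. Intensities are
measured on the raw image — no background subtraction is applied anywhere.

**Cluster eccentricity direction.** The protocol this reimplements prints
"eccentricity higher than 0.97 were kept" for clusters, while cell bodies
use a *maximum* eccentricity — for compact punctate signal the printed
direction would discard every true spot, so it is almost certainly a
wording slip for "at most". Both directions are implemented;
`detect_spots` defaults to the printed `keep_greater` reading, and the
pipeline configuration (and all synthetic-scene evaluations) set
`keep_at_most` explicitly. Flip one flag to compare.

**Manual ROI mode.** Each user-supplied ellipse yields exactly one region:
the ellipse interior intersected with the supra-threshold mask, falling
back to the whole interior (flagged `below_threshold`) when the
intersection is empty. Out-of-image ROIs are clipped with a warning.

## Per-cell quantification

Clusters are attributed to DAPI-positive cells by **majority overlap**: a
cluster belongs to the cell owning the largest share of its pixels,
provided at least one pixel overlaps; ties break to the lower cell id;
clusters overlapping no nucleus stay *unassigned* and are reported, so
assigned + unassigned always equals detected (checked per run). A
`centroid_in_mask` rule is offered. Since the upstream segmentation has no
cytoplasm model, the nucleus mask is the cell territory; an expanded
territory would change absolute counts but not the group contrasts this
pipeline is designed to test.

A cell is **endothelial** when it carries at least `min_cd31` CD31
clusters (default 1 — "double labeled" sets no count). The **shell/core**
label is the region-mask value at the rounded nucleus centroid (nuclei are
small relative to the region geometry); value 0 or out-of-bounds is
`unassigned`. Group summaries bin endothelial cells by cluster count
(0 … max_bin−1, ≥max_bin; default max_bin 8), split by region, and report
the non-endothelial complement as the pie-chart denominator.

## Tabular stages

* **SI phenotype**: ratio = time with target present / time absent
  (zero denominator is a domain error). Stressed mice: < 1 → SS, > 1 →
  RES; exactly 1.0 is *unclassified* — neither printed rule covers the
  boundary, and faithfulness beats convenience. Unstressed mice are CTRL.
* **ΔΔCt**: per-sample ΔCt = Ct_gene − Ct_housekeeping; per gene,
  ΔΔCt = ΔCt − mean(control ΔCt) (arithmetic mean, so control fold changes
  have geometric mean 1); fold = 2^−ΔΔCt. Adding a constant to every Ct
  leaves fold changes unchanged.
* **Outlier screen**: single pass; x is removed when |x − mean| > 2·SD,
  both computed on the full input with population SD. Note a degeneracy:
  a single extreme among n−1 ties reaches z = √(n−1), so for n = 5 such a
  point sits *exactly* at 2 SD and is kept by the strict rule; the screen
  only removes points strictly beyond it. Fewer than 3 values: no-op with
  a warning.
* **DE filter**: signed linear fold changes (−2 means halved); up requires
  FC ≥ +2 and p < 0.05, down FC ≤ −2 and p < 0.05; FC exactly ±2 is kept,
  p exactly 0.05 dropped. Venn counts enumerate the disjoint regions of 2
  or 3 gene sets and sum to the union.
* **ChIP percent-input**: the input Ct is adjusted by the dilution factor
  (Ct_adj = Ct_input − log2(1/fraction)), then
  %input = 100·2^(Ct_adj − Ct_IP) — the standard convention; equal Cts at
  fraction 1 give 100%, one cycle of separation halves it.
* **Group tests**: one-way ANOVA (scipy) with pairwise two-sided t-tests
  adjusted by Bonferroni (p_adj = min(1, m·p)); two-way type-II ANOVA with
  interaction via statsmodels OLS; Pearson correlation with two-sided p.

## Synthetic scenes

The generator emulates a confocal field of the nucleus accumbens: default
512×512 px holding 30 non-overlapping elliptical nuclei (semi-axes
20–27 px, eccentricity ≤ 0.8, DAPI amplitude 500 above background), 30% of
them endothelial. Background = level 200 + a low-frequency sinusoidal
illumination gradient (amplitude 60) + i.i.d. Gaussian noise (SD 20),
clipped at zero; the gradient is what makes *local* thresholding
demonstrably necessary. Puncta are Poisson per cell — the standard sm-FISH
count model — with defaults CD31 5 (endothelial cells only, centers within
the nucleus dilated by 2 px) and TARGET1 4, rendered as Gaussian blobs
(σ = 1.6 px, peak 300 = background + 5·noise SD). Images are synthesized
in floating point and quantized to 16 bit on write; detection consumes the
quantized rasters. Identical config + seed is bit-identical.

**Resolvable clusters.** Puncta are placed with a minimum pairwise
separation (12 px per channel, best-effort: the Poisson count is always
honored and a crowded cell falls back to the best-separated candidate).
Rationale: two Gaussian puncta inside one 15×15 statistics tile inflate
that tile's SD enough that neither footprint can reach the 7-px area floor
— analytically, the supra-threshold area of m = 2 cofocal blobs is bounded
near 5 px for every blob width — so overlapping "clusters" are not
individually countable objects under this detector (or under the cluster
definition itself). The generator therefore plants clusters that are
resolvable by construction, which is what gives ground-truth counts a
meaning.

What the generator does **not** emulate: 3D optics and true PSFs, vessel
morphology (CD31 appears as perinuclear puncta, sufficient to exercise
double-labeling), touching or overlapping nuclei, autofluorescence
texture, and cytoplasmic transcript spread. Passing tests show the
algorithmic chain is correct and well-calibrated on images matching its
assumptions; they do not certify performance on real tissue, where
segmentation errors and background structure dominate.

## Evaluation design and problem sizes

* Detection scoring: 10 seeded default scenes; detections match truth by
  greedy 1-1 nearest-neighbour pairing (10 px for nuclei, 5 px for spots).
  Measured operating point: nucleus recall/precision ≈ 1.0, spot recall
  ≈ 0.97 (losses are blobs split by tile boundaries or sub-7-px
  footprints), spot precision ≈ 1.0, endothelial accuracy ≈ 1.0.
* Planted effect: 3 groups × 4 scenes, target means 4.0/4.0/2.4
  (a 40% RES reduction); 10 replicates; significance read from the
  CTRL–RES Bonferroni posttest at α = 0.05; the reduction estimate is the
  replicate mean ± SE of 100·(1 − mean_RES/mean_CTRL) over endothelial
  cells.
* Type-I calibration: 100 replicates of the group test on per-cell counts
  drawn from the generator's Poisson count model at the pipeline's group
  sizes (3 × 36 cells), with rendering bypassed so the calibration loop
  stays cheap; the rendered-scene path is exercised by the planted-effect
  experiment instead.

## Known limitations

* At k < 1 the cell-body threshold is deliberately permissive; on fields
  with a strong illumination gradient and *few or no* nuclei, the bright
  flank of the gradient itself can exceed mean + k·SD over a contiguous
  ≥ 500 px patch and be reported as a cell body. With realistic nucleus
  density the nuclei dominate each tile's SD and this does not occur.
* Block tiling introduces threshold discontinuities at tile boundaries; a
  punctum straddling a boundary can split into sub-minimum fragments
  (the main component survives in ~97% of cases at the default geometry).
* Touching nuclei are out of scope (the generator never produces them and
  the detector performs no watershed splitting).
* The two-sided t posttests assume approximate normality; Poisson counts
  with means ≥ 2.4 at n = 36 are comfortably within its robustness range,
  as the type-I calibration confirms.
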