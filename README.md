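# vascuscope

Cell-resolved quantification of multiplexed RNAscope fluorescence images,
with the downstream group statistics used in stress-phenotyping studies of
the brain vasculature.

RNAscope in-situ hybridization renders individual mRNA transcripts as
punctate fluorescent clusters. To ask cell-type-specific questions — for
example, how many *Foxo1* or *cldn5* transcripts sit in each endothelial
cell of the nucleus accumbens shell versus core — the raw images must be
turned into per-cell counts. `vascuscope` implements that quantification as
a tested, reusable pipeline:

* **Adaptive local thresholding.** A pixel is signal when its intensity
  exceeds the *local* mean plus k local standard deviations, computed over
  non-overlapping square tiles (or a sliding window). Cell bodies on the
  DAPI channel use 200×200 px statistics with k ∈ [0.5, 1]; RNA clusters
  use 15×15 px statistics with k = 2.5. Local statistics make detection
  robust to the uneven illumination typical of confocal mosaics.
* **Morphological gating.** Connected components are kept by area and
  eccentricity (the ellipse-of-equal-second-moments measure,
  e = √(1 − λ_min/λ_max)): cell bodies need area > 500 px and e ≤ 0.9;
  clusters need area in [7, 200] px, with a configurable eccentricity rule.
  A manual ellipse-ROI mode measures user-drawn regions instead.
* **Per-cell measurement.** Each cluster is attributed to the DAPI-positive
  cell owning the majority of its pixels; cells co-labeled with CD31
  clusters are classified endothelial; a region mask splits cells into
  anatomical shell/core; group summaries bin endothelial cells by cluster
  count.
* **Tabular stages.** Social-interaction (SI) ratio phenotyping
  (ratio < 1 → susceptible, > 1 → resilient), ΔΔCt relative qPCR
  quantification (fold = 2^−ΔΔCt, normalized on a housekeeping gene), the
  2-SD outlier screen, differential-expression filtering at |FC| ≥ 2 and
  P < 0.05 with Venn-region counts, ChIP-qPCR percent-input, one/two-way
  ANOVA with Bonferroni posttests, and Pearson correlation.
* **Synthetic ground truth.** A scene generator renders elliptical nuclei,
  CD31-bearing endothelial subsets, and Poisson-distributed Gaussian
  puncta on a noisy, unevenly lit background — with full truth tables — so
  every stage is testable end-to-end without animal data.

## Worked example

Run the full pipeline on three synthetic groups (CTRL / SS / RES, four
512×512 scenes of 30 nuclei each) in which the resilient group's
per-endothelial-cell target-puncta mean is reduced 40% (4.0 → 2.4):

```python
from vascuscope import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=7))
table = result.cell_table
endo = table[table["is_endothelial"]]
print("cells detected:", len(table), "| endothelial:", len(endo))
print(endo.groupby("group")["count_TARGET1"].agg(["mean", "count"]).round(2))
rep = result.stats_report
print(f"one-way ANOVA: F={rep['F']:.2f}, df={rep['df']}, p={rep['p']:.3g}")
for post in rep["posttests"]:
    print(f"  {post['pair'][0]} vs {post['pair'][1]}: "
          f"p_adj={post['p_adj']:.3g} {'*' if post['significant'] else 'ns'}")
```

prints

```
cells detected: 360 | endothelial: 108
       mean  count
group
CTRL   3.50     36
RES    2.33     36
SS     4.11     36
one-way ANOVA: F=9.16, df=(2, 105), p=0.000215
  CTRL vs SS: p_adj=0.579 ns
  CTRL vs RES: p_adj=0.0159 *
  SS vs RES: p_adj=6.94e-05 *
```

All 360 planted nuclei are recovered as DAPI-positive cells; the 30%
endothelial subset is classified from CD31 co-labeling; the RES group's
mean cluster count per endothelial cell (2.33 vs 3.50 in CTRL, a 33%
observed reduction of the planted 40% effect at this seed) is flagged by
the Bonferroni posttest while the null CTRL–SS contrast is not.

The same stages are available from the shell:

```sh
vascuscope synth --config scene.yaml --out scene/ --seed 3
vascuscope detect --image scene/DAPI.tif --mode cells --out cells.csv
vascuscope quantify --dapi scene/DAPI.tif --spots CD31 scene/CD31.tif \
    --spots TARGET1 scene/TARGET1.tif --mask scene/region_mask.tif \
    --out cells_quant.csv
vascuscope stats --behavior behavior.csv --qpcr qpcr.csv --genes genes.csv \
    --out report/
vascuscope run --config run.yaml --seed 7 --out runout/
```

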