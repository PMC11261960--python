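# imcpheno

Artifact correction and semi-supervised cell phenotyping for multiplexed
ion-beam / imaging mass cytometry (IMC) data.

IMC and MIBI produce one ion-count image per antibody channel.  Three
artifact classes corrupt them — channel spillover (isotopic impurity / oxide
formation leaking a "source" channel into "target" channels), shot noise,
and antibody aggregates ("hot pixels") — and, downstream, cells in dense
immune infiltrates acquire non-biological co-expression patterns (e.g.
CD20 with CD8) that produce implausible phenotypes.  `imcpheno` addresses
both ends for scientists analyzing immune-rich tissue:

* **imclean** — per-channel artifact correction: spillover is removed by
  capping, smoothing and binarizing the source channel into a mask
  `M = [G_sigma(min(S, cap)) > t]` and subtracting a fixed removal value `v`
  under it, `T' = max(T − v, 0) on M`; noise by a floor threshold with a
  local-support test; aggregates by blur → binarize → connected-component
  labelling, zeroing components smaller than a size threshold.  All
  operators are pixelwise non-amplifying and preserve non-negativity.
* **measure** — single-cell tables from an image stack plus an integer
  label mask (segmentation itself is external): per-cell mean channel
  intensity, area, centroid, plus centroid-distance spatial neighbors.
* **phenotype** — a two-stage phenotyper.  Stage 1 scales expressions
  (`asinh(x/5)` then per-channel z-score), ranks each cell's top-3 markers,
  finds its dominant lineage marker, and applies an ordered, editable rule
  tree (first match wins; a negative-selection fallback labels cells
  matching no rule, e.g. hepatocytes).  Stage 2 subclusters a metacluster
  with a seeded self-organizing map whose codebook is merged (average
  linkage) into 9 consensus clusters by default, followed by manual
  merge/annotate and integration back into the master table.
* **metrics** — raw-vs-processed comparison statistics: positive-marker
  percentages, relative changes, specificity ratios
  (in-phenotype rate / out-of-phenotype rate), median fold changes,
  mixed-phenotype rates per conflict pair, and composition summaries.
* **synth** — a ground-truth simulator: disk-shaped cells with
  phenotype-specific Poisson signatures, injected channel crosstalk,
  background speckle and logged aggregate blobs, rendered to the same TIFF
  layouts the rest of the pipeline reads; plus a fast expression-table
  generator with mixed-phenotype contamination.

Default rule trees for a 22-marker human liver panel (10 metaclusters) and
a 25-marker mouse liver panel (7 immune metaclusters) ship as editable JSON.

## Worked example

Simulate a contaminated ROI, correct it, phenotype both branches against
the same segmentation mask, and compare:

```python
from imcpheno import (
    DEFAULT_CONFLICT_PAIRS, DEFAULT_HUMAN_SPILLOVER, ROIConfig,
    assign_metaclusters, human_rules, measure_cells, mixed_phenotype_rate,
    pooled_transform_scale, recommended_settings, simulate_roi,
    specificity_ratio,
)
from imcpheno.io import preprocess_stack

config = ROIConfig(spillover=DEFAULT_HUMAN_SPILLOVER)
roi = simulate_roi(config, seed=42)
processed = preprocess_stack(roi.stack, recommended_settings(config))

raw = measure_cells(roi.stack, roi.mask, sample_id="s1")
proc = measure_cells(processed, roi.mask, sample_id="s1")
markers = config.signatures.markers
raw_s, proc_s = pooled_transform_scale([raw, proc], markers)
rules = human_rules()
raw_ann = assign_metaclusters(raw_s, rules, markers)
proc_ann = assign_metaclusters(proc_s, rules, markers)

pairs = DEFAULT_CONFLICT_PAIRS["human"]
mr, mp = mixed_phenotype_rate(raw_ann, pairs), mixed_phenotype_rate(proc_ann, pairs)
for pair in pairs:
    print(f"mixed {pair[0]}+{pair[1]}: raw {mr[pair]:.1f}% -> processed {mp[pair]:.1f}%")
for marker, label in [("CD20", "B cells"), ("CD68", "Macrophages")]:
    print(f"specificity of {marker} in {label}: raw "
          f"{specificity_ratio(raw_ann, label, marker):.2f} -> processed "
          f"{specificity_ratio(proc_ann, label, marker):.2f}")
```

Output:

```
mixed CD20+CD4: raw 9.0% -> processed 0.0%
mixed CD20+CD8: raw 12.5% -> processed 0.0%
mixed CD3+CD20: raw 21.5% -> processed 0.0%
specificity of CD20 in B cells: raw 2.40 -> processed inf
specificity of CD68 in Macrophages: raw 8.43 -> processed inf
```

Reading it: in the raw branch, injected crosstalk puts B- and T-cell lineage
markers together in single cells' top-3 (9–21% of cells show a conflicting
pair), and CD20 is only 2.4x more often positive inside the B-cell
metacluster than outside it.  After artifact correction the mixed phenotypes
vanish and each lineage marker is positive essentially only in its own
metacluster (an infinite ratio means the outside rate dropped to zero).

The same flow is available from the shell:

```sh
imcpheno simulate roi --n-cells 200 --seed 42 --out roi_1
imcpheno preprocess --input roi_1 --panel roi_1/panel.csv --params params.yaml --output roi_1_clean
imcpheno measure --stack roi_1_clean --mask roi_1/mask.tiff --panel roi_1/panel.csv --output cells.csv
imcpheno phenotype meta --cells cells.csv --rules human --out labeled.csv
imcpheno phenotype sub --cells labeled.csv --metacluster Macrophages \
    --split CD163:0 --markers CD16,HLADR,CD68,CD163,Ki67 --k 9 --seed 42 --out sub.csv
imcpheno metrics --raw raw_labeled.csv --processed labeled.csv --out report.json
imcpheno run --config run.yaml   # full pipeline + manifest
```

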