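{
  "name": "mouse_liver_default",
  "species": "mouse",
  "lineage_markers": ["CD3", "CD4", "CD8", "B220", "CD68", "CD11c", "F480", "CD206", "CD11b", "Ly6G", "MHCII", "CD161", "CD31", "CD29", "Ecad", "aSMA"],
  "fallback_label": "Other non-immune",
  "fallback_immune": false,
  "rank_k": 3,
  "conflict_pairs": [["B220", "CD4"], ["B220", "CD8"], ["CD3", "B220"], ["CD11c", "CD3"], ["CD11c", "B220"]],
  "rules": [
    {
      "label": "CD4+ T-cells",
      "lineage_marker": "CD4",
      "conditions": [["CD4", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad"],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "CD8+ T-cells",
      "lineage_marker": "CD8",
      "conditions": [["CD8", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad"],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "NK cells",
      "lineage_marker": "CD161",
      "conditions": [["CD161", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "B cells",
      "lineage_marker": "B220",
      "conditions": [["B220", ">", 0.0]],
      "topk_exclude": ["CD4", "CD8", "CD68", "F480", "Ly6G", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Dendritic cells",
      "lineage_marker": "CD11c",
      "conditions": [["CD11c", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Macrophages",
      "lineage_marker": "CD68",
      "conditions": [["CD68", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": 5,
      "immune": true
    },
    {
      "label": "Macrophages",
      "lineage_marker": "F480",
      "conditions": [["F480", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": 5,
      "immune": true
    },
    {
      "label": "Macrophages",
      "lineage_marker": "CD206",
      "conditions": [["CD206", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": 5,
      "immune": true
    },
    {
      "label": "PMNs",
      "lineage_marker": "Ly6G",
      "conditions": [["Ly6G", ">", 0.0]],
      "topk_exclude": ["B220", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Myofibroblasts",
      "lineage_marker": "aSMA",
      "conditions": [["aSMA", ">", 0.0]],
      "topk_exclude": ["CD4", "CD8", "B220", "Ly6G"],
      "topk_require": [],
      "rank_k": null,
      "immune": false
    },
    {
      "label": "Epithelial cells",
      "lineage_marker": "Ecad",
      "conditions": [["Ecad", ">", 0.0]],
      "topk_exclude": ["CD4", "CD8", "B220", "Ly6G", "aSMA"],
      "topk_require": [],
      "rank_k": null,
      "immune": false
    },
    {
      "label": "Endothelial cells",
      "lineage_marker": "CD31",
      "conditions": [["CD31", ">", 0.0]],
      "topk_exclude": ["B220", "Ly6G", "Ecad", "aSMA"],
      "topk_require": [],
      "rank_k": null,
      "immune": false
    }
  ]
}
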