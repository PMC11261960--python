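{
  "name": "human_liver_default",
  "species": "human",
  "lineage_markers": [
    "CD4",
    "CD8",
    "CD20",
    "CD68",
    "CD163",
    "CD11b",
    "CD66b",
    "CD31",
    "CK7",
    "CD138"
  ],
  "fallback_label": "Hepatocytes",
  "fallback_immune": false,
  "rank_k": 3,
  "conflict_pairs": [
    [
      "CD20",
      "CD4"
    ],
    [
      "CD20",
      "CD8"
    ],
    [
      "CD3",
      "CD20"
    ]
  ],
  "rules": [
    {
      "label": "CD4+ T-cells",
      "lineage_marker": "CD4",
      "conditions": [
        [
          "CD4",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [
        "CD66b",
        "CK7"
      ],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "CD8+ T-cells",
      "lineage_marker": "CD8",
      "conditions": [
        [
          "CD8",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [
        "CD66b",
        "CK7"
      ],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "B cells",
      "lineage_marker": "CD20",
      "conditions": [
        [
          "CD20",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [
        "CD4",
        "CD8",
        "CD68",
        "CD163",
        "CD66b",
        "CD31",
        "CK7",
        "GranzymeB"
      ],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Macrophages",
      "lineage_marker": "CD68",
      "conditions": [
        [
          "CD68",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Macrophages",
      "lineage_marker": "CD163",
      "conditions": [
        [
          "CD163",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Monocytes",
      "lineage_marker": "CD11b",
      "conditions": [
        [
          "CD11b",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [
        "CD20",
        "CD66b",
        "CK7"
      ],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Neutrophils",
      "lineage_marker": "CD66b",
      "conditions": [
        [
          "CD66b",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [
        "CD20",
        "CK7"
      ],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Plasma cells",
      "lineage_marker": "CD138",
      "conditions": [
        [
          "CD138",
          ">",
          1.0
        ]
      ],
      "topk_exclude": [],
      "topk_require": [],
      "rank_k": null,
      "immune": true
    },
    {
      "label": "Endothelial cells",
      "lineage_marker": "CD31",
      "conditions": [
        [
          "CD31",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [
        "CD20",
        "CD66b"
      ],
      "topk_require": [],
      "rank_k": null,
      "immune": false
    },
    {
      "label": "Cholangiocytes",
      "lineage_marker": "CK7",
      "conditions": [
        [
          "CK7",
          ">",
          0.0
        ]
      ],
      "topk_exclude": [
        "CD20",
        "CD66b"
      ],
      "topk_require": [],
      "rank_k": null,
      "immune": false
    }
  ]
}
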