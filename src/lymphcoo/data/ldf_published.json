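{
  "_comment": "Published per-class linear discriminant function coefficients for the eight antibody combinations used by the decision-tree algorithms, plus the unnamed (1,4,5) row. Inputs are positivity indicators in {0,1}. sens/spec are the printed resubstitution metrics for reference.",
  "3,5": {
    "label": "As in Nyman",
    "sens": 0.81, "spec": 0.74,
    "GCB":     {"constant": -0.57, "FOXP1": 2.47, "MUM1": 1.11},
    "non-GCB": {"constant": -3.29, "FOXP1": 4.38, "MUM1": 5.06}
  },
  "1,2,5": {
    "label": "As in Hans and Colomo",
    "sens": 0.86, "spec": 0.88,
    "GCB":     {"constant": -4.21, "CD10": 5.01, "BCL6": 7.00, "MUM1": 1.05},
    "non-GCB": {"constant": -3.09, "CD10": 0.20, "BCL6": 4.99, "MUM1": 5.69}
  },
  "1,5": {
    "label": "As in Hans*",
    "sens": 0.77, "spec": 0.91,
    "GCB":     {"constant": -2.29, "CD10": 6.53, "MUM1": 2.11},
    "non-GCB": {"constant": -2.12, "CD10": 1.28, "MUM1": 6.45}
  },
  "1,2,3,4,5": {
    "label": "As in Choi",
    "sens": 0.87, "spec": 0.91,
    "GCB":     {"constant": -4.80, "CD10": 4.59, "BCL6": 6.31, "FOXP1": 0.71, "GCET1": 3.28, "MUM1": 1.02},
    "non-GCB": {"constant": -3.98, "CD10": -0.41, "BCL6": 3.80, "FOXP1": 3.75, "GCET1": 1.24, "MUM1": 4.73}
  },
  "1,3,4,5": {
    "label": "As in Choi*",
    "sens": 0.86, "spec": 0.91,
    "GCB":     {"constant": -3.34, "CD10": 5.67, "FOXP1": 1.78, "GCET1": 4.03, "MUM1": 1.67},
    "non-GCB": {"constant": -3.46, "CD10": 0.24, "FOXP1": 4.39, "GCET1": 1.69, "MUM1": 5.12}
  },
  "1,2,3": {
    "label": "As in VY3",
    "sens": 0.87, "spec": 0.91,
    "GCB":     {"constant": -4.18, "CD10": 4.86, "BCL6": 6.99, "FOXP1": 0.64},
    "non-GCB": {"constant": -2.90, "CD10": -0.74, "BCL6": 4.58, "FOXP1": 4.61}
  },
  "1,2,3,4": {
    "label": "As in VY4",
    "sens": 0.84, "spec": 0.90,
    "GCB":     {"constant": -4.75, "CD10": 4.49, "BCL6": 6.44, "FOXP1": 0.91, "GCET1": 3.26},
    "non-GCB": {"constant": -2.97, "CD10": -0.86, "BCL6": 4.40, "FOXP1": 4.70, "GCET1": 1.12}
  },
  "1,4,5": {
    "label": "(unnamed)",
    "sens": 0.81, "spec": 0.92,
    "GCB":     {"constant": -3.14, "CD10": 6.01, "GCET1": 3.93, "MUM1": 2.22},
    "non-GCB": {"constant": -2.23, "CD10": 1.09, "GCET1": 1.44, "MUM1": 6.49}
  }
}
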