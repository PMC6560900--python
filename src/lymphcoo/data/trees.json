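{
  "Hans": {
    "name": "Hans",
    "nodes": [
      {"id": "cd10", "marker": "CD10", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "bcl6"},
      {"id": "bcl6", "marker": "BCL6", "cutoff_percent": 30, "if_positive": "mum1", "if_negative": "nonGCB"},
      {"id": "mum1", "marker": "MUM1", "cutoff_percent": 30, "if_positive": "nonGCB", "if_negative": "GCB"}
    ]
  },
  "Colomo": {
    "name": "Colomo",
    "nodes": [
      {"id": "cd10", "marker": "CD10", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "mum1"},
      {"id": "mum1", "marker": "MUM1", "cutoff_percent": 30, "if_positive": "nonGCB", "if_negative": "bcl6"},
      {"id": "bcl6", "marker": "BCL6", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "nonGCB"}
    ]
  },
  "Nyman": {
    "name": "Nyman",
    "nodes": [
      {"id": "mum1", "marker": "MUM1", "cutoff_percent": 30, "if_positive": "nonGCB", "if_negative": "foxp1"},
      {"id": "foxp1", "marker": "FOXP1", "cutoff_percent": 80, "if_positive": "nonGCB", "if_negative": "GCB"}
    ]
  },
  "Choi": {
    "name": "Choi",
    "nodes": [
      {"id": "gcet1", "marker": "GCET1", "cutoff_percent": 80, "if_positive": "mum1", "if_negative": "cd10"},
      {"id": "mum1", "marker": "MUM1", "cutoff_percent": 80, "if_positive": "nonGCB", "if_negative": "GCB"},
      {"id": "cd10", "marker": "CD10", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "foxp1"},
      {"id": "foxp1", "marker": "FOXP1", "cutoff_percent": 80, "if_positive": "nonGCB", "if_negative": "bcl6"},
      {"id": "bcl6", "marker": "BCL6", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "nonGCB"}
    ]
  },
  "Choi*": {
    "name": "Choi*",
    "nodes": [
      {"id": "gcet1", "marker": "GCET1", "cutoff_percent": 80, "if_positive": "mum1", "if_negative": "cd10"},
      {"id": "mum1", "marker": "MUM1", "cutoff_percent": 80, "if_positive": "nonGCB", "if_negative": "GCB"},
      {"id": "cd10", "marker": "CD10", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "foxp1"},
      {"id": "foxp1", "marker": "FOXP1", "cutoff_percent": 80, "if_positive": "nonGCB", "if_negative": "GCB"}
    ]
  },
  "Hans*": {
    "name": "Hans*",
    "nodes": [
      {"id": "cd10", "marker": "CD10", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "mum1"},
      {"id": "mum1", "marker": "MUM1", "cutoff_percent": 30, "if_positive": "nonGCB", "if_negative": "GCB"}
    ]
  },
  "VY3": {
    "name": "VY3",
    "nodes": [
      {"id": "cd10", "marker": "CD10", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "foxp1"},
      {"id": "foxp1", "marker": "FOXP1", "cutoff_percent": 60, "if_positive": "nonGCB", "if_negative": "bcl6"},
      {"id": "bcl6", "marker": "BCL6", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "nonGCB"}
    ]
  },
  "VY4": {
    "name": "VY4",
    "nodes": [
      {"id": "cd10", "marker": "CD10", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "foxp1"},
      {"id": "foxp1", "marker": "FOXP1", "cutoff_percent": 60, "if_positive": "nonGCB", "if_negative": "gcet1"},
      {"id": "gcet1", "marker": "GCET1", "cutoff_percent": 60, "if_positive": "GCB", "if_negative": "bcl6"},
      {"id": "bcl6", "marker": "BCL6", "cutoff_percent": 30, "if_positive": "GCB", "if_negative": "nonGCB"}
    ]
  }
}
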