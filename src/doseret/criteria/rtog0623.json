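{
  "name": "RTOG0623",
  "version": "1.0",
  "rules": [
    {"structure": "spinal_cord", "metric": "Dmax", "comparator": "<=", "threshold": 45.0, "units": "Gy"},
    {"structure": "total_lung", "metric": "V20", "comparator": "<", "threshold": 37.0, "units": "%"},
    {"structure": "total_lung", "metric": "MLD", "comparator": "<", "threshold": 20.0, "units": "Gy"},
    {"structure": "heart", "metric": "V40", "comparator": "<", "threshold": 100.0, "units": "%"},
    {"structure": "heart", "metric": "V45", "comparator": "<", "threshold": 67.0, "units": "%"},
    {"structure": "heart", "metric": "V60", "comparator": "<", "threshold": 33.0, "units": "%"}
  ]
}
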