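{
  "name": "department",
  "version": "1.0",
  "rules": [
    {"structure": "spinal_cord", "metric": "Dmax", "comparator": "<=", "threshold": 45.0, "units": "Gy"},
    {"structure": "total_lung", "metric": "V20", "comparator": "<", "threshold": 25.0, "units": "%"},
    {"structure": "total_lung", "metric": "V5", "comparator": "<", "threshold": 45.0, "units": "%"},
    {"structure": "total_lung", "metric": "MLD", "comparator": "<=", "threshold": 15.0, "units": "Gy"},
    {"structure": "heart", "metric": "V30", "comparator": "<", "threshold": 40.0, "units": "%"},
    {"structure": "heart", "metric": "V40", "comparator": "<", "threshold": 30.0, "units": "%"},
    {"structure": "heart", "metric": "MHD", "comparator": "<=", "threshold": 26.0, "units": "Gy", "advisory": true}
  ]
}
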