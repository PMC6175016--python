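{
  "design": {
    "prevalences": [0.25, 0.5, 0.75, 1.0],
    "sigma": 7.0,
    "futility_b": 2.0,
    "n1": [90, 90, 90, 90],
    "n2": [120, 120, 120, 120]
  },
  "data": {
    "summary": "examples/worked_example_summary.csv"
  }
}
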