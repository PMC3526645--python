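{
  "16S": {"p": "<0.001", "op": 0.2, "sensitivity": 100, "specificity": 96, "ppv": 75, "npv": 100, "auc": 0.99},
  "ITS": {"p": "<0.001", "op": 0.25, "sensitivity": 100, "specificity": 76, "ppv": 35, "npv": 100, "auc": 0.92},
  "rpoB": {"p": "<0.001", "op": 0.2, "sensitivity": 100, "specificity": 100, "ppv": 100, "npv": 100, "auc": 1.0}
}
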