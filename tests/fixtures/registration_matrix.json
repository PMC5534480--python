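{
  "description": "Whole-brain rigid registration matrix estimated from 10 um resampled mouse-brain data (reconstructed from a published run-on listing; rotation only, zero translation).",
  "matrix": [
    [0.868588, -0.391007, -0.304410, 0.0],
    [0.273509, 0.890550, -0.363469, 0.0],
    [0.413211, 0.232447, 0.880467, 0.0],
    [0.0, 0.0, 0.0, 1.0]
  ]
}
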