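# Adult (ages 19-65) body weights, kg, by reporting stratum.
strata:
  male: 69.33
  female: 57.27
  mean: 63.3
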