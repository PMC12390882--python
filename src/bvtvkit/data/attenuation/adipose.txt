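# mass attenuation coefficients, adipose tissue, ICRU-46 elemental composition
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  0.305016
   35.0  0.267589
   40.0  0.238901
   45.0  0.224276
   50.0  0.211954
   55.0  0.204086
   60.0  0.197159
   65.0  0.192212
   70.0  0.187743
   75.0  0.183676
   80.0  0.179951
   90.0  0.173979
  100.0  0.168804
  110.0  0.164172
  120.0  0.160054
  135.0  0.154643
  150.0  0.149958
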