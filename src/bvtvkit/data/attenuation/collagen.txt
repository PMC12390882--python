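# mass attenuation coefficients, collagen, C102H149N31O38 repeat unit
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  0.304508
   35.0  0.264353
   40.0  0.233875
   45.0  0.218397
   50.0  0.205422
   55.0  0.197252
   60.0  0.190077
   65.0  0.185052
   70.0  0.180518
   75.0  0.176397
   80.0  0.172627
   90.0  0.166711
  100.0  0.161591
  110.0  0.157087
  120.0  0.153084
  135.0  0.147829
  150.0  0.143281
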