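# mass attenuation coefficients, polymethyl methacrylate C5H8O2
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  0.303229
   35.0  0.264522
   40.0  0.235011
   45.0  0.220007
   50.0  0.207400
   55.0  0.199408
   60.0  0.192382
   65.0  0.187419
   70.0  0.182939
   75.0  0.178864
   80.0  0.175134
   90.0  0.169223
  100.0  0.164105
  110.0  0.159564
  120.0  0.155528
  135.0  0.150227
  150.0  0.145638
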