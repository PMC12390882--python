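# mass attenuation coefficients, 0.9% NaCl saline, mass-weighted water + NaCl
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  0.383595
   35.0  0.318626
   40.0  0.271313
   45.0  0.247657
   50.0  0.228249
   55.0  0.216641
   60.0  0.206559
   65.0  0.199971
   70.0  0.194059
   75.0  0.188712
   80.0  0.183844
   90.0  0.176770
  100.0  0.170673
  110.0  0.165666
  120.0  0.161224
  135.0  0.155400
  150.0  0.150369
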