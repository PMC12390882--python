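# mass attenuation coefficients, dry air, sea level (NIST tabulation)
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  0.353800
   35.0  0.292781
   40.0  0.248500
   45.0  0.226227
   50.0  0.208000
   55.0  0.197018
   60.0  0.187500
   65.0  0.181313
   70.0  0.175768
   75.0  0.170757
   80.0  0.166200
   90.0  0.159699
  100.0  0.154100
  110.0  0.149536
  120.0  0.145488
  135.0  0.140182
  150.0  0.135600
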