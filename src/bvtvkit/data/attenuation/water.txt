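# mass attenuation coefficients, liquid water (NIST tabulation)
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  0.375600
   35.0  0.313644
   40.0  0.268300
   45.0  0.245585
   50.0  0.226900
   55.0  0.215668
   60.0  0.205900
   65.0  0.199467
   70.0  0.193690
   75.0  0.188462
   80.0  0.183700
   90.0  0.176719
  100.0  0.170700
  110.0  0.165720
  120.0  0.161302
  135.0  0.155507
  150.0  0.150500
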