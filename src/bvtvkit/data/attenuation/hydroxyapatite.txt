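# mass attenuation coefficients, calcium hydroxyapatite Ca10(PO4)6(OH)2
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  1.458415
   35.0  0.969810
   40.0  0.681074
   45.0  0.525435
   50.0  0.416609
   55.0  0.352911
   60.0  0.303303
   65.0  0.274580
   70.0  0.250418
   75.0  0.229838
   80.0  0.212121
   90.0  0.192316
  100.0  0.176171
  110.0  0.167354
  120.0  0.159691
  135.0  0.149873
  150.0  0.141604
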