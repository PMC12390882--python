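# mass attenuation coefficients, sodium chloride, elemental mixture rule
# anchored to NIST/XCOM reference values (water, air, H, C);
# heavier elements via Klein-Nishina + coherent/photoelectric scaling
# energy_keV  mu_over_rho_cm2_per_g
   30.0  1.263958
   35.0  0.850189
   40.0  0.603024
   45.0  0.470485
   50.0  0.376812
   55.0  0.322131
   60.0  0.279170
   65.0  0.254306
   70.0  0.233265
   75.0  0.215244
   80.0  0.199649
   90.0  0.182075
  100.0  0.167670
  110.0  0.159606
  120.0  0.152583
  135.0  0.143567
  150.0  0.135954
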