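molecule,p_sim_440K_cm_s,p_sim_sd_cm_s,p_eff_310K_cm_s,p_sim_lit_310K_cm_s,p_exp_lit_310K_cm_s
Ammonia,30.2,0.586,6.88e-4,8.10e-4,
Ethanol,24.4,0.29,5.42e-4,9.3e-4,1.10e-3
Nicotine,4.6,0.225,8.36e-5,1.98e-4,1.78e-4
Tariquidar,0.0148,0.0106,1.03e-8,,
Rhodamine 123,2.04,0.129,3.36e-5,,
Fasudil,1.54,0.0918,2.45e-5,,
DKP,0.736,0.067,1.07e-5,3.4e-5,
PPF,0.232,0.0362,2.95e-6,,6.88e-6
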