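molecule,dg_barrier_kcal_mol,dg_barrier_sd,sigma_nm,sigma_sd
Ammonia,0.28,0.04,1.13,0.10
Ethanol,0.97,0.08,1.07,0.11
Nicotine,0.79,0.05,0.69,0.06
Fasudil,1.78,0.05,0.36,0.05
Rhodamine,0.61,0.04,0.52,0.06
Tariquidar,0.69,0.07,0.45,0.04
DKP,0.62,0.06,0.96,0.08
PPF,1.37,0.15,1.11,0.10
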