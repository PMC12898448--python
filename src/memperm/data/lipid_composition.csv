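species,full_name,percentage
POPC,1-palmitoyl-2-oleoyl-sn-glycero-3-phosphocholine,4.1
SAPI,1-stearoyl-2-arachidonoyl-sn-glycero-3-phosphoinositol,2.0
CHOL,Cholesterol,29.3
SAPE,1-stearoyl-2-arachidonoyl-sn-glycero-3-phosphoethanolamine,14.5
SAPC,1-stearoyl-2-arachidonoyl-sn-glycero-3-phosphocholine,8.3
OSM,palmitoyl sphingomyelin,18.9
SLPC,1-stearoyl-2-linoleoyl-sn-glycero-3-phosphocholine,8.3
SOPE,1-stearoyl-2-oleoyl-sn-glycero-3-phosphoethanolamine,6.3
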