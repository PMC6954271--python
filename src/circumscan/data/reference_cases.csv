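method,case_id,sim_area_cm2,surface_area_cm2,elapsed_min
manual,21,18.58,96.90,39
manual,22,28.63,86.16,53
manual,25,12.62,57.20,39
manual,27,21.99,64.60,42
manual,28,18.84,68.80,42
manual,30,25.19,76.48,46
manual,31,12.25,65.70,35
manual,33,16.80,56.70,34
manual,38,24.48,71.64,43
manual,40,27.97,64.12,46
manual,41,22.36,66.72,42
manual,42,25.14,55.21,43
manual,43,29.92,54.44,40
manual,44,23.20,58.04,49
manual,45,21.33,70.64,58
apps,57,26.63,,39
apps,58,30.64,,32
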