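method	variant_name	delta_n	delta_w	max_af
energy_scan	rs1479981622:C>T	5	-62.01	8e-06
energy_scan	rs536092006:T>C	5	-61.06	0.0003
energy_scan	rs1049043869:C>G	6	-55.91	6.4e-05
seed_scan	rs775376244:T>C	2	-24.60	0.0005
seed_scan	rs550965893:T>G	2	-22.41	0.0002
seed_scan	rs771705336:C>G	1	-17.85	0.0003
seed_scan	rs766853644:T>C	1	-17.68	8e-06
seed_scan	rs1362918185:G>A	1	-16.64	2.4e-05
seed_scan	rs536221210:A>G	1	-16.57	
seed_scan	rs1221977896:A>C	1	-16.30	2.4e-05
seed_scan	rs752035593:G>A	1	-15.81	3.2e-05
seed_scan	rs1260437486:G>A	1	-15.56	8e-06
seed_scan	rs1014491371:C>G	1	-15.29	8e-06
seed_scan	rs761935330:G>A	1	-15.03	0.0003
seed_scan	rs1441949563:C>T	1	-14.07	3e-05
seed_scan	rs1033831185:A>G	1	-11.70	3e-05
seed_scan	rs1358226278:C>G	1	-11.38	8e-06
seed_scan	rs1424327104:C>T	1	-11.11	
seed_scan	rs1288407577:T>G	1	-10.58	4e-06
seed_scan	rs1187772510:A>G	1	-8.98	3.2e-05
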