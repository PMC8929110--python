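method	variant_name	delta_n	delta_w	max_af
energy_scan	rs1296755923:T>G	9	-126.61	0.0003
energy_scan	rs1207839989:A>G	8	-101.32	3e-05
energy_scan	rs1041875974:G>T	6	-98.42	
energy_scan	rs981079616:T>G	6	-94.19	8e-06
energy_scan	rs760246677:G>T	6	-91.69	8e-06
energy_scan	rs989262025:A>G	6	-84.46	3.3e-05
energy_scan	rs1281573015:A>T	8	-83.06	8e-06
energy_scan	rs1248738927:G>C	6	-82.47	
energy_scan	rs1221590835:G>A	7	-79.94	3e-05
energy_scan	rs1324216335:T>C	7	-74.46	8e-06
energy_scan	rs1206166531:C>G	5	-71.61	0
energy_scan	rs1194042023:A>G	5	-68.88	3.2e-05
energy_scan	rs889120755:C>G	5	-68.86	
energy_scan	rs571735282:A>G	5	-65.47	0.0012
energy_scan	COSN31961029:T>C	5	-65.08	
energy_scan	rs902240610:A>G	5	-64.83	8e-05
energy_scan	rs552609115:T>C	5	-64.25	
energy_scan	rs930259829:T>G	7	-63.86	4.8e-05
energy_scan	rs1206166531:C>T	5	-58.35	0.0002
energy_scan	rs535308545:A>C	5	-58.35	3.2e-05
energy_scan	rs1381450764:G>A	6	-57.20	
energy_scan	rs923348310:C>T	5	-53.65	7.2e-05
energy_scan	rs752666806:C>T	5	-45.40	
seed_scan	rs565097712:G>A	7	-77.40	0.0004
seed_scan	rs1396697573:A>G	2	-41.98	
seed_scan	rs1307365736:A>T	2	-30.12	8e-06
seed_scan	rs895962647:A>T	2	-27.72	3.2e-05
seed_scan	rs942463789:T>G	1	-24.94	0.0003
seed_scan	rs997751105:C>T	2	-22.40	1.6e-05
seed_scan	rs926249853:T>G	2	-20.43	8e-06
seed_scan	rs1478240035:G>T	1	-19.62	8e-06
seed_scan	rs1405544334:G>T	1	-19.59	8e-06
seed_scan	rs1273786688:T>G	2	-18.42	0.005
seed_scan	rs1045581145:A>T	1	-17.48	8e-06
seed_scan	rs889120755:C>G	1	-16.79	
seed_scan	rs923753708:G>C	1	-16.70	
seed_scan	rs1461667204:T>A	1	-16.60	8e-06
seed_scan	rs528282193:C>T	1	-16.60	0.001
seed_scan	rs1338875884:A>G	1	-16.32	3e-05
seed_scan	rs1165916168:C>T	1	-16.04	
seed_scan	MU75396710:C>G	1	-15.66	
seed_scan	rs1394767633:A>G	1	-15.34	3.2e-05
seed_scan	rs1288975386:T>A	1	-14.99	
seed_scan	rs752666806:C>T	1	-14.39	
seed_scan	rs1253019517:T>A	1	-14.31	1.6e-05
seed_scan	rs1219762419:A>G	1	-13.75	6e-05
seed_scan	rs1371551409:A>C	1	-13.69	8e-06
seed_scan	rs1181773370:C>T	1	-12.71	3e-05
seed_scan	rs1452738847:A>G	1	-12.03	8e-06
seed_scan	rs1467042427:A>G	1	-11.51	8e-06
seed_scan	COSN25075844:T>C	1	-11.48	
seed_scan	COSN25075844:T>C	1	-11.48	
seed_scan	MU85472748:T>C	1	-11.48	
seed_scan	MU85472748:T>C	1	-11.48	
seed_scan	rs972230345:A>G	1	-11.44	4e-05
seed_scan	rs887676239:A>G	1	-11.12	5.6e-05
seed_scan	rs959339279:A>G	1	-11.00	0.0001
seed_scan	rs971064154:A>G	1	-10.68	8e-06
seed_scan	rs1205529398:G>A	1	-9.88	8e-06
seed_scan	rs1306390419:A>G	1	-9.49	8e-06
seed_scan	rs1292049568:G>T	1	-9.33	8e-06
seed_scan	rs982013263:G>T	1	-9.17	6.4e-05
seed_scan	rs914976738:C>T	1	-8.97	
seed_scan	rs1488494352:A>G	1	-8.60	8e-06
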