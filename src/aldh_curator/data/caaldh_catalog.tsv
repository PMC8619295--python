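gene_name	locus_id	chromosome	start_bp	end_bp	strand	exon_count	protein_length_aa	molecular_weight_kda	isoform_count	isoelectric_point
CaALDH3F1	LOC101497113	Ca1	11135019	11130555	-	10	494	54.82	1	8.10
CaALDH22A1	LOC101512347	Ca1	17180053	17171549	-	14	595	65.35	1	6.72
CaALDH7A1	LOC101513733	Ca1	23039421	23046624	+	15	508	54.09	2	5.70
CaALDH5F1	LOC101506901	Ca1	37645851	37658363	+	20	530	56.59	1	6.58
CaALDH18B3	LOC101499756	Ca3	8714224	8700487	-	20	717	77.75	2	5.96
CaALDH3H3	LOC101515558	Ca4	38313842	38325387	+	10	488	53.06	1	8.43
CaALDH10A8	LOC101507930	Ca5	39963842	39971506	+	15	503	54.53	1	5.37
CaALDH3H2	LOC101510937	Ca5	44008221	44002223	-	11	488	53.18	3	7.01
CaALDH3H4	LOC101511680	Ca5	44024284	44016817	-	10	486	52.99	1	8.33
CaALDH18B2	LOC101490622	Ca6	1317458	1311762	-	21	715	77.65	1	6.62
CaALDH2C5	LOC101493969	Ca6	3278797	3283156	+	10	480	52.33	1	6.44
CaALDH3H1	LOC101505038	Ca6	6829385	6835166	+	12	542	59.76	2	7.96
CaALDH6B2	LOC101490310	Ca6	15177302	15170648	-	19	539	57.63	1	7.08
CaALDH18B1	LOC101512568	Ca6	44541903	44527947	-	21	759	82.38	4	6.82
CaALDH3F2	LOC101491914	Ca6	53416538	53426529	+	10	488	54.56	1	9.22
CaALDH11A3	LOC101510843	Ca7	1260647	1264733	+	9	496	52.81	1	6.53
CaALDH12A1	LOC101490107	Ca7	8738308	8744740	+	16	553	61.30	1	6.17
CaALDH10A9	LOC101506136	Ca7	9155132	9150438	-	14	503	54.40	1	5.37
CaALDH2B4	LOC101490532	Ca7	9459504	9464830	+	12	536	58.58	3	7.57
CaALDH3F3	LOC101511819	Ca7	14455263	14450584	-	10	488	54.13	1	7.99
CaALDH2B7	LOC101492709	Ca7	21404965	21399791	-	11	539	58.04	1	6.58
CaALDH2C6	LOC101513875	Ca8	14992271	14983690	-	9	498	44.10	1	5.55
CaALDH2C4	LOC101514219	Ca8	14998332	15002867	+	9	503	54.64	2	6.19
CaALDH3H7	LOC101502106	Un	0	0	-	0	134	15.07	1	9.49
CaALDH18B4	LOC105852801	Un	0	0	-	0	248	27.72	1	4.34
CaALDH3H5	LOC101497514	Un	0	0	-	0	214	23.51	4	9.21
CaALDH3H6	LOC101488602	Un	0	0	-	0	145	16.19	4	9.47
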