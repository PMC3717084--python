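tissue	kind	name	definition
adipose	band	A3006	2997:3017
adipose	band	A2957	2950:2966
adipose	band	A2922	2905:2936
adipose	band	A2853	2840:2861
adipose	band	A1743	1730:1760
adipose	band	A1464	1454:1474
adipose	band	A1160	1133:1200
adipose	band	A1550	1506:1571
adipose	band	A1340	1336:1345
adipose	band	A1320	1315:1327
adipose	band	A1280	1275:1285
adipose	composite	A_FAT	A3006+A2957+A2922+A2853+A1743+A1464+A1160
adipose	composite	A_SATF	A2922+A2853
adipose	composite	A_UNSATF	A3006
adipose	composite	A_COL	A1340+A1320+A1280
adipose	composite	A_PROT	A1550+A1340+A1320+A1280
adipose	ratio	saturated_to_unsaturated_fat_ratio	(A2922+A2853)/A3006
adipose	ratio	acyl_chain_length	A2922/A2957
adipose	ratio	collagen_integrity	A1550/(A1340+A1320+A1280)
adipose	ratio	lipid_to_protein_ratio	(A3006+A2957+A2922+A2853+A1743+A1464+A1160)/(A1550+A1340+A1320+A1280)
liver	band	A2963	2952:2968
liver	band	A2927	2900:2938
liver	band	A2854	2840:2861
liver	band	A1745	1737:1759
liver	band	A1455	1437:1475
liver	band	A1547	1500:1565
liver	band	A1340	1332:1346
liver	band	A1154	1141:1174
liver	band	A1081	1071:1091
liver	band	A1044	1020:1050
liver	composite	A_FAT	A2963+A2927+A2854+A1745+A1455
liver	composite	A_SATF	A2927+A2854
liver	composite	A_COL	A1340
liver	composite	A_PROT	A1547+A1340
liver	composite	A_GLYC	A1154+A1081+A1044
liver	ratio	acyl_chain_length	A2927/A2963
liver	ratio	collagen_integrity	A1547/A1340
liver	ratio	lipid_to_protein_ratio	(A2963+A2927+A2854+A1745+A1455)/(A1547+A1340)
muscle	band	A2961	2951:2968
muscle	band	A2927	2900:2939
muscle	band	A2854	2840:2861
muscle	band	A1741	1735:1755
muscle	band	A1457	1450:1472
muscle	band	A1550	1500:1570
muscle	band	A1340	1334:1355
muscle	band	A1282	1275:1287
muscle	band	A1081	1067:1100
muscle	band	A1046	1030:1052
muscle	composite	A_FAT	A2961+A2927+A2854+A1741+A1457
muscle	composite	A_SATF	A2927+A2854
muscle	composite	A_COL	A1340+A1282
muscle	composite	A_PROT	A1550+A1340+A1282
muscle	composite	A_GLYC	A1081+A1046
muscle	ratio	acyl_chain_length	A2927/A2961
muscle	ratio	collagen_integrity	A1550/(A1340+A1282)
muscle	ratio	lipid_to_protein_ratio	(A2961+A2927+A2854+A1741+A1457)/(A1550+A1340+A1282)
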