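arm_id	chrom	start	end	excluded
1p	chr1	0	121535434	0
1q	chr1	124535434	249250621	0
2p	chr2	0	92326171	0
2q	chr2	95326171	243199373	0
3p	chr3	0	90504854	0
3q	chr3	93504854	198022430	0
4p	chr4	0	49660117	0
4q	chr4	52660117	191154276	0
5p	chr5	0	46405641	0
5q	chr5	49405641	180915260	0
6p	chr6	0	58830166	0
6q	chr6	61830166	171115067	0
7p	chr7	0	58054331	0
7q	chr7	61054331	159138663	0
8p	chr8	0	43838887	0
8q	chr8	46838887	146364022	0
9p	chr9	0	47367679	0
9q	chr9	50367679	141213431	0
10p	chr10	0	39254935	0
10q	chr10	42254935	135534747	0
11p	chr11	0	51644205	0
11q	chr11	54644205	135006516	0
12p	chr12	0	34856694	0
12q	chr12	37856694	133851895	0
13p	chr13	0	16000000	1
13q	chr13	19000000	115169878	0
14p	chr14	0	16000000	1
14q	chr14	19000000	107349540	0
15p	chr15	0	17000000	1
15q	chr15	20000000	102531392	0
16p	chr16	0	35335801	0
16q	chr16	38335801	90354753	0
17p	chr17	0	22263006	0
17q	chr17	25263006	81195210	0
18p	chr18	0	15460898	0
18q	chr18	18460898	78077248	0
19p	chr19	0	24681782	0
19q	chr19	27681782	59128983	0
20p	chr20	0	26369569	0
20q	chr20	29369569	63025520	0
21p	chr21	0	11288129	1
21q	chr21	14288129	48129895	0
22p	chr22	0	13000000	1
22q	chr22	16000000	51304566	0
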