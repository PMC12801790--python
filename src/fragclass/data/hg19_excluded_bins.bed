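chr1	0	1000000
chr1	115000000	131000000
chr1	249000000	249250621
chr2	0	1000000
chr2	86000000	102000000
chr2	243000000	243199373
chr3	0	1000000
chr3	84000000	100000000
chr3	198000000	198022430
chr4	0	1000000
chr4	43000000	59000000
chr4	191000000	191154276
chr5	0	1000000
chr5	40000000	56000000
chr5	180000000	180915260
chr6	0	1000000
chr6	52000000	68000000
chr6	171000000	171115067
chr7	0	1000000
chr7	52000000	68000000
chr7	159000000	159138663
chr8	0	1000000
chr8	37000000	53000000
chr8	146000000	146364022
chr9	0	1000000
chr9	41000000	57000000
chr9	141000000	141213431
chr10	0	1000000
chr10	33000000	49000000
chr10	135000000	135534747
chr11	0	1000000
chr11	45000000	61000000
chr11	135000000	135006516
chr12	0	1000000
chr12	28000000	44000000
chr12	133000000	133851895
chr13	0	25000000
chr13	115000000	115169878
chr14	0	25000000
chr14	107000000	107349540
chr15	0	25000000
chr15	102000000	102531392
chr16	0	1000000
chr16	29000000	44000000
chr16	90000000	90354753
chr17	0	1000000
chr17	16000000	31000000
chr17	81000000	81195210
chr18	0	1000000
chr18	9000000	24000000
chr18	78000000	78077248
chr19	0	1000000
chr19	18000000	33000000
chr19	59000000	59128983
chr20	0	1000000
chr20	20000000	35000000
chr20	63000000	63025520
chr21	0	20000000
chr21	48000000	48129895
chr22	0	21000000
chr22	51000000	51304566
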