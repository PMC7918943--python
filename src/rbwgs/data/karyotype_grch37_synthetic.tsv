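chrom	length	centromere_start	centromere_end
1	249250621	121535434	124535434
2	243199373	92326171	95326171
3	198022430	90504854	93504854
4	191154276	49660117	52660117
5	180915260	46405641	49405641
6	171115067	58830166	61830166
7	159138663	58054331	61054331
8	146364022	43838887	46838887
9	141213431	47367679	50367679
10	135534747	39254935	42254935
11	135006516	51644205	54644205
12	133851895	34856694	37856694
13	115169878	16000000	19000000
14	107349540	16000000	19000000
15	102531392	17000000	20000000
16	90354753	35335801	38335801
17	81195210	22263006	25263006
18	78077248	15460898	18460898
19	59128983	24681782	27681782
20	63025520	26369569	29369569
21	48129895	11288129	14288129
22	51304566	13000000	16000000
X	155270560	58632012	61632012
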