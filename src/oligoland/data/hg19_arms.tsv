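# hg19 chromosome-arm intervals (1-based inclusive); p/q split at the
# centromere boundary of the UCSC cytoBand acen bands
chrom	arm	start	end
1	p	1	125000000
1	q	125000001	249250621
2	p	1	93300000
2	q	93300001	243199373
3	p	1	91000000
3	q	91000001	198022430
4	p	1	50400000
4	q	50400001	191154276
5	p	1	48400000
5	q	48400001	180915260
6	p	1	61000000
6	q	61000001	171115067
7	p	1	59900000
7	q	59900001	159138663
8	p	1	45600000
8	q	45600001	146364022
9	p	1	49000000
9	q	49000001	141213431
10	p	1	40200000
10	q	40200001	135534747
11	p	1	53700000
11	q	53700001	135006516
12	p	1	35800000
12	q	35800001	133851895
13	p	1	17900000
13	q	17900001	115169878
14	p	1	17600000
14	q	17600001	107349540
15	p	1	19000000
15	q	19000001	102531392
16	p	1	36600000
16	q	36600001	90354753
17	p	1	24000000
17	q	24000001	81195210
18	p	1	17200000
18	q	17200001	78077248
19	p	1	26500000
19	q	26500001	59128983
20	p	1	27500000
20	q	27500001	63025520
21	p	1	13200000
21	q	13200001	48129895
22	p	1	14700000
22	q	14700001	51304566
X	p	1	60600000
X	q	60600001	155270560
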