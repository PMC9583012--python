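no	major_allele_frequency	alleles	chromosome	position	W-2	W-3	W-4	W-6	W-7	W-43	W-45	W-46	W-9	W-106	W-108	W-109	W-111	W-112
1	0.78571	C/G	1D	170914803	C	C	C	C	C	G	G	G	C	C	C	C	C	C
2	0.78571	A/G	1D	170914885	A	A	A	A	A	G	G	G	A	A	A	A	A	A
3	0.57143	G/C	1D	402694752	G	G	G	G	G	G	G	G	C	C	C	C	C	C
4	0.71429	C/G/A	1D	438741637	C	C	C	C	C	G	G	G	A	C	C	C	C	C
5	0.57143	G/A	1D	446643840	G	G	G	G	G	G	G	G	A	A	A	A	A	A
6	0.57143	T/G/A	2D	154402884	G	G	G	G	G	T	T	T	T	T	T	T	A	T
7	0.64286	C/A	2D	219835561	A	A	A	A	A	C	C	C	C	C	C	C	C	C
8	0.78571	C/G	2D	323454908	C	C	C	C	C	G	G	G	C	C	C	C	C	C
9	0.57143	G/A	2D	376884273	G	G	G	G	G	G	G	G	A	A	A	A	A	A
10	0.64286	T/G	2D	398965931	G	G	G	G	G	T	T	T	T	T	T	T	T	T
11	0.64286	C/T	2D	398966000	T	T	T	T	T	C	C	C	C	C	C	C	C	C
12	0.71429	C/T/A	3D	15908948	C	C	C	C	C	T	T	T	A	C	C	C	C	C
13	0.78571	T/C	3D	50158698	T	T	T	T	T	C	C	C	T	T	T	T	T	T
14	0.57143	G/A	3D	91598837	G	G	G	G	G	G	G	G	A	A	A	A	A	A
15	0.57143	C/T	3D	110978366	C	C	C	C	C	C	C	C	T	T	T	T	T	T
16	0.57143	G/A	3D	123666416	G	G	G	G	G	G	G	G	A	A	A	A	A	A
17	0.57143	A/G	3D	173185540	A	A	A	A	A	A	A	A	G	G	G	G	G	G
18	0.57143	C/T	3D	211653623	C	C	C	C	C	C	C	C	T	T	T	T	T	T
19	0.78571	G/T	3D	243220047	G	G	G	G	G	T	T	T	G	G	G	G	G	G
20	0.57143	A/T	3D	325280760	A	A	A	A	A	A	A	A	T	T	T	T	T	T
21	0.57143	G/C	4D	98966982	G	G	G	G	G	G	G	G	C	C	C	C	C	C
22	0.57143	G/T	4D	106342034	G	G	G	G	G	G	G	G	T	T	T	T	T	T
23	0.57143	A/G	4D	106343975	A	A	A	A	A	A	A	A	G	G	G	G	G	G
24	0.78571	C/G	4D	359828556	C	C	C	C	C	G	G	G	C	C	C	C	C	C
25	0.57143	A/G	4D	411973293	A	A	A	A	A	A	A	A	G	G	G	G	G	G
26	0.78571	A/C	5D	95729416	A	A	A	A	A	C	C	C	A	A	A	A	A	A
27	0.78571	C/G	5D	95729417	C	C	C	C	C	G	G	G	C	C	C	C	C	C
28	0.78571	G/C	5D	283515563	G	G	G	G	G	C	C	C	G	G	G	G	G	G
29	0.57143	A/G	6D	404358451	A	A	A	A	A	A	A	A	G	G	G	G	G	G
30	0.78571	G/A	7D	198673099	G	G	G	G	G	A	A	A	G	G	G	G	G	G
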