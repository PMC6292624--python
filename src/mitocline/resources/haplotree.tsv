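# Example mtDNA haplogroup tree (PhyloTree-style nomenclature, rCRS coordinates).
# Covers the macro / haplogroup / sub-haplogroup labels observed in large Northern
# European cohorts. Defining variants are illustrative: positions are chosen to be
# globally unique so that tree-path haplotypes are well defined; well-known motifs
# (e.g. M 10400T/14783C/15043A, H 2706A/7028C, U 12308G) are used where they do not
# collide, synthetic placeholders elsewhere.
# Columns: name	parent	level	variants (comma-separated pos:derived_allele, "-" = none)
mt-MRCA	-	root	-
L0	mt-MRCA	macro	5442:C,9042:T
L1	mt-MRCA	macro	3666:A,7055:G
L2	mt-MRCA	macro	8206:A,13590:A
L3	mt-MRCA	macro	769:A,1018:A
L4	mt-MRCA	macro	5460:T,8790:T
L5	mt-MRCA	macro	7972:C,12950:G
L6	mt-MRCA	macro	9072:G,16048:A
M	mt-MRCA	macro	10400:T,14783:C,15043:A
N	mt-MRCA	macro	8701:G,9540:C,15301:A
R	mt-MRCA	macro	12705:C,16223:C
A	N	hg	663:G,1736:G
I	N	hg	10034:C,16129:A
N1-5	N	hg	10238:C
N2	N	hg	1719:A
W	N	hg	11947:G,15884:C
X	N	hg	6371:T,14470:C
Y	N	hg	7933:C,8392:A
C	M	hg	3552:A,9545:G
D4	M	hg	4883:T,8414:T
D5	M	hg	1107:C
D6	M	hg	5301:G
E	M	hg	3027:C,13626:A
G	M	hg	4833:G,8200:C
M1	M	hg	6446:A,6680:C
M2	M	hg	1780:C,8502:T
M3	M	hg	482:C
M30	M	hg	12007:A
M4	M	hg	6620:C
M5	M	hg	1888:A
M6	M	hg	3537:G
M7	M	hg	9824:C
M8a	M	hg	6179:A
M9	M	hg	3394:C
Z	M	hg	6752:G,9090:C
H	R	hg	2706:A,7028:C
V	R	hg	4580:A,15904:T
U	R	hg	12308:G
T	R	hg	4917:G,13368:A
J	R	hg	4216:C,13708:A
K	R	hg	1811:G,9055:A
F	R	hg	6392:C,10310:A
B	R	hg	827:G,16189:C
H1	H	subhg	3010:A
H2	H	subhg	1438:A,4769:A
H3	H	subhg	6776:C
H4	H	subhg	3992:T,5004:C
H5	H	subhg	456:T
J1	J	subhg	462:T,14798:C
J2	J	subhg	7476:T,15257:A
T1	T	subhg	12633:A
T2	T	subhg	11812:G,14233:G
K1	K	subhg	497:T,1189:C
K2	K	subhg	9716:C
K3	K	subhg	9093:G
U1	U	subhg	2218:T,7581:C
U2	U	subhg	16051:G
U3	U	subhg	150:T,14139:G
U4	U	subhg	4646:C,11332:T
U5a	U	subhg	3197:C,14793:G
U5b	U	subhg	7768:G,14182:C
U6	U	subhg	3348:G,16172:C
U7	U	subhg	8137:T,10142:T
U8	U	subhg	3480:G,9698:C
U9	U	subhg	3531:A,13020:C
A1	A	subhg	16362:C
A5	A	subhg	11641:G
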