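case_id	limb	laterality	surgeries	followup_months	postop_patella	postop_lameness	outcome	complications
1		unilateral	DFO;TTT;TPLO	2	in_situ	0	full
2		unilateral	DFO;FDO	2	in_situ	0	full
3		unilateral	DFO	2	in_situ	0	full
4		unilateral	Arthroscopic CP;TTT	2	in_situ	0	full
5		unilateral	Block trochleoplasty;TTT	7	in_situ	0	full
6		unilateral	Block trochleoplasty;TTT;revision:DFO;revision:FDO	23	LPL;revision:in_situ	1	acceptable	Patellar luxation;Delayed bone union
7		unilateral	DFO;TRP;TTT	13	in_situ	0	full
8		unilateral	DFO;FDO	5	in_situ	0	full
9		unilateral	Wedge trochleoplasty;TTT	6	in_situ	0	full	Periarticular fibrosis
10		unilateral	Wedge trochleoplasty;TTT	4	in_situ	0	full
11		unilateral	Arthroscopic CP;TTT	6	MPL	2	acceptable	Patellar luxation
12		unilateral	TRP;TTT	9	in_situ	0	full
13		unilateral	DFO;FDO;TDO	2	in_situ	0	full
14		unilateral	DFO;Wedge trochleoplasty;TTT	13	in_situ	1	acceptable	Kirschner wire migration
15	R	bilateral	DFO;TRP;TDO	2	in_situ	0	full
15	L	bilateral	DFO;TRP;TDO	2	in_situ	0	full
16		unilateral	DFO;TTT;Block trochleoplasty	10	in_situ	1	acceptable	Seroma;Screw fracture
17		unilateral	TRP;TTT	2	in_situ	0	full
18		unilateral	Block trochleoplasty;TTT	2	in_situ	0	full
19		unilateral	DFO;FDO;Wedge trochleoplasty;TTT	2	in_situ	0	full
20	R	bilateral	Wedge trochleoplasty;TTT;revision:DFO;revision:FDO	2	MPL	1	acceptable	Patellar luxation
20	L	bilateral	DFO;FDO	2	in_situ	0	full
21		unilateral	DFO;FDO	2	in_situ	0	full
22	R	bilateral	DFO;FDO;TRP	2	in_situ	0	full
22	L	bilateral	DFO;FDO;TRP	2	in_situ	0	full
23		unilateral	DFO;FDO;TDO	2	in_situ	0	full
24		unilateral	DFO;TDO	12	in_situ	0	full
25		unilateral	Block trochleoplasty;TTT	2	MPL	2	unacceptable	Patellar luxation
26		unilateral	DFO;FDO;TDO	2	in_situ	0	full
27		unilateral	Block trochleoplasty;FDO;TPLO	3	in_situ	1	acceptable	Delayed bone union
28		unilateral	DFO;TTT	2	in_situ	0	full
29		unilateral	FDO;PGR;TPLO	2	in_situ	0	full	Kirschner wire migration
30	R	bilateral	Block trochleoplasty;TDO	6	in_situ	0	full
30	L	bilateral	Block trochleoplasty;TDO	3	in_situ	0	full
31		unilateral	DFO;TPLO	2	in_situ	0	full
32		unilateral	DFO;FDO;TDO	2	in_situ	0	acceptable	Seroma
33		unilateral	FDO;TTT	4	in_situ	0	full
34		unilateral	Block trochleoplasty;DFO;FDO;TDO	3	in_situ	0	acceptable	Patellar tendon tendinitis
35		unilateral	DFO;Block trochleoplasty	2	MPL	4	unacceptable	Patellar luxation
36		unilateral	Block trochleoplasty;FDO;PTO	4	in_situ	0	full	Kirschner wire migration
37		unilateral	DFO;PTO	2	in_situ	0	full
38	R	bilateral	Wedge trochleoplasty;TDO	2	in_situ	0	full
38	L	bilateral	TDO
39		unilateral	Block trochleoplasty;DFO;FDO;TDO		in_situ	1	acceptable
40	R	bilateral	TTT		in_situ	0	full	Incisional seroma
40	L	bilateral	TTT
41		unilateral	Arthroscopic CP		in_situ	0	full
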