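event_id	abbreviation	A.f.	G.f.	S.i.	N.h.	P.f.	N.i.	P.h.
1	[A1/A2]	2	1	1	1	1	1	1
2	[Md]	2	1	1	1	1	3	1
3	[Mx1]	7	3	7	3	2	3	2
4	[Mx2]	7	4	7	3	2	3	2
5	[T1]	6	4	7	3	2	3	2
6	[P6]	n.a.	7	11	7	6	5	5
7	[FS]	n.a.	5	10	4	4	3	4
8	[st]	1	4	7	2	2	5	6
9	[a1-m]	2	5	3	4	9	9	11
10	[a1-l]	2	10	3	9	9	9	11
11	[a2-m]	2	7	4	2	9	7	8
12	[a2-l]	2	4	2	4	2	7	8
13	[md-m]	2	5	4	2	2	5	8
14	[md-l]	2	4	3	2	2	6	9
15	[mx1-m]	7	8	9	5	7	6	8
16	[mx1-l]	7	10	9	5	2	7	9
17	[lmp-mx1]	7	7	8	5	3	6	-
18	[mx2-m]	9	10	9	5	7	6	8
19	[mx2-l]	8	5	9	5	5	7	8
20	[lmp-mx2]	-	5	8	4	3	4	-
21	[t1-m]	7	10	9	5	7	7	8
22	[t1-l]	7	10	9	5	7	7	8
23	[lmp-t1]	7	4	8	4	3	4	6
24	[lmp-p6]	n.a.	7	10	5	5	6	9
25	[lmp-post]	-	4	8	4	3	-	-
26	[NGA]	2	2	3	2	2	4	3
27	[mx1-g]	7	5	8	4	3	5	3
28	[mx2-g]	7	5	8	4	3	5	3
29	[t1-g]	7	6	9	4	4	6	3
30	[p6-g]	n.a.	9	10	6	6	8	7
31	[NEA]	3	2	5	3	-	-	-
32	[PPN]	5	2	5	2	2	-	-
33	[HAT]	4	10	6	8	8	2	10
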