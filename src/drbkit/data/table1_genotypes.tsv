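# status: Gugu-DRB*01=functional,Gugu-DRB*02=functional,Gugu-DRB*03=functional,Gugu-DRB*04=functional,Gugu-DRB*05=functional,Gugu-DRB*06=functional,Gugu-DRB*07=functional,Gugu-DRB*08=functional,Gugu-DRB*09=functional,Gugu-DRB*10=functional,Gugu-DRB*11=functional,Gugu-DRB*PS01=pseudogene,Gugu-DRB*PS02=pseudogene,Gugu-DRB*PS03=pseudogene
individual_id	subpop	Gugu-DRB*01	Gugu-DRB*02	Gugu-DRB*03	Gugu-DRB*04	Gugu-DRB*05	Gugu-DRB*06	Gugu-DRB*07	Gugu-DRB*08	Gugu-DRB*09	Gugu-DRB*10	Gugu-DRB*11	Gugu-DRB*PS01	Gugu-DRB*PS02	Gugu-DRB*PS03
1	east	0	1	1	0	0	1	0	1	1	0	0	1	0	0
2	east	1	1	1	0	0	0	1	0	0	0	0	1	0	0
3	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
4	east	1	1	1	0	0	0	0	0	0	0	0	1	0	1
5	east	1	1	1	1	0	0	0	0	0	0	0	1	0	0
6	east	1	1	1	1	0	0	0	0	0	0	0	1	1	0
7	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
8	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
9	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
10	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
11	east	1	1	1	0	0	0	0	0	0	1	0	1	0	1
12	east	0	1	1	0	0	0	0	0	0	0	0	1	0	0
21	east	0	1	1	0	0	0	0	0	0	0	0	1	0	0
22	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
23	east	0	1	1	0	0	0	0	0	0	0	0	1	0	0
24	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
29	east	1	1	1	0	0	0	0	0	0	0	0	1	0	0
30	east	0	1	1	0	0	0	0	0	0	0	0	1	0	0
32	east	0	1	1	0	0	0	0	0	0	0	0	1	0	0
13	north	1	0	0	0	0	0	0	0	0	0	0	1	0	0
14	north	1	0	0	0	0	0	0	0	0	0	0	1	0	0
15	north	1	0	0	1	0	0	0	0	0	0	0	1	0	0
16	admixed	1	0	0	0	0	0	0	0	0	0	0	1	0	0
17	north	1	1	1	0	0	1	0	0	0	0	1	1	0	0
18	north	1	1	1	0	0	0	0	0	0	0	0	1	0	0
19	north	1	0	0	0	0	0	0	0	0	0	0	1	0	0
20	north	1	1	1	0	0	0	0	0	0	0	0	1	0	0
25	north	1	0	0	0	0	0	0	0	0	0	0	1	0	0
26	admixed	1	0	0	0	0	0	0	0	0	0	0	1	0	0
27	north	1	0	0	0	1	0	0	0	0	0	0	1	0	0
28	north	1	0	0	0	1	0	0	0	0	0	0	1	0	0
31	north	1	1	1	0	0	0	0	0	0	0	0	1	0	0
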