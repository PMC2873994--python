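locus	HLA-B
reference	NC_000006.10 C31432914-31429628

[primers]
B224F01	GCTCCCACTCCATGAGGTATTTC	forward	202-224
B225F01	GCTCCCACTCCATGAGGTATTTC[C]	forward	202-225
B225F02	GCTCCCACTCCATGAGGTATTTC[G]	forward	202-225
B225F03	GCTCCCACTCCATGAGGTATTTC[T]	forward	202-225
B231F01	CCCCACTCCATGAAGTATTTCNACACC[G]	forward	204-231
B234F01	CCACTCCATGAAGTATTTCNACACCNCC[A]	forward	206-234
B270F01	GGAGCCCCGCTTCATC[A]	forward	254-270
B270F02	GGAGCCCCGCTTCATC[G]	forward	254-270
B270F03	GGAGCCCCGCTTCATCT	forward	254-270
B270F04	GGAGCCCCGCTTCATC[T]	forward	254-270
B350R01	GCCCCTCCTGCTCTATCCAT	reverse	350-369
B350R02	GCCCCTCCTGCTCTATCCA[C]	reverse	350-369
B408R01	GGCTCTCTCGGTMAGTCTGTGTGT[T]	reverse	408-432
B429F01	TCTCTCGGTMAGTCTGTGCCT[G]	forward	408-429
B429F02	TCTCTCGGTMAGTCTGTGCGGA	forward	408-429
B445R01	CGCTCTGGTTGTAGTAGCCGC	reverse	445-465
B445R02	CGCTCTGGTTGTAGTAGCCG[C]	reverse	445-465
B445R03	CCTCYCTCTGGTTGTAGTAGCCSGM	reverse	445-445
B445R04	CCTCTCTCTGGTTGTAGTAGCGGA	reverse	445-468
B734F01	CAGGGTCTCACATCATCCAG[A]	forward	714-734
B734F02	GGGTCTCACATCATCCAG[T]	forward	716-734
B734F03	CAGGGTCTCACATCATCCAG[T]	forward	714-734
B751F01	CAGANSATGTAYGGCTGCGAC	forward	731-751
B752F01	CAGANSATGTAYGGCTGCGACC	forward	731-752
B752F02	CAGANSATGTAYGGCTGCGAC[C]	forward	731-752
B752F03	CAGANSATGTAYGGCTGCGAC[G]	forward	731-752
B785F01	CCTCCTCCACGGGCAT[A]	forward	769-785
B785F02	CCTCCTCCACGGGCAT[G]	forward	769-785
B792F01	CGCGGGCATAACCAGT[A]	forward	776-792
B792F02	CGGGCATGACCAGT[C]	forward	778-792
B792F03	GCGGGCATGACCAGT[C]	forward	777-792
B793F01	CGGGCATGACCAGGA[C]	forward	778-793
B793F02	CGCGGGCATGACCAGTA[C]	forward	776-793
B793F03	GCGGGCATGACCAGTTA	forward	777-793
B793F04	GCGGGCATGACCAGTT[A]	forward	777-793
B793F05	CGCGGGTATAACCAGTT[C]	forward	776-793
B859R01	GGTGATCTGAGCCGCG	reverse	859-874
B859R02	GGTGATCTGAGCCGCC	reverse	859-874
B859R03	GGTGATCTGAGCCGC[C]	reverse	859-874
B860R01	CTGGGTGATCTGAGCCGC	reverse	860-877
B879R01	GCCGCCTCCMACTTGC	reverse	879-894
B879R02	GCCGCCTCCMACTTG[C]	reverse	879-894
B879R03	GGCCGCCTCCMACTTGA	reverse	879-895
B911R01	CCTCCAGGTAGGTAGGCTCTCCG	reverse	911-933
B911R02	CCTCCAGGTAGGTAGGCTCTCAG	reverse	911-933
B911R03	CCTCCAGGTAGGTAGGCTCTCA[G]	reverse	911-933
B911R04	CCTCCAGGTAGGTAGGCTCTGTC	reverse	911-933
B932R01	GAGCAACTCCACGCACGT	reverse	932-949
B932R02	GAGCAACTCCACGCACAG	reverse	932-949
B932R03	GAGCAACTCCACGCACA[G]	reverse	932-949

[probes]
B320P01	FAM	BHQ1	CWGTACGTGAGGTTCGACAGCGACGCC	294-320
B805P01	TET	BHQ1	CAAGGATTACATCGCCCTGAACGAGGACCTG	805-835

[reactions]
HLA-B 001	B225F01	B350R01	B320P01	B751F01	B860R01	B805P01	B*4101,B*4501,B*4901
HLA-B 002	B225F01	B408R01	B320P01	B751F01	B860R01	B805P01	B*1801,B*4101,B*4501,B*4901
HLA-B 003	B225F02	B350R02	B320P01	B751F01	B860R01	B805P01	B*0801
HLA-B 004	B225F03	B429F01	B320P01	B751F01	B860R01	B805P01	B*0702,B*4201,B*8101
HLA-B 005	B231F01	B429F02	B320P01	B751F01	B860R01	B805P01	B*1516,B*5701,B*5703,B*5801,B*5802
HLA-B 006	B231F01	B445R02	B320P01	B751F01	B860R01	B805P01	B*0801,B*1402,B*1503,B*1510,B*3501,B*4101,B*4501
HLA-B 007	B231F01	B445R04	B320P01	B751F01	B860R01	B805P01	B*1302,B*1516,B*4403,B*4901,B*5101,B*5301,B*5701,B*5703,B*5801,B*5802
HLA-B 008	B234F01	B445R02	B320P01	B751F01	B860R01	B805P01	B*0801,B*1503,B*1510,B*3501,B*4101,B*4501
HLA-B 009	B270F01	B408R01	B320P01	B751F01	B860R01	B805P01	B*1302,B*4101,B*4403,B*4501,B*4901
HLA-B 010	B270F01	B445R01	B320P01	B751F01	B860R01	B805P01	B*4101,B*4501
HLA-B 011	B270F01	B445R04	B320P01	B751F01	B860R01	B805P01	B*1302,B*2703,B*4403,B*4901
HLA-B 012	B270F02	B350R01	B320P01	B751F01	B860R01	B805P01	B*1516,B*3501,B*5301,B*5701,B*5703,B*5801,B*5802
HLA-B 013	B270F02	B408R01	B320P01	B751F01	B860R01	B805P01	B*3501,B*5301
HLA-B 014	B270F02	B445R02	B320P01	B751F01	B860R01	B805P01	B*3501
HLA-B 015	B270F03	B429F01	B320P01	B751F01	B860R01	B805P01	B*0702,B*4201,B*4202,B*8101
HLA-B 016	B270F03	B445R02	B320P01	B751F01	B860R01	B805P01	B*0702,B*0801,B*1402,B*1503,B*1510,B*1801,B*4201,B*4202,B*8101
HLA-B 017	B270F04	B445R04	B320P01	B751F01	B860R01	B805P01	B*5101
HLA-B 018	B734F01	B859R01	B805P01	B224F01	B445R03	B320P01	B*0801,B*1801,B*3501,B*4201,B*4202,B*4403,B*5301,B*5801
HLA-B 019	B734F02	B932R02	B805P01	B224F01	B445R03	B320P01	B*5802
HLA-B 020	B734F03	B911R02	B805P01	B224F01	B445R03	B320P01	B*1402,B*5802
HLA-B 021	B752F01	B879R02	B805P01	B224F01	B445R03	B320P01	B*1516,B*3501,B*4501,B*4901,B*5301,B*5801,B*5802
HLA-B 022	B752F02	B859R01	B805P01	B224F01	B445R03	B320P01	B*1302,B*3501,B*4501,B*4901,B*5301,B*5801,B*5802
HLA-B 023	B752F02	B911R04	B805P01	B224F01	B445R03	B320P01	B*4501
HLA-B 024	B752F03	B859R02	B805P01	B224F01	B445R03	B320P01	B*0702,B*1503,B*1510,B*2703,B*5701,B*5703,B*8101
HLA-B 025	B752F03	B879R01	B805P01	B224F01	B445R03	B320P01	B*0702,B*0801,B*1402,B*1503,B*1510,B*1801,B*2703,B*4101,B*4201,B*4202,B*4403,B*5101,B*5701,B*5703,B*8101
HLA-B 026	B752F03	B932R03	B805P01	B224F01	B445R03	B320P01	B*1503,B*1510,B*4403,B*5101,B*5701,B*5703
HLA-B 027	B785F01	B879R01	B805P01	B224F01	B445R03	B320P01	B*0801,B*4101,B*4201,B*4202,B*5101,B*5703,B*8101
HLA-B 028	B785F01	B911R02	B805P01	B224F01	B445R03	B320P01	B*1302,B*5101,B*5703,B*8101
HLA-B 029	B785F01	B932R03	B805P01	B224F01	B445R03	B320P01	B*5101,B*5703
HLA-B 030	B785F02	B879R01	B805P01	B224F01	B445R03	B320P01	B*0702,B*1503,B*1510,B*1516,B*1801,B*3501,B*5301,B*5701,B*5801,B*5802
HLA-B 031	B785F02	B911R02	B805P01	B224F01	B445R03	B320P01	B*1503,B*1510,B*1516,B*1801,B*3501,B*5301,B*5701,B*5801,B*5802
HLA-B 032	B785F02	B932R03	B805P01	B224F01	B445R03	B320P01	B*1503,B*1510,B*1516,B*3501,B*5301,B*5701,B*5801,B*5802
HLA-B 033	B793F01	B859R01	B805P01	B224F01	B445R03	B320P01	B*4403
HLA-B 034	B793F01	B879R02	B805P01	B224F01	B445R03	B320P01	B*2703,B*4403
HLA-B 035	B793F01	B911R03	B805P01	B224F01	B445R03	B320P01	B*2703,B*4403
HLA-B 036	B792F01	B911R02	B805P01	B224F01	B445R03	B320P01	B*1510,B*5101,B*5703,B*8101
HLA-B 037	B792F01	B911R04	B805P01	B224F01	B445R03	B320P01	B*0801,B*4101,B*4201,B*4202
HLA-B 038	B792F01	B932R02	B805P01	B224F01	B445R03	B320P01	B*1510,B*5101,B*5703
HLA-B 039	B793F02	B911R01	B805P01	B224F01	B445R03	B320P01	B*0702
HLA-B 040	B792F02	B911R02	B805P01	B224F01	B445R03	B320P01	B*1503,B*1516,B*1801,B*3501,B*5301,B*5701,B*5801,B*5802
HLA-B 041	B792F02	B932R02	B805P01	B224F01	B445R03	B320P01	B*1503,B*1516,B*3501,B*5301,B*5701,B*5801,B*5802
HLA-B 042	B792F03	B859R02	B805P01	B224F01	B445R03	B320P01	B*1503,B*1516,B*5701
HLA-B 043	B793F03	B879R03	B805P01	B224F01	B445R03	B320P01	B*1302
HLA-B 044	B793F04	B911R02	B805P01	B224F01	B445R03	B320P01	B*1302,B*4901
HLA-B 045	B793F05	B932R01	B805P01	B224F01	B445R03	B320P01	B*1402
HLA-B 046	B752F02	B859R03	B805P01	B224F01	B445R03	B320P01	B*1516
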