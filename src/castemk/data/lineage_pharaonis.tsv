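rank	name	taxon_ids
1	cellular organisms	131567
2	Eukaryota	2759
3	Opisthokonta	33154
4	Metazoa	33208
5	Eumetazoa	6072
6	Bilateria	33213
7	Protostomia	33317
8	Ecdysozoa	1206794
9	Arthropoda	6656
10	Hexapoda	6960
11	Insecta	50557
12	Pterygota	7496
13	Neoptera	33340
14	Holometabola	33392
15	Hymenoptera	7399
16	Apocrita	7400
17	Aculeata	7434
18	Formicidae	36668
19	Monomorium pharaonis	307658
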