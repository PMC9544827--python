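# Packaged example dataset: component p-values for the 22 circulating
# metabolites (out of 149 candidates) that pass the adaptive screen in a
# case-control mediation screen of fish intake on colorectal adenoma risk.
# pmin/pmax are the row-wise min/max of the two component p-values; min_ind
# says whether the minimum belongs to the exposure-side test (1) or the
# outcome-side test (2). Rows are sorted by increasing pmin; 1-based ids.
id	name	pmin	pmax	min_ind
1	2-hydroxybutyrate (AHB)	1.2e-06	1.5e-02	2
2	docosahexaenoate (DHA; 22:6n3)	1.9e-06	8.3e-03	1
3	3-hydroxybutyrate (BHBA)	7.8e-06	2.2e-01	2
4	oleate (18:1n9)	2.5e-05	7.3e-01	2
5	glycerol	3.9e-05	8.4e-01	2
6	eicosenoate (20:1n9 or 11)	5.9e-05	4.1e-01	2
7	dihomo-linoleate (20:2n6)	9.0e-05	2.6e-01	2
8	10-nonadecenoate (19:1n9)	9.4e-05	5.4e-01	2
9	creatine	1.7e-04	9.2e-01	1
10	palmitoleate (16:1n7)	1.7e-04	6.3e-01	2
11	10-heptadecenoate (17:1n7)	2.8e-04	7.1e-01	2
12	myristoleate (14:1n5)	2.9e-04	8.2e-01	2
13	docosapentaenoate (n3 DPA; 22:5n3)	3.0e-04	2.9e-01	2
14	methyl palmitate (15 or 2)	5.4e-04	1.8e-01	2
15	N-acetyl-beta-alanine	5.9e-04	1.3e-01	1
16	linoleate (18:2n6)	8.8e-04	6.7e-01	2
17	3-methyl-2-oxobutyrate	8.9e-04	2.0e-01	2
18	palmitate (16:0)	9.9e-04	5.6e-01	2
19	fumarate	1.4e-03	5.0e-01	2
20	2-aminobutyrate	1.4e-03	8.3e-03	2
21	linolenate [alpha or gamma; (18:3n3 or 6)]	1.6e-03	5.4e-01	2
22	10-undecenoate (11:1n1)	1.8e-03	3.2e-01	2
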