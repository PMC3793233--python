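name	peptide	multiplicity	n_hydroxyl_sulfoxyl
DBAD1	STEARATTLTACDAY	49	7
DBAD5	LFHRSCPSYDTYSCL	1	8
DBAD4	HIGPSRYSSAFHCLS	1	6
DBAD10	SSCCSIHHRDCF	1	6
DBAD7	GSMFILTGFTGTVSH	1	5
DBAD19	DHCFRIPNLPTYRSC	1	5
DBAD8	QVHPRGSYHRAPSIC	1	4
DBAD11	ASRTALRCVQHRVRT	1	4
DBAD14	NGATICKAHPSALVT	1	4
DBAD16	KYRPCYPRLKPFIHT	1	4
DBAD6	SNIAPIPRNHFIHTS	1	3
DBAD12	PQALNSYSAIFAAIN	1	3
DBAD15	VNVSYAWFVHGSRRM	1	3
DBAD18	STVQAFGPGCVAQHL	1	3
DBAD20	SGHHCDKEIGARLLH	1	2
DBAD21	VSPPGPHLRGALPIG	1	1
DBAD24	LPRIPGNLFTILQPM	1	1
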