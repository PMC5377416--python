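ERBB4	ppi	RAC1
IQGAP1	ppi	RAC1
NRAS	ppi	RAC1
PARK2	ppi	RAC1
PTGS2	ppi	RAC1
RAC1	ppi	RACGAP1
RAC1	ppi	ROBO1
RAC1	ppi	SMAD4
RAC1	ppi	TRAF6
RAC1	ppi	YES1
ELAVL1	ppi	NRAS
ERBB4	ppi	NRAS
NOTCH2	ppi	NRAS
NRAS	ppi	PTGS2
NRAS	ppi	RACGAP1
NRAS	ppi	SMAD4
NRAS	ppi	YES1
ERBB4	ppi	TRAF6
IL17A	ppi	TRAF6
IRAK1	ppi	TRAF6
OTUD7B	ppi	TRAF6
PARK2	ppi	TRAF6
SORT1	ppi	TRAF6
ERBB4	ppi	NOTCH2
ERBB4	ppi	PTGS2
HEYL	ppi	NOTCH2
NOTCH2	ppi	PTGS2
NOTCH2	ppi	SMAD4
ELAVL1	ppi	PTGS2
ELAVL1	ppi	NOVA1
ELAVL1	ppi	PARK2
PARK2	ppi	SMAD4
PTPRE	ppi	YES1
RACGAP1	ppi	YES1
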