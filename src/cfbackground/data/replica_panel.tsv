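gene	contig	start	end
ABL1	ABL1	20	127
ABL1	ABL1	147	254
ABL1	ABL1	274	381
ABL1	ABL1	401	508
AKT1	AKT1	20	127
AKT1	AKT1	147	254
ALK	ALK	20	127
ALK	ALK	147	254
ALK	ALK	274	381
APC	APC	20	127
APC	APC	147	254
APC	APC	274	381
APC	APC	401	508
ATM	ATM	20	127
ATM	ATM	147	254
ATM	ATM	274	381
BRAF	BRAF	20	127
BRAF	BRAF	147	254
BRAF	BRAF	274	381
BRAF	BRAF	401	508
CDH1	CDH1	20	127
CDH1	CDH1	147	254
CDH1	CDH1	274	381
CDH1	CDH1	401	508
CDH1	CDH1	528	635
CDH1	CDH1	655	762
CDKN2A	CDKN2A	20	127
CDKN2A	CDKN2A	147	254
CDKN2A	CDKN2A	274	381
CSF1R	CSF1R	20	127
CSF1R	CSF1R	147	254
CSF1R	CSF1R	274	381
CSF1R	CSF1R	401	508
CTNNB1	CTNNB1	20	127
CTNNB1	CTNNB1	147	254
EGFR	EGFR	20	127
EGFR	EGFR	147	254
EGFR	EGFR	274	381
ERBB2	ERBB2	20	127
ERBB2	ERBB2	147	254
ERBB2	ERBB2	274	381
ERBB2	ERBB2	401	508
ERBB4	ERBB4	20	127
ERBB4	ERBB4	147	254
ERBB4	ERBB4	274	381
ERBB4	ERBB4	401	508
ERBB4	ERBB4	528	635
ERBB4	ERBB4	655	762
ERBB4	ERBB4	782	889
EZH2	EZH2	20	127
EZH2	EZH2	147	254
EZH2	EZH2	274	381
EZH2	EZH2	401	508
FBXW7	FBXW7	20	127
FBXW7	FBXW7	147	254
FBXW7	FBXW7	274	381
FBXW7	FBXW7	401	508
FBXW7	FBXW7	528	635
FBXW7	FBXW7	655	762
FBXW7	FBXW7	782	889
FBXW7	FBXW7	909	1016
FGFR1	FGFR1	20	127
FGFR1	FGFR1	147	254
FGFR1	FGFR1	274	381
FGFR1	FGFR1	401	508
FGFR1	FGFR1	528	635
FGFR2	FGFR2	20	127
FGFR2	FGFR2	147	254
FGFR2	FGFR2	274	381
FGFR2	FGFR2	401	508
FGFR2	FGFR2	528	635
FGFR3	FGFR3	20	127
FGFR3	FGFR3	147	254
FGFR3	FGFR3	274	381
FGFR3	FGFR3	401	508
FGFR3	FGFR3	528	635
FGFR3	FGFR3	655	762
FLT3	FLT3	20	127
FLT3	FLT3	147	254
FLT3	FLT3	274	381
GNA11	GNA11	20	127
GNAQ	GNAQ	20	127
GNAQ	GNAQ	147	254
GNAQ	GNAQ	274	381
GNAQ	GNAQ	401	508
GNAQ	GNAQ	528	634
GNAQ	GNAQ	654	760
GNAS	GNAS	20	126
GNAS	GNAS	146	252
GNAS	GNAS	272	378
GNAS	GNAS	398	504
GNAS	GNAS	524	630
HNF1A	HNF1A	20	126
HNF1A	HNF1A	146	252
HNF1A	HNF1A	272	378
HNF1A	HNF1A	398	504
HRAS	HRAS	20	126
HRAS	HRAS	146	252
HRAS	HRAS	272	378
HRAS	HRAS	398	504
HRAS	HRAS	524	630
HRAS	HRAS	650	756
HRAS	HRAS	776	882
HRAS	HRAS	902	1008
IDH1	IDH1	20	126
IDH1	IDH1	146	252
IDH1	IDH1	272	378
IDH1	IDH1	398	504
IDH1	IDH1	524	630
IDH1	IDH1	650	756
IDH2	IDH2	20	126
IDH2	IDH2	146	252
IDH2	IDH2	272	378
JAK2	JAK2	20	126
JAK2	JAK2	146	252
JAK2	JAK2	272	378
JAK2	JAK2	398	504
JAK3	JAK3	20	126
JAK3	JAK3	146	252
JAK3	JAK3	272	378
JAK3	JAK3	398	504
JAK3	JAK3	524	630
JAK3	JAK3	650	756
KDR	KDR	20	126
KDR	KDR	146	252
KIT	KIT	20	126
KIT	KIT	146	252
KRAS	KRAS	20	126
KRAS	KRAS	146	252
KRAS	KRAS	272	378
KRAS	KRAS	398	504
MET	MET	20	126
MET	MET	146	252
MET	MET	272	378
MLH1	MLH1	20	126
MLH1	MLH1	146	252
MLH1	MLH1	272	378
MPL	MPL	20	126
MPL	MPL	146	252
MPL	MPL	272	378
MPL	MPL	398	504
MPL	MPL	524	630
NOTCH1	NOTCH1	20	126
NOTCH1	NOTCH1	146	252
NOTCH1	NOTCH1	272	378
NOTCH1	NOTCH1	398	504
NPM1	NPM1	20	126
NRAS	NRAS	20	126
NRAS	NRAS	146	252
NRAS	NRAS	272	378
NRAS	NRAS	398	504
NRAS	NRAS	524	630
PDGFRA	PDGFRA	20	126
PDGFRA	PDGFRA	146	252
PDGFRA	PDGFRA	272	378
PDGFRA	PDGFRA	398	504
PDGFRA	PDGFRA	524	630
PIK3CA	PIK3CA	20	126
PTEN	PTEN	20	126
PTEN	PTEN	146	252
PTEN	PTEN	272	378
PTEN	PTEN	398	504
PTPN11	PTPN11	20	126
PTPN11	PTPN11	146	252
PTPN11	PTPN11	272	378
PTPN11	PTPN11	398	504
PTPN11	PTPN11	524	630
RB1	RB1	20	126
RB1	RB1	146	252
RB1	RB1	272	378
RB1	RB1	398	504
RB1	RB1	524	630
RB1	RB1	650	756
RB1	RB1	776	882
RET	RET	20	126
RET	RET	146	252
RET	RET	272	378
RET	RET	398	504
SMAD4	SMAD4	20	126
SMAD4	SMAD4	146	252
SMAD4	SMAD4	272	378
SMARCB1	SMARCB1	20	126
SMARCB1	SMARCB1	146	252
SMARCB1	SMARCB1	272	378
SMARCB1	SMARCB1	398	504
SMO	SMO	20	126
SMO	SMO	146	252
SMO	SMO	272	378
SMO	SMO	398	504
SMO	SMO	524	630
SRC	SRC	20	126
SRC	SRC	146	252
SRC	SRC	272	378
SRC	SRC	398	504
STK11	STK11	20	126
STK11	STK11	146	252
STK11	STK11	272	378
TP53	TP53	20	126
TP53	TP53	146	252
TP53	TP53	272	378
TP53	TP53	398	504
TP53	TP53	524	630
TP53	TP53	650	756
TP53	TP53	776	882
VHL	VHL	20	126
VHL	VHL	146	252
VHL	VHL	272	378
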