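gene	pathway	pathway_class
EGFR	RTK/RAS	oncogenic
KRAS	RTK/RAS	oncogenic
IRS1	RTK/RAS	oncogenic
RASAL2	RTK/RAS	oncogenic
RRAD	RTK/RAS	oncogenic
SHKBP1	RTK/RAS	oncogenic
TP53	p53	oncogenic
MDM2	p53	oncogenic
CDKN1A	Cell Cycle	oncogenic
RB1	Cell Cycle	oncogenic
RBL1	Cell Cycle	oncogenic
NUMA1	Cell Cycle	oncogenic
ZNF143	Cell Cycle	oncogenic
ORC1	Cell Cycle	oncogenic
LZTR1	Wnt	oncogenic
LEF1	Wnt	oncogenic
FZD10	Wnt	oncogenic
BPTF	Wnt	oncogenic
NOTCH1	Notch	oncogenic
NOTCH2	Notch	oncogenic
FAT1	Hippo	oncogenic
TAOK1	Hippo	oncogenic
KEAP1	NRF2	oncogenic
PIK3CA	PI3K	oncogenic
ELP3	PI3K	oncogenic
SMAD4	TGF-beta	oncogenic
MYC	Myc	oncogenic
MSH6	Mismatch Repair	ddr
MLH1	Mismatch Repair	ddr
NTHL1	Base Excision Repair	ddr
POLH	Translesion Synthesis	ddr
POLR2A	Nucleotide Excision Repair	ddr
XAB2	Nucleotide Excision Repair	ddr
ATR	Damage Sensing	ddr
ATRIP	Damage Sensing	ddr
APTX	Single Strand Break Repair	ddr
FANCM	Fanconi Anemia	ddr
BRCA1	Homologous Recombination	ddr
BRCA2	Homologous Recombination	ddr
PRKDC	Nonhomologous End Joining	ddr
PER1	Damage Sensing	ddr
PPP4R4	Damage Sensing	ddr
MGMT	Direct Repair	ddr
RRM1	Nucleotide Pool Maintenance	ddr
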