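gene	annotation
PON1	Paraoxonase 1; increases Nanog expression, stem-cell related feature in genome-RNAi screens
ORC1	Origin recognition complex subunit 1; cell cycle regulator, cancer stem cell feature related in lung adenocarcinoma
SHKBP1	Regulates EGFR activity through TGF-beta signaling; associated with stem-cell-like erlotinib resistance
NUMA1	Nuclear mitotic apparatus protein 1; mitosis regulator with roles in stem cell division asymmetry
ZNF143	Transcriptional regulator of replication and cell cycle genes; reported stem-cell maintenance roles
MUC16	Mucin 16 (CA125); apoptosis and migration regulator
PELP1	Proline, glutamate and leucine rich protein 1; estrogen receptor coregulator with stem cell expansion roles
BPTF	Bromodomain PHD finger transcription factor; chromatin remodeling in embryonic stem cells
ELP3	Elongator acetyltransferase complex subunit 3; translation and chromatin regulation
LEF1	Lymphoid enhancer binding factor 1; Wnt effector active in stem cell programs
RRAD	Ras-related glycolysis inhibitor and calcium channel regulator
CSMD3	CUB and Sushi multiple domains 3; dendrite development regulator
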