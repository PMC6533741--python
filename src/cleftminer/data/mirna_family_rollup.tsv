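# Published rollup: candidate genes targeted by at least two known miRNA
# families among the significant miRNAs.  families is comma-joined, sorted.
gene	n_families	families
EN2	6	miR-154,miR-203,miR-27,miR-368,miR-374,miR-497
YOD1	5	miR-1271,miR-154,miR-374,miR-497,miR-550
FZD6	5	miR-1271,miR-154,miR-374,miR-497,miR-550
HECTD1	5	miR-154,miR-203,miR-374,miR-497,miR-503
GREM1	4	miR-124,miR-154,miR-203,miR-27
HOXB3	4	miR-124,miR-154,miR-27,miR-374
PAX6	4	miR-154,miR-203,miR-368,miR-374
RAD51	4	miR-124,miR-1271,miR-374,miR-550
CHD7	4	miR-154,miR-27,miR-374,miR-497
EYA1	4	miR-154,miR-27,miR-374,miR-497
RUNX2	4	miR-124,miR-203,miR-374,miR-497
FGF1	4	miR-124,miR-154,miR-27,miR-497
FGFR1	4	miR-124,miR-368,miR-497,miR-503
GABRB3	3	miR-124,miR-154,miR-27
FGFR2	3	miR-154,miR-374,miR-497
JARID2	3	miR-374,miR-497,miR-503
CRISPLD2	3	miR-154,miR-368,miR-497
FOXP2	3	miR-154,miR-27,miR-497
TANC2	3	miR-124,miR-154,miR-368
DVL2	3	miR-124,miR-154,miR-27
DCAF7	3	miR-1271,miR-27,miR-550
BCL2	3	miR-154,miR-497,miR-503
SATB2	3	miR-154,miR-27,miR-497
FGF2	3	miR-368,miR-497,miR-503
SMAD2	3	miR-203,miR-27,miR-503
DMD	2	miR-154,miR-374
WNT5A	2	miR-154,miR-374
NOG	2	miR-154,miR-374
NTN1	2	miR-154,miR-374
FOXG1	2	miR-368,miR-374
RHPN2	2	miR-374,miR-497
WNT5B	2	miR-124,miR-374
JAG2	2	miR-124,miR-154
FOXF2	2	miR-124,miR-154
PDGFC	2	miR-124,miR-154
CBS	2	miR-1271,miR-550
BAG4	2	miR-154,miR-497
MAFB	2	miR-154,miR-503
PAX7	2	miR-27,miR-497
WNT3A	2	miR-497,miR-503
TFAP2A	2	miR-497,miR-503
TPM1	2	miR-124,miR-497
GCH1	2	miR-124,miR-27
KIF2A	2	miR-124,miR-203
MYH9	2	miR-124,miR-368
TP63	2	miR-124,miR-203
PAX3	2	miR-27,miR-368
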