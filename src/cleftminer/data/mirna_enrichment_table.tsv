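# Published per-miRNA enrichment table: significant miRNAs (FDR < 0.1), their
# seed-family ids, the candidate genes in each miRNA's target set, and the
# printed BH-adjusted value.  Family "NA" marks a miRNA without a known family.
family	mirna	fdr	genes
miR-154	hsa-miR-369-3p	0.03	CHD7,DMD,EYA1,GABRB3,GREM1,HOXB3,NOG,PAX6,TIMP2,TULP4,BAG4,FZD6,YOD1
miR-154	hsa-miR-655-3p	0.03	BCL2,DMD,EN2,GREM1,HOXB3,MAFB,MID1,NTN1,PAX6,SATB2,TULP4,CYP1A1,FZD6,YOD1
miR-374	hsa-miR-374a-5p	0.07	CHD7,DMD,EYA1,FGFR2,FOXG1,HECTD1,HOXB3,JARID2,MSX1,NOG,NTN1,PAX6,RAD51,RHPN2,RUNX2,TGFA,TNS1,WNT5A,WNT5B,YOD1,EN2,FZD6
miR-374	hsa-miR-374b-5p	0.07	CHD7,DMD,EYA1,FGFR2,FOXG1,HECTD1,HOXB3,JARID2,MSX1,NOG,NTN1,PAX6,RAD51,RHPN2,RUNX2,TGFA,TNS1,WNT5A,WNT5B,YOD1,EN2,FZD6
miR-497	hsa-miR-497-5p	0.07	AXIN2,BAG4,BCL2,CHD7,CRISPLD2,EN2,EYA1,FGF1,FGF2,FGFR1,FGFR2,FOXP2,FZD6,HECTD1,JARID2,PAX7,RHPN2,SATB2,SLC6A4,WNT3A,YOD1,MTHFR,RUNX2,TFAP2A,TPM1
miR-124	hsa-miR-124-3p	0.09	GABRB3,GCH1,JAG2,KIF2A,MTR,MYH9,ROR2,RYK,TANC2,ARHGAP29,COL4A4,DVL2,EFNB1,FGF1,FGFR1,FOXF2,GREM1,HOXB3,KIF7,PDGFC,PEMT,PKP1,RAD51,RUNX2,SOX9,TBX22,TP63,TPM1,WNT5B
miR-1271	hsa-miR-1271-3p	0.09	CBS,DCAF7,FZD6,RAD51,YOD1
miR-203	hsa-miR-203a-3p	0.09	E2F1,EN2,GREM1,HECTD1,KIF2A,PAX6,RUNX2,SMAD2,TP63
miR-27	hsa-miR-27b-3p	0.09	BCL3,CHD7,COL21A1,DVL2,EN2,EYA1,FGF1,FOXP2,GABRB3,GCH1,GREM1,HOXB3,PAX9,RARA,SATB2,SMAD1,STK32B,SMAD2,DCAF7,PAX3,PAX7,SEC16A,WNT9B
miR-154	hsa-miR-300	0.09	CR1,DVL2,FGF1,FGFR2,FOXF2,FOXP2,GABRB3,GAD1,HECTD1,JAG2,MID1,PDGFC,TANC2,TGFB3,WNT5A,CRISPLD2,GREM1,PHF8
NA	hsa-miR-3678-3p	0.09	E2F1,GABRB3,JARID2,SLC6A4,YOD1
miR-368	hsa-miR-376b-3p	0.09	CRISPLD2,EN2,FGFR1,MYH9,PAX3,PAX6,PRSS35,TANC2,FGF2,FOXG1
miR-154	hsa-miR-381-3p	0.09	CR1,DVL2,FGF1,FGFR2,FOXF2,FOXP2,GABRB3,GAD1,HECTD1,JAG2,MID1,PDGFC,TANC2,TGFB3,WNT5A,CRISPLD2,GREM1,PHF8
miR-503	hsa-miR-503-5p	0.09	HECTD1,JARID2,MAFB,WNT3A,BCL2,DHFR,FGF2,FGFR1,SMAD2,TFAP2A
miR-550	hsa-miR-550a-3-5p	0.09	CBS,DCAF7,FZD6,RAD51,YOD1
miR-550	hsa-miR-550a-5p	0.09	CBS,DCAF7,FZD6,RAD51,YOD1
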