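# miRNA -> seed-family assignment for the packaged enrichment table.
# "NA" marks a miRNA with no known family.
mirna	family
hsa-miR-369-3p	miR-154
hsa-miR-655-3p	miR-154
hsa-miR-300	miR-154
hsa-miR-381-3p	miR-154
hsa-miR-374a-5p	miR-374
hsa-miR-374b-5p	miR-374
hsa-miR-497-5p	miR-497
hsa-miR-124-3p	miR-124
hsa-miR-1271-3p	miR-1271
hsa-miR-203a-3p	miR-203
hsa-miR-27b-3p	miR-27
hsa-miR-3678-3p	NA
hsa-miR-376b-3p	miR-368
hsa-miR-503-5p	miR-503
hsa-miR-550a-3-5p	miR-550
hsa-miR-550a-5p	miR-550
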