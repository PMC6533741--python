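{
  "catalog_file": "clp_gene_catalog.tsv",
  "n_genes": 172,
  "description": "Curated human CL/P candidate-gene catalog from a systematic literature review; distinct gene symbols after normalization."
}
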