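# Maps canonical column names (left) to the column names used in a source
# extraction file (right).  Canonical names absent here are assumed to appear
# verbatim.  Use with:  pstfst ingest theirs.csv --schema-map this.yaml --out canonical.csv
paper_id: Paper
phenotype_id: Phenotype
pst: PST
fst_neutral: Neutral_FST
fst_nonneutral: NonNeutral_FST
n_loci_nonneutral: N_loci_selected
n_loci_total: N_loci_examined
mean_n_individuals: Mean_N
common_garden: Common_garden
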