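# pgxkit diplotype-to-phenotype rules
# schema_version=1
# guideline_version=DPWG-2020.1
# Explicit star-pair rules override the generic activity-score translation
# ("*" matches any allele of the gene). Alleles within a pair are unordered.
gene	allele_a	allele_b	phenotype
VKORC1	*2	*2	high_sensitivity
VKORC1	*	*	normal_sensitivity
F5	Leiden	Leiden	carrier
F5	Leiden	*	carrier
F5	*	*	non_carrier
HCP5	rs2395029	rs2395029	carrier
HCP5	rs2395029	*	carrier
HCP5	*	*	non_carrier
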