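# pgxkit CYP2D6 star-allele counts, in-house WGS cohort (547 genomes, Aldy calls)
# schema_version=1
# total_alleles=1094
# Only the most frequently detected alleles are tabulated; the remaining
# alleles of the 1094 are rarer labels not listed here.
allele	count	function_class
*1	351	normal
*2	187	normal
*41	93	decreased
*10	25	decreased
*4	123	no_function
*68+*4	71	no_function
*5	30	no_function
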