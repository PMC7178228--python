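# pgxkit CYP2D6 caller-comparison fixture: 21 publicly characterized
# reference samples with their GeT-RM 2019 consensus genotypes and the
# diplotypes reported by Astrolabe v0.8.6.1, Aldy v2.2.3 and Stargazer
# v1.0.7, including footnote annotations.
# schema_version=1
# Annotation tokens (semicolon-separated):
#   hybrid:<caller>=<*label>   caller additionally detected a hybrid allele,
#                              appended to that caller's allele multiset
#   dup_unassigned:<caller>    caller flagged a possible duplication without
#                              assigning it to an allele (contributes nothing)
#   alt=<*a>|<*b>              manually confirmed alternate allele pair,
#                              treated as equivalent for every caller
#   note:<caller>=<text>       informational only
sample	consensus	astrolabe	aldy	stargazer	annotations
HG00436	*2x2/*71	*2/*71	*2x2/*71	*1/*83+*2
NA07029	*1/*35	*1/*35	*1/*35	*1/*35
NA18959	*2/*36+*10	*2/*10	*2/*36+*10	*2/*36+*10
NA19109	*2x2/*29	*2/*29	*2x2/*29	*29/*83+*2
NA21781	*2x2/*68+*4	*2/*4	*2x2/*68+*4	*4N+*4/*68+*4	dup_unassigned:astrolabe
NA12878	*3/(*68)+*4	*3/*4	*3/*68+*4	*3/*4	hybrid:astrolabe=*68
NA12873	*1/*5	*1/*5	*5/*61	*1/*5	note:aldy=no_major_solution_phased
NA18861	*5/*29	*5/*29	*5/*29	*13C/*29
HG00589	*1/*21	*1/*2	*1/*21	*1/*2
NA19917	*1/*40	*1/*40	*1/*40	*1/*40
NA07019	*1/*4	*1/*4	*1/*4	*1/*4
NA12717	*1/*1	*1/*1	*1/*1	*1/*1
HG00276	*4/*5	*4/*4	*4/*5	*4/*5
NA18524	*1/*36x2+*10	*1/*10	*1+*36/*36+*10	*1/*10x3
NA18540	(*36+)*10/*41	*41/*10	*36+*10/*61+*69	*10x2/*41x2	hybrid:astrolabe=*68
NA12892	*2/*3	*2/*3	*2/*3	*2/*3
NA07348	*1/*6	*1/*6	*1/*6	*1/*6
NA18519	*1/*29	*1/*29	*106/*29	*106/*29	alt=*1|*106
NA18966	*1/*2	*1/*2	*1/*2	*1/*2
NA18992	*1/*5	*1/*5	*1/*5	*1/*13C
NA19226	*2/*2x2	*2/*2	*2/*2x2	*2/*83+*2	dup_unassigned:astrolabe
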