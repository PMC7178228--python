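# pgxkit combined VKORC1/CYP2C9 coumarin starting-dose table
# schema_version=1
# guideline_version=DPWG-2020.1
# dose_fraction is the phenprocoumon/warfarin starting dose as a percentage
# of the standard starting dose for VKORC1 *1/*1 + CYP2C9 *1/*1 individuals.
# Only combinations with an established fraction carry one; all other
# resolved combinations receive gene-level action text without a number.
vkorc1_diplotype	cyp2c9_diplotype	dose_fraction	action_text
*1/*1	*1/*1	100	Standard starting dose.
*2/*2	*2/*2	35	Reduce phenprocoumon/warfarin starting dose to ~35% of standard; intensify INR monitoring.
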