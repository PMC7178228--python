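# pgxkit

Pharmacogenetic (PGx) profiling from whole-genome sequencing variant calls.

Clinical WGS pipelines built for rare-disease diagnostics already sequence
every pharmacogene; `pgxkit` turns that by-product into pre-emptive
pharmacogenetic information. From a (gVCF-like) VCF it calls star-allele
diplotypes for the 11 pharmacogenes with Dutch Pharmacogenetics Working Group
(DPWG) dosing guidelines, translates them into metabolizer phenotypes and
drug recommendations, and emits a per-patient report plus a compact
machine-readable Medication Safety Card payload. At cohort level it
aggregates the pharmacogene allele-frequency landscape, and it ships a
concordance scorer for CYP2D6 diplotype callers evaluated against GeT-RM
consensus genotypes. It is aimed at bioinformaticians running clinical WGS
pipelines and at anyone studying how much of pharmacogene variation the
established panel variants capture.

## What it computes

**Star-allele calling.** The bundled panel holds 45 SNV/indel definitions in
*CYP2B6, CYP2C9, CYP2C19, CYP2D6, CYP3A5, DPYD, F5, SLCO1B1, TPMT, UGT1A1,
VKORC1*, plus the HLA-B\*57:01 tag variant HCP5 rs2395029 and CYP2D6
structural-variant slots (\*5 deletion, xN duplication, hybrid alleles), with
left-aligned coordinates on GRCh37 and GRCh38. Each alternate allele at a
panel site contributes its star allele; remaining haplotypes are filled with
\*1 — but only where a genotype (including explicit homozygous-reference
evidence) exists. A missing genotype yields an unknown allele, never a silent
wildtype.

**Beyond the panel.** Retained sites are classified by a strict cascade —
panel match ≻ loss-of-function (nonsense, frameshift, canonical ±1–2 bp
splice SNVs predicted splice-altering) ≻ missense called damaging by all six
of FATHMM, FATHMM-MKL, MutationAssessor, MutationTaster, Polyphen2 and SIFT —
and split into *known* (ClinVar drug response / HGMD FP, DFP, DM?, DM /
PharmGKB) versus *novel*. Individuals carrying a panel variant and a novel
LOF/missense variant in the same gene are flagged: unphased, such an allele
can overturn a panel-only phenotype (e.g. a novel splice allele behind an
ultrarapid-metabolizer call).

**Landscape statistics.** Per gene, relative allele frequencies with the
wildtype count inferred as AN − Σ AC under the assumption that variants in
one gene occur in *trans*; minor-allele-frequency bins (MAF < 0.1%,
0.1%–5%, > 5%); and 95% confidence intervals from the continuity-corrected
Wilson score interval

```
low, high = (2np̂ + z² ∓ 1 ∓ z·sqrt(z² ∓ 2 − 1/n + 4p̂(nq̂ ± 1))) / (2(n + z²))
```

clipped to [0, 1] (low = 0 at x = 0, high = 1 at x = n).

**CYP2D6 concordance.** A parser for the diplotype grammar
`*2x2/*71`, `*68+*4/*5`, `(*36+)*10/*41` (copy counts, tandem hybrids,
annotated consensus segments) and a phase-insensitive scorer: a call is
correct when its expanded allele multiset equals the consensus multiset,
honouring accepted alternate alleles (\*1 ↔ \*106) and footnote annotations
(separately detected hybrids count; unassigned duplications do not).

**Synthetic cohorts.** A seeded generator emulating the study conditions:
Hardy–Weinberg genotypes at the panel sites (default preset ≈ 6 actionable
panel alleles per genome, 547 genomes), ten rare novel LOF/missense
singletons, and planted scenario individuals (a CYP2C19 \*17 + \*2 +
novel-splice carrier; five VKORC1\*2/CYP2C9\*2 double homozygotes). Its truth
tables are the oracle for the end-to-end tests.

## Worked example

Score the bundled 21-sample CYP2D6 caller comparison:

```
$ pgxkit --quiet score
astrolabe: 12/21 correct
aldy: 19/21 correct
stargazer: 11/21 correct
  ERR HG00436      astrolabe  *2/*71             vs *2x2/*71
  OK  HG00436      aldy       *2x2/*71           vs *2x2/*71
  ...
```

Aldy's 19/21 is the count of samples whose allele multiset matches the
GeT-RM 2019 consensus; the two misses are an unphased solution and a complex
hybrid arrangement. Simulate a cohort and profile it:

```
$ pgxkit simulate --seed 1 --out-dir sim/
$ pgxkit profile --vcf sim/cohort.vcf --annotations sim/annotations.tsv --out-dir profiles/
```

`profiles/S0001/report.txt` (S0001 is a planted VKORC1\*2/CYP2C9\*2 double
homozygote):

```
PGx report — sample S0001
panel DPWG-2020.1, guidelines DPWG-2020.1

gene      diplotype             phenotype         flags
CYP2B6    *1/*6                 IM                -
CYP2C19   *1/*1                 NM                -
CYP2C9    *2/*2                 IM                -
...
VKORC1    *2/*2                 high_sensitivity  -

Coumarin starting dose (VKORC1 x CYP2C9): 35% of standard starting dose
  Reduce phenprocoumon/warfarin starting dose to ~35% of standard; intensify INR monitoring.
```

The 35% figure is the combined-genotype starting dose for phenprocoumon or
warfarin relative to a VKORC1\*1/\*1 + CYP2C9\*1/\*1 individual.
`profiles/S0001/msc.json` is the Medication Safety Card payload: the
gene → phenotype mapping, guideline versions and a stable `profile_id`
digest suitable for QR encoding.

## Scope

`pgxkit` consumes variant calls and annotations; it does not align reads,
call variants, run the six missense predictors, execute CYP2D6 SV callers
(their output is consumed via `--sv-table` and the concordance fixture), or
lift coordinates between builds. HLA typing is limited to the single tag
variant. See `docs/methods.md` for the model, parameter and design details.
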