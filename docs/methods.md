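# Methods

## Panel model

The unit of genotyping is a *panel variant*: one genomic change (SNV or
indel) with a star-allele or named-variant label, a gene, a function class
(`no_function`, `decreased`, `normal`, `increased`, `unknown`) and
coordinates on both GRCh37 and GRCh38. The bundle holds 45 SNV/indel
definitions in 11 DPWG pharmacogenes, the HCP5 rs2395029 tag for
HLA-B\*57:01, and opaque CYP2D6 structural-variant slots. The DPWG guidance
itself does not enumerate its panel in one table; the bundle was assembled
from the variants named across the DPWG/PREPARE materials (all CYP2C19,
CYP2C9, VKORC1, CYP3A5, UGT1A1, CYP2B6 and CYP2D6 alleles with established
dosing guidance) and padded to the canonical 45 with the remaining
widely-genotyped DPWG alleles (DPYD, TPMT, SLCO1B1, F5). Coordinates beyond
the anchors validated in the tests are best-effort transcriptions of the
public allele definitions; the panel is a versioned, user-editable TSV
precisely so a deployment can swap in its own validated coordinates without
code changes.

Two deliberate representation choices:

* **CYP2B6 \*6/\*9 share the c.516G>T site.** \*9 is the single-site allele
  and \*6 the common two-site haplotype; without phase, single-site evidence
  is reported under the primary label (\*6, the first entry in panel order),
  while lookups can enumerate all labels at a site. One site is never counted
  twice in the landscape.
* **UGT1A1 \*28/\*37 are overlapping TA-repeat promoter duplications.** Both
  are stored left-aligned and matched only after indel normalization
  (suffix-then-prefix trimming to the minimal representation), so a padded
  VCF representation still hits the right allele. Full repeat-aware
  left-alignment would need the reference sequence; trimming is sufficient
  because panel entries and all VCF input pass through the same
  normalization.

## Diplotype → phenotype

Genes with their own vocabulary get explicit star-pair rules: VKORC1
(\*2/\*2 → `high_sensitivity`, else `normal_sensitivity`), F5 (any Leiden
allele → `carrier`), the HLA tag (carrier/non-carrier). Every other gene uses
an activity score — one haplotype contributes 0 (`no_function`), 0.5
(`decreased`), 1 (`normal`), 1.5 (`increased`) — mapped as 0 → PM,
(0, 2) → IM, 2 → NM, (2, 3) → RM, ≥ 3 → UM. This reproduces the DPWG anchor
translations (\*2/\*2 poor, \*17/\*17 ultrarapid, \*2/\*17 intermediate for
CYP2C19) and is total over the four known function classes; `unknown` on
either haplotype yields phenotype `unknown` rather than a guess. The rule
table is a TSV the user can extend.

CYP3A5 is translated with the same convention, so the homozygous wildtype
(\*1/\*1, a CYP3A5 expresser) is phenotype NM and receives no dose
adjustment; the bundled tacrolimus recommendation fires for IM/RM/UM. This
keeps "all-wildtype ⇒ no action" uniform across genes at the cost of not
prompting a tacrolimus dose increase for the rare \*1/\*1 expresser — a
known limitation of the normal-equals-reference convention, noted here
deliberately.

Recommendations are (gene, phenotypes, drug, action) rows — 77 individual
drugs plus the oral-contraceptives group entry. Numeric dose fractions live
only in the combined VKORC1 × CYP2C9 coumarin table (100% reference, 35%
for the \*2/\*2 + \*2/\*2 double homozygote); other resolved combinations
get action text without a number, and guidance is withheld whenever either
diplotype is unresolved.

## Variant I/O and filters

VCF input is decomposed to biallelic records with left-aligned indels;
gVCF-like homozygous-reference rows are first-class records (ac = 0 with
explicit genotypes), because distinguishing \*1 from no-call is what makes
"never impute wildtype" enforceable. Haploid genotypes are rejected — all
panel genes are handled diploid. Cohort mode derives AC/AN from genotypes;
sites mode mirrors INFO AC/AN and any AC_*pop*/AN_*pop* pairs.

The high-confidence site filter retains PASS records with 150-mer
mappability ≥ 1.0 (both configurable); every exclusion carries a
machine-readable reason (`non_pass`, `low_mappability`). A record lacking a
mappability annotation is treated as fully mappable with a warning rather
than silently dropped: population-scale inputs always carry the score, and
erring toward retention keeps the filter auditable.

## Classification cascade

Precedence is panel > LOF > consensus-damaging missense > other, one category
per record. A panel variant that is also loss-of-function (e.g. the CYP2D6
frameshifts) stays `dpwg` — panel semantics dominate. LOF means premature
termination (nonsense or frameshift, regardless of expected
nonsense-mediated decay) or a canonical ±1–2 bp splice-site SNV predicted to
alter splicing; when no splice prediction is present, a canonical splice SNV
defaults to altering, with a warning, while an explicit negative verdict
wins. Consensus-damaging missense requires all six predictor verdicts
present and damaging — a missing verdict never counts. Novelty (`known`
versus `novel`) is membership in ClinVar drug-response, HGMD (FP/DFP/DM?/DM
in drug-response context, pre-filtered upstream into one column) or
PharmGKB; adding a database flag can change novelty but never category.
LOF/missense calls in HLA-B are forced to `other` — short-read alignment in
that locus is too ambiguous to trust them — which is also why HLA-B\*57:01
is handled through the HCP5 tag, with an explicit European-ancestry caveat
and no imputation of non-carrier status from missing data.

## Landscape statistics

Wildtype alleles are inferred as AN − Σ AC per gene under the *trans*
assumption. Because co-occurring variants on one haplotype are invisible
without phase, this underestimates \*1; a negative inferred count is floored
at zero and flagged (`wildtype_overflow`) instead of raising. MAF is
min(AC, AN−AC)/AN — necessary because majority alternate alleles (CYP3A5\*3)
would otherwise land in a frequency bin meant for minor alleles. Bins are
[0, 0.1%) / [0.1%, 5%] / (5%, 50%]: the published three-way split uses
strict inequalities on all rows, leaving the two boundary points formally
unassigned; both are placed in the middle bin, a deterministic choice that
is immaterial at cohort scale (a boundary case requires AC·1000 = AN
exactly).

Confidence intervals use the continuity-corrected Wilson score interval
(Newcombe's method 4) with the closed-form bounds, clipped to [0, 1] and
exact at the x = 0 and x = n boundaries. The tests check it against an
independent implementation (the score equation solved at p̂ ∓ 1/2n) to 1e-6
and verify ≥ 93% empirical coverage at the 95% level over 2,000 binomial
simulations per true proportion — the interval is conservative by
construction.

Cohort summaries tabulate detected variants (AC > 0) by group — panel
variants, known LOF/missense, novel LOF/missense — and MAF bin, with allele
sums and within-group percentages; `dpwg_fraction` reports the share of
detected alleles carrying a panel label, per gene and overall. In tandem
labels such as \*68+\*4 one haplotype is one allele (the tandem is a single
allele label), noted in output metadata.

## Per-sample profiling

Star alleles are assigned under the *trans* assumption. Two different
heterozygous alleles in one gene produce an unphased two-allele diplotype
with `ambiguous_phase`; statistical phasing is deliberately out of scope, so
the flag is never cleared by inference. More than two alleles triggers the
conservative tie-break — keep the two highest-impact alleles, ranked
no_function > decreased > increased > normal — plus
`possible_misclassification`, mirroring the clinical concern that the
discarded allele could change the phenotype. CYP2D6 diplotypes come from the
external SV call table when provided (a double whole-gene deletion
contradicting detected SNV alleles is flagged `sv_conflict`); otherwise the
SNV-derived diplotype carries `sv_unknown`.

The co-occurrence screen notes every gene in which one individual carries
two or more relevant variant alleles, listing the variant identities; the
combination of a panel variant with a novel LOF/missense variant marks the
gene call `possible_misclassification`.

The Medication Safety Card payload is canonical JSON (sorted keys) holding
the gene → phenotype map, bundle versions, flags and a SHA-256-derived
`profile_id`; no timestamp enters the digest, so identical inputs give
byte-identical payloads.

## Synthetic data

The generator draws genotypes per variant under Hardy–Weinberg at the
configured frequency, independently across variants; linkage disequilibrium,
haplotype blocks and read-level noise are explicitly not modelled, so
passing tests demonstrate correctness of the calling/aggregation logic, not
robustness to calling errors or LD structure in real data. Randomness is
keyed `(seed, site index)` so extending the panel never perturbs existing
draws, and a fixed seed reproduces the VCF byte-for-byte.

Defaults are the study conditions the package targets: 547 genomes; a
European-ancestry-like frequency preset chosen so the expected actionable
panel-allele count per genome Σ2fᵢ ≈ 6 (illustrative, not population truth);
ten novel LOF/missense singletons (each het in one carrier, MAF ≈ 0.09%);
and planted scenario individuals — one CYP2C19 \*17 + \*2 + novel-splice
carrier and five VKORC1\*2/CYP2C9\*2 double homozygotes. VKORC1\*2 is set to
f = 0.45 so homozygotes are common, as observed in European-ancestry
cohorts. A plant at a zero-frequency site or referencing an undeclared novel
variant is an explicit error; novel variants must stay at or below the 0.1%
frequency ceiling. Sites-only generation draws AC ~ Binomial(AN, f) and can
inject non-PASS and low-mappability decoys to exercise the filter cascade.

Problem sizes in the tests follow the same conditions: the recovery suites
run one 500-genome and one 547-genome cohort, coverage checks use 2,000
binomial draws per proportion, and the concordance oracle comparison uses
1,000 random diplotype pairs.

## CYP2D6 concordance scoring

Calls are compared to consensus genotypes by expanded allele multiset —
phase- and arrangement-insensitive, with ×N expanding to N copies. Design
decisions, all recorded because the printed notation underdetermines them:

* **Parenthesized consensus segments are required, not optional.** Under the
  required interpretation the packaged 21-sample matrix reproduces the
  published per-caller totals (a bare `*3/*4` call scores incorrect against
  `*3/(*68)+*4`, while the same call with a separately reported hybrid \*68
  scores correct). Common GeT-RM usage reads parentheses as uncertainty;
  the parser retains the annotation so either convention can be displayed.
* **Suballele granularity is preserved** (\*13C ≠ \*1, \*4N is an opaque
  label distinct from \*4): collapsing to core alleles would flip verdicts
  the published comparison marks incorrect.
* **Footnote annotations are data**, encoded in the fixture: hybrid alleles
  a caller detected outside its diplotype string are appended to that
  caller's multiset; "possible duplication" flags without an allele
  assignment contribute nothing; the one manually confirmed alternate pair
  (\*1 ↔ \*106) is applied symmetrically to call and consensus; a caller's
  unphased potential-allele output is scored as an ordinary (incorrect)
  call.

## Known limitations

* Wildtype inference underestimates \*1 whenever variants co-occur in cis.
* The activity-score translation is a declared convention, not a per-gene
  DPWG table; deployments should review the TSVs (especially CYP3A5, see
  above) before clinical use.
* Panel coordinates outside the test-anchored entries are best-effort; the
  bundle is data, not ground truth.
* No statistical phasing, no LD in the generator, no read-level simulation;
  hemizygous and mosaic genotypes are rejected rather than modelled.
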