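"""Per-individual PGx profiling.

From gVCF-like genotypes at the panel sites, each sample receives a star
allele multiset per gene: every alternate allele at a panel site contributes
its star allele, the remaining haplotypes are filled with *1, and a missing
genotype at a panel site yields an unknown allele — never a silent wildtype.
Because short-read genotypes are unphased, two different heterozygous alleles
in one gene are reported in trans with an ``ambiguous_phase`` flag, and more
than two alleles are truncated to the two highest-impact ones (no function >
decreased > increased > normal), a conservative tie-break that keeps the
caution flag rather than the optimistic call.

The per-gene diplotypes are translated to metabolizer phenotypes and DPWG
drug recommendations; genes carrying both a panel variant and a rare/novel
LOF or consensus-damaging missense variant in the same individual are flagged
(`co-occurrence`), since an unphased novel loss-of-function allele can
invalidate the panel-only phenotype (an increased-function diplotype most of
all). The combined VKORC1/CYP2C9 coumarin starting-dose lookup and the
HLA-B*57:01 tag report round out the profile, which is rendered as a
plain-text report plus a compact machine-readable Medication Safety Card
payload with a stable profile identifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from pgxkit.panel import (
    Panel, PanelVariant, PhenotypeRules, Recommendations, WILDTYPE, _data_path,
)
from pgxkit.variant_io import SiteRecord, merge_sv_calls
from pgxkit.classify import classify_variant

#: impact ranking used to keep the two highest-impact alleles per gene
IMPACT_ORDER = {"no_function": 0, "decreased": 1, "increased": 2, "normal": 3, "unknown": 4}

UNKNOWN_ALLELE = "*?"


@dataclass
class GeneCall:
    gene: str
    alleles: tuple[str, ...]          # star alleles incl. filled *1 / unknown *?
    diplotype: str
    phenotype: str
    flags: set[str] = field(default_factory=set)
    notes: list[str] = field(default_factory=list)


@dataclass
class DoseGuidance:
    dose_fraction: Optional[float]
    action_text: str
    withheld: bool = False


@dataclass
class PGxProfile:
    sample: str
    calls: dict[str, GeneCall]
    recommendations: list
    co_occurrence: list[dict]
    hla_tag: dict
    anticoagulant: Optional[DoseGuidance]
    panel_version: str
    guideline_version: str


# -- star-allele calling -------------------------------------------------------


def _genotype_at(records_by_key: dict, pv: PanelVariant, sample: str, build: str):
    rec = records_by_key.get(pv.key(build))
    if rec is None or rec.genotypes is None or sample not in rec.genotypes:
        return None
    gt = rec.genotypes[sample]
    if any(a is None for a in gt):
        return None
    return sum(gt)


def call_star_alleles(sample: str, records: Iterable[SiteRecord], panel: Panel,
                      build: str) -> dict[str, tuple[list[str], set[str]]]:
    """Per-gene star-allele multisets for one sample.

    Returns gene -> (alleles, flags). Alleles are the alternate star alleles
    observed (one entry per haplotype copy); a panel site with no usable
    genotype contributes an ``allele_unknown:<star>`` flag instead of being
    imputed as wildtype.
    """
    records_by_key = {r.key: r for r in records if r.alt is not None}
    out: dict[str, tuple[list[str], set[str]]] = {g: ([], set()) for g in panel.genes}
    for pv in panel.sites(build):
        if pv.variant_kind == "tag":
            continue
        alleles, flags = out[pv.gene]
        copies = _genotype_at(records_by_key, pv, sample, build)
        if copies is None:
            flags.add(f"allele_unknown:{pv.star_label}")
        else:
            alleles.extend([pv.star_label] * copies)
    return out


def assign_diplotype(gene: str, alleles: list[str], flags: set[str], panel: Panel) -> GeneCall:
    """Fold a star-allele multiset into a two-haplotype call under trans."""
    flags = set(flags)
    notes: list[str] = []
    alleles = sorted(alleles)
    if len(alleles) > 2:
        ranked = sorted(alleles, key=lambda a: IMPACT_ORDER[panel.function_class(gene, a)])
        kept, dropped = sorted(ranked[:2]), sorted(ranked[2:])
        flags.update({"ambiguous_phase", "possible_misclassification"})
        notes.append(f"{len(alleles)} alleles detected ({', '.join(alleles)}); "
                     f"kept two highest-impact ({', '.join(kept)}), dropped {', '.join(dropped)}")
        alleles = kept
    elif len(alleles) == 2 and alleles[0] != alleles[1]:
        flags.add("ambiguous_phase")
        notes.append("two heterozygous alleles assumed in trans (phase unknown)")
    missing = sorted(f.split(":", 1)[1] for f in flags if f.startswith("allele_unknown:"))
    if missing:
        notes.append(f"no genotype at panel site(s) {', '.join(missing)}; "
                     "allele unknown, not assumed wildtype")
    while len(alleles) < 2:
        alleles.append(UNKNOWN_ALLELE if missing else WILDTYPE)
    diplotype = "/".join(sorted(alleles))
    return GeneCall(gene=gene, alleles=tuple(sorted(alleles)), diplotype=diplotype,
                    phenotype="unknown", flags=flags, notes=notes)


# -- co-occurrence screening ---------------------------------------------------


def co_occurrence_screen(sample: str, records: Iterable[SiteRecord], panel: Panel,
                         build: str) -> list[dict]:
    """Notes for genes where one individual carries >= 2 relevant variants.

    Relevant variants are panel (DPWG) hits, LOF and consensus-damaging
    missense variants the sample actually carries. One note per gene lists
    every variant identity; a combination of a panel variant with a novel
    LOF/missense variant is additionally marked ``possible_misclassification``
    (the unphased novel allele may overturn the panel-only phenotype).
    """
    per_gene: dict[str, list[dict]] = {}
    for rec in records:
        if rec.alt is None or rec.genotypes is None or sample not in rec.genotypes:
            continue
        gt = rec.genotypes[sample]
        copies = sum(1 for a in gt if a == 1)
        if copies == 0:
            continue
        vc = classify_variant(rec, panel, build)
        if vc.category not in ("dpwg", "lof", "damaging_missense"):
            continue
        gene = rec.gene or (rec.annotations or {}).get("gene")
        if gene is None:
            continue
        per_gene.setdefault(gene, []).append({
            "variant": f"{rec.chrom}:{rec.pos}{rec.ref}>{rec.alt}",
            "category": vc.category, "novelty": vc.novelty, "copies": copies,
        })
    notes = []
    for gene, variants in sorted(per_gene.items()):
        if len(variants) < 2:
            continue
        has_dpwg = any(v["category"] == "dpwg" for v in variants)
        has_novel_lof = any(v["category"] in ("lof", "damaging_missense") and v["novelty"] == "novel"
                            for v in variants)
        notes.append({
            "sample": sample, "gene": gene, "variants": variants,
            "possible_misclassification": has_dpwg and has_novel_lof,
        })
    return notes


# -- anticoagulant dosing ------------------------------------------------------


def _load_dose_table(path: Optional[str | Path] = None) -> list[dict]:
    if path is None:
        path = _data_path("anticoagulant_doses.tsv")
    rows = []
    header = None
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#") or not raw.strip():
            continue
        fields = raw.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        row["dose_fraction"] = float(row["dose_fraction"]) if row.get("dose_fraction") else None
        rows.append(row)
    return rows


def _norm_diplotype(text: str) -> str:
    parts = sorted(p.strip() for p in text.split("/"))
    if len(parts) != 2:
        raise ValueError(f"not a diplotype: {text!r}")
    return "/".join(parts)


def anticoagulant_dose_lookup(vkorc1_diplotype: str, cyp2c9_diplotype: str,
                              table: Optional[list[dict]] = None) -> DoseGuidance:
    """Combined VKORC1/CYP2C9 phenprocoumon/warfarin starting-dose guidance.

    Returns the starting dose as a percentage of the standard dose where the
    bundled combination table defines one; other resolved combinations get
    gene-level action text without a number. Guidance is withheld when either
    diplotype is unresolved.
    """
    if UNKNOWN_ALLELE in vkorc1_diplotype or UNKNOWN_ALLELE in cyp2c9_diplotype \
            or "unknown" in (vkorc1_diplotype.lower(), cyp2c9_diplotype.lower()):
        return DoseGuidance(None, "Genotype unresolved; dose guidance withheld.", withheld=True)
    vk = _norm_diplotype(vkorc1_diplotype)
    c9 = _norm_diplotype(cyp2c9_diplotype)
    for row in table if table is not None else _load_dose_table():
        if _norm_diplotype(row["vkorc1_diplotype"]) == vk \
                and _norm_diplotype(row["cyp2c9_diplotype"]) == c9:
            return DoseGuidance(row["dose_fraction"], row["action_text"])
    return DoseGuidance(None, "No combined dose fraction established for "
                              f"VKORC1 {vk} + CYP2C9 {c9}; apply gene-level guidance "
                              "and intensify INR monitoring.")


# -- HLA tag -------------------------------------------------------------------

_HLA_CAVEAT = ("HCP5 rs2395029 tags HLA-B*57:01 in populations of European ancestry; "
               "carrier status should be confirmed by sequence-based HLA typing, and the "
               "tag is uninformative outside populations where the linkage holds.")


def hla_tag_report(tag_copies: Optional[int]) -> dict:
    """Abacavir-risk note from the genotype at the HCP5 tag site.

    ``tag_copies`` is the number of tag (alternate) alleles, or None for a
    no-call — which yields status ``unknown``, never ``non_carrier``.
    """
    if tag_copies is None:
        status = "unknown"
    elif tag_copies > 0:
        status = "carrier"
    else:
        status = "non_carrier"
    return {"marker": "HCP5 rs2395029 (HLA-B*57:01 tag)", "status": status,
            "caveat": _HLA_CAVEAT}


# -- profile assembly ----------------------------------------------------------


def build_profile(sample: str, records: list[SiteRecord], panel: Panel,
                  rules: Optional[PhenotypeRules] = None,
                  recommendations: Optional[Recommendations] = None,
                  sv_table: Optional[dict[str, str]] = None,
                  build: str = "GRCh37") -> PGxProfile:
    """Assemble the complete PGx profile of one sample.

    ``records`` are the sample-bearing (gVCF-like) site records; ``sv_table``
    optionally maps samples to externally called CYP2D6 SV diplotypes. Every
    panel gene appears exactly once in the result.
    """
    rules = rules or PhenotypeRules.load()
    recommendations = recommendations or Recommendations.load()
    star_calls = call_star_alleles(sample, records, panel, build)
    calls: dict[str, GeneCall] = {}
    for gene, (alleles, flags) in star_calls.items():
        calls[gene] = assign_diplotype(gene, alleles, flags, panel)

    # CYP2D6: SV-aware merge when an external call table is provided
    merged = merge_sv_calls({sample: list(star_calls["CYP2D6"][0])}, sv_table or {})[sample]
    cyp2d6 = calls["CYP2D6"]
    cyp2d6.flags |= merged.flags
    if "sv_unknown" not in merged.flags:
        cyp2d6.diplotype = merged.diplotype
        cyp2d6.notes.append(f"diplotype from external SV caller: {merged.diplotype}")

    co_notes = co_occurrence_screen(sample, records, panel, build)
    for note in co_notes:
        gene = note["gene"]
        if gene in calls:
            calls[gene].notes.append(
                "co-occurring variants: " + ", ".join(v["variant"] for v in note["variants"]))
            if note["possible_misclassification"]:
                calls[gene].flags.add("possible_misclassification")

    # phenotype translation (CYP2D6 SV diplotypes fall back to unknown labels)
    recs = []
    for gene, call in calls.items():
        pair = tuple(call.diplotype.split("/"))
        if len(pair) == 2:
            call.phenotype = rules.translate(panel, gene, pair)  # type: ignore[arg-type]
        for r in recommendations.lookup(gene, call.phenotype):
            recs.append(r)

    # HLA tag
    tag = panel.tag_variants[0] if panel.tag_variants else None
    tag_copies = None
    if tag is not None:
        by_key = {r.key: r for r in records if r.alt is not None}
        tag_copies = _genotype_at(by_key, tag, sample, build)
    hla = hla_tag_report(tag_copies)
    if hla["status"] == "carrier":
        recs.extend(recommendations.lookup(tag.gene, "carrier"))

    anticoagulant = None
    if "VKORC1" in calls and "CYP2C9" in calls:
        anticoagulant = anticoagulant_dose_lookup(calls["VKORC1"].diplotype,
                                                  calls["CYP2C9"].diplotype)

    return PGxProfile(sample=sample, calls=calls, recommendations=recs,
                      co_occurrence=co_notes, hla_tag=hla, anticoagulant=anticoagulant,
                      panel_version=panel.version, guideline_version=recommendations.version)


# -- report + Medication Safety Card ------------------------------------------


def msc_payload(profile: PGxProfile) -> dict:
    """Compact machine-readable card payload with a stable identifier.

    The identifier is a SHA-256 digest of the canonical gene-to-phenotype
    mapping plus versions, so identical inputs yield byte-identical payloads.
    """
    phenotypes = {gene: call.phenotype for gene, call in sorted(profile.calls.items())}
    body = {
        "sample": profile.sample,
        "panel_version": profile.panel_version,
        "guideline_version": profile.guideline_version,
        "phenotypes": phenotypes,
        "hla_b_5701_tag": profile.hla_tag["status"],
        "flags": {g: sorted(c.flags) for g, c in sorted(profile.calls.items()) if c.flags},
    }
    digest = hashlib.sha256(json.dumps(body, sort_keys=True).encode()).hexdigest()[:16]
    return {**body, "profile_id": digest}


def generate_report(profile: PGxProfile) -> tuple[str, dict]:
    """Human-readable PGx report plus the Medication Safety Card payload."""
    lines = [
        f"PGx report — sample {profile.sample}",
        f"panel {profile.panel_version}, guidelines {profile.guideline_version}",
        "",
        f"{'gene':<10}{'diplotype':<22}{'phenotype':<18}flags",
    ]
    for gene, call in sorted(profile.calls.items()):
        flags = ",".join(sorted(call.flags)) or "-"
        lines.append(f"{gene:<10}{call.diplotype:<22}{call.phenotype:<18}{flags}")
    lines.append("")
    lines.append(f"HLA-B*57:01 tag: {profile.hla_tag['status']}")
    lines.append(f"  {profile.hla_tag['caveat']}")
    if profile.anticoagulant is not None:
        g = profile.anticoagulant
        dose = f"{g.dose_fraction:.0f}% of standard starting dose" if g.dose_fraction is not None \
            else ("withheld" if g.withheld else "no combined fraction established")
        lines.append(f"Coumarin starting dose (VKORC1 x CYP2C9): {dose}")
        lines.append(f"  {g.action_text}")
    if profile.co_occurrence:
        lines.append("")
        lines.append("Co-occurring variants in the same gene:")
        for note in profile.co_occurrence:
            mark = " [possible misclassification]" if note["possible_misclassification"] else ""
            lines.append(f"  {note['gene']}: "
                         + ", ".join(v["variant"] for v in note["variants"]) + mark)
    actionable = [r for r in profile.recommendations if r.phenotypes]
    if actionable:
        lines.append("")
        lines.append("Drug recommendations:")
        for r in sorted(actionable, key=lambda r: (r.gene, r.drug)):
            lines.append(f"  {r.gene} / {r.drug}: {r.action_text}")
    else:
        lines.append("")
        lines.append("Drug recommendations: none — no dose adjustments indicated.")
    return "\n".join(lines) + "\n", msc_payload(profile)


def profile_cohort(records: list[SiteRecord], panel: Panel,
                   rules: Optional[PhenotypeRules] = None,
                   recommendations: Optional[Recommendations] = None,
                   sv_table: Optional[dict[str, str]] = None,
                   build: str = "GRCh37") -> list[PGxProfile]:
    """Profiles for every sample present in the records."""
    samples = sorted({s for r in records if r.genotypes for s in r.genotypes})
    rules = rules or PhenotypeRules.load()
    recommendations = recommendations or Recommendations.load()
    return [build_profile(s, records, panel, rules, recommendations, sv_table, build)
            for s in samples]
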