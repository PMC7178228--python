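"""Variant classification cascade.

Every retained site falls into exactly one category, with panel semantics
dominating:

1. ``dpwg`` — the site matches a bundled panel definition;
2. ``lof`` — premature termination (nonsense, frameshift — with or without
   expected nonsense-mediated decay) or a canonical splice-site SNV
   (intronic +/-1-2 bp) predicted to alter splicing;
3. ``damaging_missense`` — missense called damaging/deleterious by all six
   predictors (FATHMM, FATHMM-MKL, MutationAssessor, MutationTaster,
   Polyphen2, SIFT); a missing verdict never counts as damaging;
4. ``other`` — everything else.

Non-panel categories carry a novelty label: ``known`` when the variant is in
ClinVar (drug response), HGMD (FP/DFP/DM?/DM in a drug-response context) or
PharmGKB, ``novel`` otherwise. LOF/missense variants in HLA-B are forced to
``other`` because short-read alignment in that locus is too ambiguous to
trust such calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from pgxkit.panel import Panel
from pgxkit.variant_io import SiteRecord

CATEGORIES = ("dpwg", "lof", "damaging_missense", "other")
NOVELTIES = ("known", "novel", "n_a")

PTC_CONSEQUENCES = frozenset({"stop_gained", "frameshift_variant", "frameshift"})
SPLICE_CONSEQUENCES = frozenset({"splice_acceptor_variant", "splice_donor_variant"})
MISSENSE_CONSEQUENCES = frozenset({"missense_variant", "missense"})
PREDICTORS = ("fathmm", "fathmm_mkl", "mutation_assessor", "mutation_taster", "polyphen2", "sift")
DAMAGING_VERDICTS = frozenset({"d", "damaging", "deleterious"})
HGMD_DRUG_CLASSES = frozenset({"FP", "DFP", "DM?", "DM"})

HLA_GENES = frozenset({"HLA-B"})


@dataclass(frozen=True)
class VariantClass:
    category: str
    novelty: str
    reasons: tuple[str, ...] = ()


def _ann(record: SiteRecord, key: str):
    value = (record.annotations or {}).get(key)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return value


def _truthy(value) -> bool:
    if value is None:
        return False
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def is_lof(record: SiteRecord) -> tuple[bool, Optional[str]]:
    """Loss-of-function test with a machine-readable reason.

    True for premature termination codons (nonsense/frameshift) and for
    canonical splice-site SNVs predicted to alter splicing. A missing
    ``splice_pred`` verdict defaults to altering for canonical +/-1-2 bp
    SNVs (with a warning); an explicit negative verdict wins.
    """
    consequence = _ann(record, "consequence")
    if consequence is None:
        return False, "unannotated"
    consequence = str(consequence).strip().lower()
    if consequence in PTC_CONSEQUENCES:
        return True, "ptc"
    if consequence in SPLICE_CONSEQUENCES:
        is_snv = record.alt is not None and len(record.ref) == 1 and len(record.alt) == 1
        if not is_snv:
            return False, None
        splice_pred = _ann(record, "splice_pred")
        if splice_pred is None:
            warnings.warn(f"{record.chrom}:{record.pos} canonical splice SNV without a "
                          f"splice prediction; assumed splice-altering", stacklevel=2)
            return True, "canonical_splice"
        if _truthy(splice_pred):
            return True, "canonical_splice"
        return False, None
    return False, None


def is_consensus_damaging_missense(record: SiteRecord) -> bool:
    """True iff all six predictor verdicts call the missense damaging."""
    consequence = _ann(record, "consequence")
    if consequence is None or str(consequence).strip().lower() not in MISSENSE_CONSEQUENCES:
        return False
    verdicts = []
    for tool in PREDICTORS:
        v = _ann(record, tool)
        if v is None:
            return False
        verdicts.append(str(v).strip().lower() in DAMAGING_VERDICTS)
    return all(verdicts)


def is_known(record: SiteRecord) -> tuple[bool, tuple[str, ...]]:
    """Database membership: ClinVar drug-response, HGMD drug classes, PharmGKB."""
    reasons = []
    if _truthy(_ann(record, "clinvar_drug_response")):
        reasons.append("clinvar_drug_response")
    hgmd = _ann(record, "hgmd_class")
    if hgmd is not None and (str(hgmd).strip() in HGMD_DRUG_CLASSES or _truthy(hgmd)):
        reasons.append("hgmd")
    if _truthy(_ann(record, "pharmgkb")):
        reasons.append("pharmgkb")
    return bool(reasons), tuple(reasons)


def classify_variant(record: SiteRecord, panel: Panel, build: str) -> VariantClass:
    """Classify one retained site (precedence dpwg > lof > damaging missense)."""
    if record.alt is not None:
        hit = panel.lookup_variant(record.chrom, record.pos, record.ref, record.alt, build)
        if hit is not None:
            record.gene = record.gene or hit.gene
            return VariantClass("dpwg", "n_a", (f"panel:{hit.gene}{hit.star_label}",))
    gene = record.gene or _ann(record, "gene")
    known, db_reasons = is_known(record)
    novelty = "known" if known else "novel"
    if gene in HLA_GENES:
        lof, _ = is_lof(record)
        if lof or is_consensus_damaging_missense(record):
            return VariantClass("other", "n_a", ("hla_excluded",))
    else:
        lof, reason = is_lof(record)
        if lof:
            return VariantClass("lof", novelty, (reason or "lof",) + db_reasons)
        if reason == "unannotated":
            return VariantClass("other", "n_a", ("unannotated",))
        if is_consensus_damaging_missense(record):
            return VariantClass("damaging_missense", novelty, ("six_of_six_damaging",) + db_reasons)
    return VariantClass("other", "n_a", ())


def classify_records(records: Iterable[SiteRecord], panel: Panel, build: str) -> pd.DataFrame:
    """Classify a collection of retained sites into a tidy table.

    One row per site: variant key, gene, star label (panel hits), AC/AN,
    category, novelty and the rule hits behind the decision.
    """
    rows = []
    for rec in records:
        vc = classify_variant(rec, panel, build)
        star = None
        if vc.category == "dpwg" and rec.alt is not None:
            hit = panel.lookup_variant(rec.chrom, rec.pos, rec.ref, rec.alt, build)
            star = hit.star_label if hit else None
        rows.append({
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt or ".",
            "gene": rec.gene or _ann(rec, "gene"), "star_label": star,
            "ac": rec.ac, "an": rec.an,
            "category": vc.category, "novelty": vc.novelty,
            "reasons": ";".join(vc.reasons),
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "star_label",
                                       "ac", "an", "category", "novelty", "reasons"])
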