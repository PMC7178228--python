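"""VCF and annotation-table I/O plus the site-level filter cascade.

Reads single-sample, multi-sample and gVCF-like VCFs (rows asserting
homozygous-reference genotypes are retained: "reference" must stay
distinguishable from "no data"), decomposes multi-allelic records into
biallelic :class:`SiteRecord` objects with left-aligned indels, attaches the
per-variant annotation table (consequence, six missense predictors, database
membership, mappability), and applies the high-confidence site filters:
non-PASS records and sites with 150-mer mappability below 1 are excluded,
each with a machine-readable reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from pgxkit.panel import normalize_variant

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "fathmm", "fathmm_mkl", "mutation_assessor", "mutation_taster", "polyphen2", "sift",
    "clinvar_drug_response", "hgmd_class", "pharmgkb", "splice_pred", "mappability",
]

#: GRCh37 contig lengths for the chromosomes the bundled panel touches
CONTIG_LENGTHS = {
    "1": 249250621, "2": 243199373, "6": 171115067, "7": 159138663,
    "10": 135534747, "12": 133851895, "16": 90354753, "19": 59128983,
    "22": 51304566,
}


class VcfError(ValueError):
    """Invalid VCF input for the requested mode."""


@dataclass
class SiteRecord:
    """One biallelic observed site with counts, annotations and genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: Optional[str]  # None for a pure homozygous-reference block
    filter_status: str = "PASS"
    ac: int = 0
    an: int = 0
    mappability: Optional[float] = None
    per_pop: Optional[dict[str, tuple[int, int]]] = None
    annotations: Optional[dict] = None
    genotypes: Optional[dict[str, tuple[Optional[int], Optional[int]]]] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.ac <= self.an):
            raise VcfError(f"{self.chrom}:{self.pos} has ac={self.ac} outside [0, an={self.an}]")
        if self.mappability is not None and not (0.0 <= self.mappability <= 1.0):
            raise VcfError(f"{self.chrom}:{self.pos} mappability {self.mappability} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt or ".")

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"


def _decomposed_gt(gt: tuple, alt_index: int) -> tuple[Optional[int], Optional[int]]:
    """Project a (possibly multi-allelic) GT onto one alternate allele."""
    out = []
    for a in gt:
        if a is None:
            out.append(None)
        else:
            out.append(1 if a == alt_index else 0)
    if len(out) == 1:  # haploid call: reject, panel genes are handled diploid
        raise VcfError("hemizygous/haploid genotype encountered; panel genes are handled diploid")
    return (out[0], out[1])


def read_vcf(path: str | Path, mode: str = "cohort", build: Optional[str] = None) -> list[SiteRecord]:
    """Read a VCF into decomposed, left-aligned :class:`SiteRecord` objects.

    ``mode="cohort"`` requires sample genotypes (GT) and derives AC/AN from
    them; ``mode="sites"`` reads AC/AN (and per-population AC_*/AN_*) from
    INFO. A declared ``build`` is checked against the header reference line
    when one is present.
    """
    if mode not in ("cohort", "sites"):
        raise VcfError(f"unknown mode {mode!r}")
    records: list[SiteRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        header_text = str(vf.header)
        if build is not None:
            other = {"GRCh37": "GRCh38", "GRCh38": "GRCh37"}[build]
            for line in header_text.splitlines():
                if line.startswith("##reference") and other.lower() in line.lower():
                    raise VcfError(f"VCF header declares {other}, run is configured for {build}")
        samples = list(vf.header.samples)
        if mode == "cohort" and not samples:
            raise VcfError("cohort mode requires sample genotypes, none found")
        for rec in vf:
            chrom = rec.chrom.removeprefix("chr")
            filter_keys = list(rec.filter.keys())
            filter_status = "PASS" if not filter_keys or filter_keys == ["PASS"] else ";".join(filter_keys)
            alts = [a for a in (rec.alts or []) if a not in (".", "<NON_REF>", "*")]
            if not alts:
                # gVCF-like homozygous-reference assertion
                genotypes = None
                an = ac = 0
                if mode == "cohort":
                    genotypes = {}
                    for s in samples:
                        gt = rec.samples[s].get("GT", (None, None))
                        genotypes[s] = _decomposed_gt(gt, alt_index=-1)
                    an = sum(a is not None for g in genotypes.values() for a in g)
                else:
                    an = rec.info.get("AN", 0)
                records.append(SiteRecord(chrom, rec.pos, rec.ref, None,
                                          filter_status=filter_status, ac=0, an=int(an),
                                          genotypes=genotypes))
                continue
            for i, alt in enumerate(alts, start=1):
                pos, ref, nalt = normalize_variant(rec.pos, rec.ref, alt)
                genotypes = None
                per_pop = None
                if mode == "cohort":
                    genotypes = {}
                    for s in samples:
                        gt = rec.samples[s].get("GT", (None, None))
                        if gt is None or all(a is None for a in gt):
                            raise VcfError(f"missing GT for sample {s} at {chrom}:{rec.pos}")
                        genotypes[s] = _decomposed_gt(gt, alt_index=i)
                    an = sum(a is not None for g in genotypes.values() for a in g)
                    ac = sum(a == 1 for g in genotypes.values() for a in g)
                else:
                    ac_info = rec.info.get("AC", 0)
                    ac = int(ac_info[i - 1] if isinstance(ac_info, tuple) else ac_info)
                    an = int(rec.info.get("AN", 0))
                    pops = {}
                    for key in rec.info.keys():
                        if key.startswith("AC_"):
                            pop = key[3:]
                            ac_p = rec.info[key]
                            ac_p = int(ac_p[i - 1] if isinstance(ac_p, tuple) else ac_p)
                            an_p = int(rec.info.get(f"AN_{pop}", 0))
                            pops[pop] = (ac_p, an_p)
                    per_pop = pops or None
                records.append(SiteRecord(chrom, pos, ref, nalt,
                                          filter_status=filter_status, ac=ac, an=an,
                                          per_pop=per_pop, genotypes=genotypes))
    return records


def write_vcf(records: Iterable[SiteRecord], path: str | Path, samples: Optional[list[str]] = None) -> None:
    """Write SiteRecords to a VCF 4.2 file (plain text)."""
    records = list(records)
    samples = samples or []
    header = pysam.VariantHeader()
    header.add_line('##source=pgxkit')
    chroms = sorted({r.chrom for r in records}, key=lambda c: (len(c), c))
    for c in chroms:
        header.add_line(f"##contig=<ID={c},length={CONTIG_LENGTHS.get(c, 250_000_000)}>")
    header.add_line('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">')
    header.add_line('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">')
    header.add_line('##FILTER=<ID=RF,Description="Failed random-forest site quality model">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    order = {c: i for i, c in enumerate(chroms)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (order[r.chrom], r.pos, r.alt or "")):
            rec = out.new_record(contig=r.chrom, start=r.pos - 1,
                                 alleles=(r.ref, r.alt) if r.alt else (r.ref, "."))
            rec.info["AC"] = (r.ac,)
            rec.info["AN"] = r.an
            if r.filter_status != "PASS":
                for f in r.filter_status.split(";"):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            if samples:
                for s in samples:
                    gt = (r.genotypes or {}).get(s, (None, None))
                    rec.samples[s]["GT"] = gt
                    rec.samples[s].phased = False
            out.write(rec)


# -- annotation table --------------------------------------------------------


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-variant annotation TSV keyed by chrom,pos,ref,alt."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise VcfError(f"annotation table lacks key columns: {missing}")
    return df


def attach_annotations(records: list[SiteRecord], annotations: pd.DataFrame,
                       default_mappability: float = 1.0) -> list[SiteRecord]:
    """Attach annotation rows to records in place (matched on normalized key).

    Records without a mappability annotation are treated as fully mappable
    (``default_mappability``) with a warning, rather than silently dropped.
    """
    index: dict[tuple, dict] = {}
    for row in annotations.to_dict("records"):
        pos, ref, alt = normalize_variant(int(row["pos"]), str(row["ref"]), str(row["alt"]))
        index[(str(row["chrom"]).removeprefix("chr"), pos, ref, alt)] = row
    n_defaulted = 0
    for rec in records:
        row = index.get(rec.key)
        if row is not None:
            rec.annotations = row
            rec.gene = row.get("gene") or rec.gene
            mappability = row.get("mappability")
            rec.mappability = default_mappability if mappability is None or pd.isna(mappability) \
                else float(mappability)
        elif rec.mappability is None:
            rec.mappability = default_mappability
            n_defaulted += 1
    if n_defaulted:
        warnings.warn(f"{n_defaulted} records lack a mappability annotation; "
                      f"treated as {default_mappability}", stacklevel=2)
    return records


# -- filter cascade ----------------------------------------------------------


def apply_site_filters(records: Iterable[SiteRecord], min_mappability: float = 1.0,
                       require_pass: bool = True) -> tuple[list[SiteRecord], list[tuple[SiteRecord, str]]]:
    """High-confidence site filters: retain PASS sites with full mappability.

    Returns ``(retained, excluded)`` where every exclusion carries a reason
    (``non_pass`` or ``low_mappability``); the two lists partition the input.
    """
    retained: list[SiteRecord] = []
    excluded: list[tuple[SiteRecord, str]] = []
    for rec in records:
        if require_pass and not rec.is_pass:
            excluded.append((rec, "non_pass"))
        elif rec.mappability is not None and rec.mappability < min_mappability:
            excluded.append((rec, "low_mappability"))
        else:
            retained.append(rec)
    return retained, excluded


# -- structural-variant merge -------------------------------------------------


@dataclass
class Cyp2d6Genotype:
    """CYP2D6 genotype after merging SNV/indel star alleles with SV calls."""

    sample: str
    diplotype: str
    flags: set[str] = field(default_factory=set)
    snv_alleles: tuple[str, ...] = ()


def _assemble_diplotype(alleles: list[str]) -> str:
    alleles = sorted(alleles)
    if len(alleles) == 0:
        return "*1/*1"
    if len(alleles) == 1:
        return f"*1/{alleles[0]}"
    return f"{alleles[0]}/{alleles[1]}"


def merge_sv_calls(snv_star_alleles: dict[str, list[str]],
                   sv_table: dict[str, str]) -> dict[str, Cyp2d6Genotype]:
    """Attach external CYP2D6 SV diplotypes to per-sample SNV star alleles.

    ``sv_table`` maps sample to a CYP2D6 diplotype string from an external
    caller (deletions *5, duplications xN, tandem hybrids ``*68+*4``). The SV
    diplotype takes precedence; a whole-gene double deletion that contradicts
    detected SNV alleles is flagged ``sv_conflict``. Samples absent from the
    table keep their SNV-derived diplotype with flag ``sv_unknown``.
    """
    from pgxkit.cyp2d6 import parse_diplotype, render

    out: dict[str, Cyp2d6Genotype] = {}
    for sample, alleles in snv_star_alleles.items():
        if sample in sv_table:
            d = parse_diplotype(sv_table[sample])  # raises on unparsable text
            flags = set()
            labels = [c.label for h in d.haplotypes for c in h.components]
            if labels == ["*5", "*5"] and alleles:
                flags.add("sv_conflict")
            out[sample] = Cyp2d6Genotype(sample, render(d), flags, tuple(alleles))
        else:
            out[sample] = Cyp2d6Genotype(sample, _assemble_diplotype(list(alleles)),
                                         {"sv_unknown"}, tuple(alleles))
    return out
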