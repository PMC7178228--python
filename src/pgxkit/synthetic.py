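"""Deterministic synthetic cohorts with the structure the analysis assumes.

The generator emulates the input the profiler sees in practice: a gVCF-like
multi-sample VCF over the panel sites (homozygous-reference rows included, so
wildtype stays distinguishable from no-call), an annotation table in the
dialect :mod:`pgxkit.variant_io` consumes, and a ground-truth table for every
sampled and planted genotype.

Genotypes are drawn per variant under Hardy-Weinberg equilibrium at the
configured allele frequency, independently across variants (no linkage
disequilibrium — a stated non-goal). The default frequency preset is chosen
so the expected number of actionable panel alleles per genome is about six,
the figure reported for a European-ancestry clinical WGS cohort; the default
cohort size is 547 genomes and the default rare-variant load is ten novel
loss-of-function/missense singletons, matching that study design. Explicit
"plants" override sampled genotypes to guarantee scenario individuals (a
CYP2C19 ultrarapid+poor+novel-splice carrier; five VKORC1*2/CYP2C9*2 double
homozygotes).

Randomness is keyed by ``(seed, site index)``: adding sites never perturbs
the draws of earlier sites, so fixtures stay stable as the panel grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from pgxkit.panel import Panel, PanelVariant
from pgxkit.variant_io import ANNOTATION_COLUMNS, SiteRecord, write_vcf

#: annotation consequence terms for panel sites that are not plain missense
_PANEL_CONSEQUENCES = {
    ("CYP2D6", "*3"): "frameshift_variant",
    ("CYP2D6", "*6"): "frameshift_variant",
    ("CYP2D6", "*9"): "inframe_deletion",
    ("CYP2D6", "*4"): "splice_acceptor_variant",
    ("CYP3A5", "*3"): "intron_variant",
    ("CYP3A5", "*7"): "frameshift_variant",
    ("CYP2C19", "*17"): "upstream_gene_variant",
    ("CYP2C9", "*2"): "missense_variant",
    ("VKORC1", "*2"): "intron_variant",
    ("UGT1A1", "*28"): "regulatory_region_variant",
    ("UGT1A1", "*37"): "regulatory_region_variant",
    ("DPYD", "*2A"): "splice_donor_variant",
    ("TPMT", "*4"): "splice_acceptor_variant",
    ("HCP5", "rs2395029"): "missense_variant",
}


def default_frequencies() -> dict[tuple[str, str], float]:
    """Bundled European-ancestry-like allele frequency preset.

    Chosen so that the expected actionable panel-allele count per genome,
    sum of 2f over the 45 panel definitions, is approximately 6. Illustrative,
    not ground truth for any real population.
    """
    return {
        ("CYP2B6", "*6"): 0.24, ("CYP2B6", "*4"): 0.04,
        ("CYP2B6", "*5"): 0.11, ("CYP2B6", "*18"): 0.02,
        ("CYP2C9", "*2"): 0.12, ("CYP2C9", "*3"): 0.07, ("CYP2C9", "*5"): 0.001,
        ("CYP2C9", "*8"): 0.003, ("CYP2C9", "*11"): 0.002,
        ("CYP2C19", "*2"): 0.15, ("CYP2C19", "*3"): 0.003, ("CYP2C19", "*4"): 0.002,
        ("CYP2C19", "*5"): 0.001, ("CYP2C19", "*6"): 0.001, ("CYP2C19", "*8"): 0.003,
        ("CYP2C19", "*17"): 0.22,
        ("CYP2D6", "*3"): 0.01, ("CYP2D6", "*4"): 0.11, ("CYP2D6", "*6"): 0.01,
        ("CYP2D6", "*7"): 0.001, ("CYP2D6", "*8"): 0.001, ("CYP2D6", "*9"): 0.03,
        ("CYP2D6", "*10"): 0.02, ("CYP2D6", "*12"): 0.001, ("CYP2D6", "*14"): 0.001,
        ("CYP2D6", "*17"): 0.002, ("CYP2D6", "*29"): 0.002, ("CYP2D6", "*41"): 0.09,
        ("CYP3A5", "*3"): 0.93, ("CYP3A5", "*6"): 0.003, ("CYP3A5", "*7"): 0.001,
        ("DPYD", "*2A"): 0.005, ("DPYD", "*13"): 0.001,
        ("DPYD", "c.2846A>T"): 0.004, ("DPYD", "HapB3"): 0.024,
        ("F5", "Leiden"): 0.03,
        ("SLCO1B1", "*5"): 0.16,
        ("TPMT", "*2"): 0.002, ("TPMT", "*3B"): 0.002,
        ("TPMT", "*3C"): 0.03, ("TPMT", "*4"): 0.001,
        ("UGT1A1", "*28"): 0.32, ("UGT1A1", "*37"): 0.001,
        ("VKORC1", "*2"): 0.45,
        ("HCP5", "rs2395029"): 0.03,
    }


@dataclass(frozen=True)
class NovelVariant:
    """A rare non-panel variant with its intended classification."""

    label: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    carriers: int = 1          # heterozygous carriers to sample (singleton default)
    damaging_missense: bool = False  # emit 6/6 damaging predictor verdicts
    known: bool = False        # set a database membership flag (else novel)
    splice_pred: Optional[bool] = None

    @property
    def expected_category(self) -> str:
        if self.consequence in ("stop_gained", "frameshift_variant"):
            return "lof"
        if self.consequence in ("splice_acceptor_variant", "splice_donor_variant") \
                and self.splice_pred is not False:
            return "lof"
        if self.consequence == "missense_variant" and self.damaging_missense:
            return "damaging_missense"
        return "other"


def default_novel_variants() -> list[NovelVariant]:
    """Ten novel LOF/consensus-damaging-missense singletons across the panel genes."""
    return [
        NovelVariant("CYP2C19:c.643-2A>T", "CYP2C19", "10", 96535600, "A", "T",
                     "splice_acceptor_variant", splice_pred=True),
        NovelVariant("CYP2B6:stop", "CYP2B6", "19", 41513100, "C", "T", "stop_gained"),
        NovelVariant("CYP2C9:fs", "CYP2C9", "10", 96702500, "CT", "C", "frameshift_variant"),
        NovelVariant("CYP2D6:stop", "CYP2D6", "22", 42525200, "G", "A", "stop_gained"),
        NovelVariant("CYP3A5:mis", "CYP3A5", "7", 99265000, "G", "C",
                     "missense_variant", damaging_missense=True),
        NovelVariant("DPYD:fs", "DPYD", "1", 97916000, "GA", "G", "frameshift_variant"),
        NovelVariant("F5:mis", "F5", "1", 169520000, "T", "G",
                     "missense_variant", damaging_missense=True),
        NovelVariant("SLCO1B1:stop", "SLCO1B1", "12", 21332000, "C", "A", "stop_gained"),
        NovelVariant("TPMT:mis", "TPMT", "6", 18140000, "A", "C",
                     "missense_variant", damaging_missense=True),
        NovelVariant("UGT1A1:splice", "UGT1A1", "2", 234670000, "G", "T",
                     "splice_donor_variant", splice_pred=True),
    ]


@dataclass(frozen=True)
class Plant:
    """An explicit sample scenario overriding sampled genotypes."""

    sample: int
    panel_genotypes: dict = field(default_factory=dict)  # (gene, star_label) -> copies
    novel_genotypes: dict = field(default_factory=dict)  # novel label -> copies
    description: str = ""


def default_plants() -> list[Plant]:
    """Scenario individuals mirroring the study's screening findings."""
    plants = [Plant(sample=0,
                    panel_genotypes={("CYP2C19", "*17"): 1, ("CYP2C19", "*2"): 1},
                    novel_genotypes={"CYP2C19:c.643-2A>T": 1},
                    description="ultrarapid + poor + novel splice alleles in CYP2C19")]
    for k in range(1, 6):
        plants.append(Plant(sample=k,
                            panel_genotypes={("VKORC1", "*2"): 2, ("CYP2C9", "*2"): 2},
                            description="VKORC1*2 and CYP2C9*2 double homozygote"))
    return plants


@dataclass
class CohortSpec:
    """Study-condition parameters of a synthetic diploid cohort."""

    seed: int
    n_samples: int = 547
    frequencies: Optional[dict[tuple[str, str], float]] = None
    novel: Optional[list[NovelVariant]] = None
    plants: Optional[list[Plant]] = None
    build: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.frequencies is None:
            self.frequencies = default_frequencies()
        if self.novel is None:
            self.novel = default_novel_variants()
        if self.plants is None:
            self.plants = default_plants()
        for key, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency out of range for {key}: {f}")
        for nv in self.novel:
            if nv.carriers / (2 * self.n_samples) > 0.001:
                raise ValueError(f"novel variant {nv.label} is not rare at n={self.n_samples}")


@dataclass
class Cohort:
    spec: CohortSpec
    samples: list[str]
    records: list[SiteRecord]
    annotations: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_genotypes: pd.DataFrame

    def actionable_per_sample(self) -> pd.Series:
        """Panel (DPWG) variant alleles carried per sample, from the truth table."""
        dp = self.truth_genotypes[self.truth_genotypes["category"] == "dpwg"]
        counts = dp.groupby("sample")["copies"].sum()
        return counts.reindex(self.samples, fill_value=0)


def _sample_names(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def _panel_annotation_row(pv: PanelVariant, build: str) -> dict:
    chrom, pos = pv.coords(build)
    consequence = _PANEL_CONSEQUENCES.get((pv.gene, pv.star_label), "missense_variant")
    return {
        "chrom": chrom, "pos": pos, "ref": pv.ref, "alt": pv.alt, "gene": pv.gene,
        "consequence": consequence,
        "fathmm": "t", "fathmm_mkl": "t", "mutation_assessor": "t",
        "mutation_taster": "t", "polyphen2": "t", "sift": "t",
        "clinvar_drug_response": 1, "hgmd_class": "", "pharmgkb": 1,
        "splice_pred": "", "mappability": 1.0,
    }


def _novel_annotation_row(nv: NovelVariant) -> dict:
    verdict = "d" if nv.damaging_missense else "t"
    return {
        "chrom": nv.chrom, "pos": nv.pos, "ref": nv.ref, "alt": nv.alt, "gene": nv.gene,
        "consequence": nv.consequence,
        "fathmm": verdict, "fathmm_mkl": verdict, "mutation_assessor": verdict,
        "mutation_taster": verdict, "polyphen2": verdict, "sift": verdict,
        "clinvar_drug_response": 1 if nv.known else 0, "hgmd_class": "", "pharmgkb": 0,
        "splice_pred": "" if nv.splice_pred is None else int(nv.splice_pred),
        "mappability": 1.0,
    }


def generate_cohort(spec: CohortSpec, panel: Panel,
                    out_dir: Optional[str | Path] = None) -> Cohort:
    """Generate a synthetic diploid cohort genotyped at the panel sites.

    Returns in-memory records plus annotation and truth tables; when
    ``out_dir`` is given, also writes ``cohort.vcf``, ``annotations.tsv``,
    ``truth_sites.tsv`` and ``truth_genotypes.tsv``.
    """
    n = spec.n_samples
    samples = _sample_names(n)
    sites = panel.sites(spec.build)
    site_keys = {pv.key(spec.build) for pv in sites}
    for nv in spec.novel:
        if (nv.chrom, nv.pos, nv.ref, nv.alt) in site_keys:
            raise ValueError(f"novel variant {nv.label} collides with a panel site")

    # feasibility of plants before any sampling
    by_star = {(pv.gene, pv.star_label): pv for pv in sites}
    novel_by_label = {nv.label: nv for nv in spec.novel}
    for plant in spec.plants:
        if not 0 <= plant.sample < n:
            raise ValueError(f"plant sample index {plant.sample} outside cohort")
        for key, copies in plant.panel_genotypes.items():
            if key not in by_star:
                raise ValueError(f"plant references unknown panel variant {key}")
            if copies > 0 and spec.frequencies.get(key, 0.0) == 0.0:
                raise ValueError(f"infeasible plant: {key} has frequency 0")
        for label in plant.novel_genotypes:
            if label not in novel_by_label:
                raise ValueError(f"plant references undeclared novel variant {label}")

    planted_by_site: dict[tuple, dict[int, int]] = {}
    for plant in spec.plants:
        for key, copies in plant.panel_genotypes.items():
            planted_by_site.setdefault(key, {})[plant.sample] = copies
        for label, copies in plant.novel_genotypes.items():
            planted_by_site.setdefault(("novel", label), {})[plant.sample] = copies

    records: list[SiteRecord] = []
    ann_rows: list[dict] = []
    truth_sites_rows: list[dict] = []
    truth_gt_rows: list[dict] = []

    def emit(chrom: str, pos: int, ref: str, alt: str, gene: str, label: str,
             copies: np.ndarray, category: str, novelty: str, freq: float,
             planted: dict[int, int], ann_row: dict) -> None:
        genotypes = {}
        for j, s in enumerate(samples):
            c = int(copies[j])
            genotypes[s] = (1, 1) if c == 2 else ((0, 1) if c == 1 else (0, 0))
            if c > 0:
                truth_gt_rows.append({"sample": s, "gene": gene, "label": label,
                                      "copies": c, "category": category,
                                      "novelty": novelty, "planted": j in planted})
        ac = int(copies.sum())
        records.append(SiteRecord(chrom, pos, ref, alt, filter_status="PASS",
                                  ac=ac, an=2 * n, mappability=1.0,
                                  genotypes=genotypes, gene=gene,
                                  annotations=dict(ann_row)))
        ann_rows.append(ann_row)
        truth_sites_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                                 "gene": gene, "label": label, "freq": freq, "ac": ac,
                                 "an": 2 * n, "category": category, "novelty": novelty,
                                 "planted": bool(planted)})

    # Hardy-Weinberg sampling at the panel sites; stream keyed by (seed, site index)
    for i, pv in enumerate(sites):
        f = float(spec.frequencies.get((pv.gene, pv.star_label), 0.0))
        rng = np.random.default_rng([spec.seed, i])
        copies = (rng.random((n, 2)) < f).sum(axis=1).astype(int)
        planted = planted_by_site.get((pv.gene, pv.star_label), {})
        for sample_idx, c in planted.items():
            copies[sample_idx] = c
        chrom, pos = pv.coords(spec.build)
        emit(chrom, pos, pv.ref, pv.alt, pv.gene, pv.star_label, copies,
             "dpwg", "n_a", f, planted, _panel_annotation_row(pv, spec.build))

    # rare novel variants: explicit carrier counts, not frequency draws
    for k, nv in enumerate(spec.novel):
        rng = np.random.default_rng([spec.seed, len(sites) + k])
        copies = np.zeros(n, dtype=int)
        planted = planted_by_site.get(("novel", nv.label), {})
        if planted:
            for sample_idx, c in planted.items():
                copies[sample_idx] = c
        elif nv.carriers > 0:
            carriers = rng.choice(n, size=nv.carriers, replace=False)
            copies[carriers] = 1
        emit(nv.chrom, nv.pos, nv.ref, nv.alt, nv.gene, nv.label, copies,
             nv.expected_category, "known" if nv.known else "novel",
             nv.carriers / (2 * n), planted, _novel_annotation_row(nv))

    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    truth_sites = pd.DataFrame(truth_sites_rows)
    truth_genotypes = pd.DataFrame(truth_gt_rows,
                                   columns=["sample", "gene", "label", "copies",
                                            "category", "novelty", "planted"])
    cohort = Cohort(spec, samples, records, annotations, truth_sites, truth_genotypes)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(records, out / "cohort.vcf", samples=samples)
        annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        truth_sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        truth_genotypes.to_csv(out / "truth_genotypes.tsv", sep="\t", index=False)
    return cohort


def generate_sites(spec: CohortSpec, panel: Panel,
                   decoy_nonpass: int = 0, decoy_lowmap: int = 0,
                   out_dir: Optional[str | Path] = None) -> tuple[list[SiteRecord], pd.DataFrame]:
    """Sites-only input (AC/AN in INFO), with optional filter-decoy records.

    AC is drawn Binomial(AN, f) per site. Decoys exercise the filter cascade:
    ``decoy_nonpass`` extra records carry a non-PASS filter and
    ``decoy_lowmap`` extra records carry 150-mer mappability 0.5.
    """
    n = spec.n_samples
    an = 2 * n
    sites = panel.sites(spec.build)
    records: list[SiteRecord] = []
    ann_rows: list[dict] = []
    for i, pv in enumerate(sites):
        f = float(spec.frequencies.get((pv.gene, pv.star_label), 0.0))
        rng = np.random.default_rng([spec.seed, 5_000_000 + i])
        ac = int(rng.binomial(an, f))
        chrom, pos = pv.coords(spec.build)
        records.append(SiteRecord(chrom, pos, pv.ref, pv.alt, filter_status="PASS",
                                  ac=ac, an=an, mappability=1.0, gene=pv.gene))
        ann_rows.append(_panel_annotation_row(pv, spec.build))
    anchor = sites[0].coords(spec.build)
    for d in range(decoy_nonpass):
        pos = anchor[1] + 10_000 + d
        records.append(SiteRecord(anchor[0], pos, "A", "G", filter_status="RF",
                                  ac=1, an=an, mappability=1.0, gene=sites[0].gene))
        ann_rows.append({"chrom": anchor[0], "pos": pos, "ref": "A", "alt": "G",
                         "gene": sites[0].gene, "consequence": "missense_variant",
                         "mappability": 1.0})
    for d in range(decoy_lowmap):
        pos = anchor[1] + 20_000 + d
        records.append(SiteRecord(anchor[0], pos, "C", "T", filter_status="PASS",
                                  ac=1, an=an, mappability=0.5, gene=sites[0].gene))
        ann_rows.append({"chrom": anchor[0], "pos": pos, "ref": "C", "alt": "T",
                         "gene": sites[0].gene, "consequence": "missense_variant",
                         "mappability": 0.5})
    annotations = pd.DataFrame(ann_rows).reindex(columns=ANNOTATION_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(records, out / "sites.vcf")
        annotations.to_csv(out / "sites_annotations.tsv", sep="\t", index=False)
    return records, annotations
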