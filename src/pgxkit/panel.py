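"""Bundled pharmacogene panel, phenotype translation and recommendations.

The panel is the set of genotyped definitions the profiler operates on: 45
SNV/indel star-allele (or named-variant) definitions in 11 DPWG pharmacogenes,
one HLA-B*57:01 tag variant (HCP5 rs2395029) and opaque CYP2D6
structural-variant slots (*5 deletion, *xN duplication, *68 hybrid). Each
SNV/indel definition carries left-aligned coordinates on both GRCh37 and
GRCh38 so a single bundle serves either build.

Diplotype-to-phenotype translation follows the DPWG convention: explicit
star-pair rules where a gene has its own vocabulary (VKORC1 coumarin
sensitivity, Factor V Leiden carriership, the HLA tag), and otherwise a
generic activity score over allele function classes (two no-function alleles
give a poor metabolizer, a single increased-function allele a rapid one, and
so on).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

FUNCTION_CLASSES = ("no_function", "decreased", "normal", "increased", "unknown")
VARIANT_KINDS = ("snv", "indel", "tag", "sv_slot")
PHENOTYPES = (
    "PM", "IM", "NM", "RM", "UM",
    "carrier", "non_carrier",
    "high_sensitivity", "normal_sensitivity",
    "unknown",
)
BUILDS = ("GRCh37", "GRCh38")

#: activity contributed by one haplotype of each function class
ACTIVITY = {"no_function": 0.0, "decreased": 0.5, "normal": 1.0, "increased": 1.5}

#: phenotype considered "no action" for each translation vocabulary
NORMAL_PHENOTYPES = frozenset({"NM", "non_carrier", "normal_sensitivity"})

WILDTYPE = "*1"

EXPECTED_SNV_INDEL_COUNT = 45
EXPECTED_GENE_COUNT = 11

DATA_VERSION = "v1"


class PanelError(ValueError):
    """Malformed or inconsistent panel/guideline bundle."""


def _data_path(name: str) -> Path:
    return Path(resources.files("pgxkit.data").joinpath(DATA_VERSION).joinpath(name))  # type: ignore[arg-type]


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align/trim an allele pair to its minimal representation.

    Shared suffix bases are removed first, then shared prefix bases (keeping
    at least one base of each allele), moving ``pos`` right accordingly.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class PanelVariant:
    """One panel entry: a genotyped variant with its star/variant label."""

    gene: str
    star_label: str
    chrom_37: Optional[str]
    pos_37: Optional[int]
    chrom_38: Optional[str]
    pos_38: Optional[int]
    ref: str
    alt: str
    hgvs_c: str
    function_class: str
    variant_kind: str

    def coords(self, build: str) -> tuple[str, int]:
        if build == "GRCh37":
            chrom, pos = self.chrom_37, self.pos_37
        elif build == "GRCh38":
            chrom, pos = self.chrom_38, self.pos_38
        else:
            raise PanelError(f"unknown genome build: {build!r}")
        if chrom is None or pos is None:
            raise PanelError(f"{self.gene} {self.star_label} has no {build} coordinates")
        return chrom, pos

    @property
    def has_coordinates(self) -> bool:
        return self.pos_37 is not None or self.pos_38 is not None

    def key(self, build: str) -> tuple[str, int, str, str]:
        chrom, pos = self.coords(build)
        return (chrom, pos, self.ref, self.alt)


class Panel:
    """Indexed collection of :class:`PanelVariant` entries."""

    def __init__(self, variants: Iterable[PanelVariant], version: str = "unversioned"):
        self.variants: list[PanelVariant] = list(variants)
        self.version = version
        self._validate()
        self._by_star = {(v.gene, v.star_label): v for v in self.variants}
        self._by_site: dict[str, dict[tuple, list[PanelVariant]]] = {b: {} for b in BUILDS}
        for v in self.variants:
            if v.variant_kind in ("snv", "indel", "tag"):
                for build in BUILDS:
                    try:
                        key = v.key(build)
                    except PanelError:
                        continue  # build-specific entry
                    self._by_site[build].setdefault(key, []).append(v)

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for v in self.variants:
            if (v.gene, v.star_label) in seen:
                raise PanelError(f"duplicate panel entry {v.gene} {v.star_label}")
            seen.add((v.gene, v.star_label))
            if v.function_class not in FUNCTION_CLASSES:
                raise PanelError(f"{v.gene} {v.star_label}: bad function class {v.function_class!r}")
            if v.variant_kind not in VARIANT_KINDS:
                raise PanelError(f"{v.gene} {v.star_label}: bad variant kind {v.variant_kind!r}")
            if v.variant_kind in ("snv", "indel", "tag"):
                if v.ref == v.alt:
                    raise PanelError(f"{v.gene} {v.star_label}: ref equals alt")
                if not v.has_coordinates:
                    raise PanelError(f"{v.gene} {v.star_label}: no coordinates on either build")
        n = self.n_snv_indel
        g = len(self.genes)
        if n != EXPECTED_SNV_INDEL_COUNT or g != EXPECTED_GENE_COUNT:
            warnings.warn(
                f"panel holds {n} SNV/indel definitions in {g} genes "
                f"(bundled default: {EXPECTED_SNV_INDEL_COUNT} in {EXPECTED_GENE_COUNT})",
                stacklevel=3,
            )

    # -- simple views -------------------------------------------------------

    @property
    def n_snv_indel(self) -> int:
        return sum(v.variant_kind in ("snv", "indel") for v in self.variants)

    @property
    def genes(self) -> tuple[str, ...]:
        """Genes with SNV/indel definitions (excludes the tag gene)."""
        return tuple(sorted({v.gene for v in self.variants if v.variant_kind in ("snv", "indel")}))

    @property
    def tag_variants(self) -> list[PanelVariant]:
        return [v for v in self.variants if v.variant_kind == "tag"]

    @property
    def sv_slots(self) -> list[PanelVariant]:
        return [v for v in self.variants if v.variant_kind == "sv_slot"]

    def count_report(self) -> dict:
        return {
            "panel_version": self.version,
            "n_snv_indel": self.n_snv_indel,
            "n_genes": len(self.genes),
            "n_tag": len(self.tag_variants),
            "n_sv_slots": len(self.sv_slots),
        }

    # -- lookups ------------------------------------------------------------

    def lookup_all(self, chrom: str, pos: int, ref: str, alt: str, build: str) -> list[PanelVariant]:
        """All panel entries at a normalized biallelic site (aliases included)."""
        if build not in BUILDS:
            raise PanelError(f"unknown genome build: {build!r}")
        pos, ref, alt = normalize_variant(int(pos), ref, alt)
        return self._by_site[build].get((str(chrom).removeprefix("chr"), pos, ref, alt), [])

    def lookup_variant(self, chrom: str, pos: int, ref: str, alt: str, build: str) -> Optional[PanelVariant]:
        """Primary panel entry at a site, or ``None`` (exact-match semantics).

        Multi-allelic records must be decomposed by the caller. Where two
        labels share a defining site (CYP2B6 *6/*9) the first entry in panel
        order is the primary, reported label.
        """
        hits = self.lookup_all(chrom, pos, ref, alt, build)
        return hits[0] if hits else None

    def by_star(self, gene: str, star_label: str) -> Optional[PanelVariant]:
        return self._by_star.get((gene, star_label))

    def function_class(self, gene: str, star_label: str) -> str:
        if star_label == WILDTYPE:
            return "normal"
        v = self._by_star.get((gene, star_label))
        return v.function_class if v is not None else "unknown"

    def sites(self, build: str) -> list[PanelVariant]:
        """Primary SNV/indel/tag entries with unique coordinates on ``build``."""
        out, seen = [], set()
        for v in self.variants:
            if v.variant_kind not in ("snv", "indel", "tag"):
                continue
            try:
                key = v.key(build)
            except PanelError:
                continue
            if key not in seen:
                seen.add(key)
                out.append(v)
        return out


# -- TSV I/O ---------------------------------------------------------------

_COLUMNS = [
    "gene", "star_label", "chrom_37", "pos_37", "chrom_38", "pos_38",
    "ref", "alt", "hgvs_c", "function_class", "variant_kind",
]


def load_panel(path: Optional[str | Path] = None) -> Panel:
    """Load a panel TSV (the bundled default when ``path`` is omitted)."""
    if path is None:
        path = _data_path("dpwg_panel.tsv")
    path = Path(path)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    version = "unversioned"
    header: Optional[list[str]] = None
    variants: list[PanelVariant] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        if raw.startswith("#"):
            if "panel_version=" in raw:
                version = raw.split("panel_version=", 1)[1].strip()
            continue
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if header is None:
            header = fields
            if header != _COLUMNS:
                raise PanelError(f"unexpected panel columns: {header}")
            continue
        if len(fields) != len(_COLUMNS):
            raise PanelError(f"line {lineno}: expected {len(_COLUMNS)} columns, got {len(fields)}")
        row = dict(zip(_COLUMNS, (f.strip() for f in fields)))
        try:
            pos_37 = int(row["pos_37"]) if row["pos_37"] else None
            pos_38 = int(row["pos_38"]) if row["pos_38"] else None
        except ValueError as exc:
            raise PanelError(f"line {lineno}: malformed coordinates") from exc
        ref, alt = row["ref"], row["alt"]
        chrom_37 = row["chrom_37"] or None
        chrom_38 = row["chrom_38"] or None
        if row["variant_kind"] in ("snv", "indel", "tag"):
            # store left-aligned minimal representation on both builds
            nref, nalt = ref, alt
            if pos_37 is not None:
                pos_37, nref, nalt = normalize_variant(pos_37, ref, alt)
            if pos_38 is not None:
                pos_38, nref, nalt = normalize_variant(pos_38, ref, alt)
            ref, alt = nref, nalt
        variants.append(
            PanelVariant(
                gene=row["gene"], star_label=row["star_label"],
                chrom_37=chrom_37, pos_37=pos_37, chrom_38=chrom_38, pos_38=pos_38,
                ref=ref, alt=alt, hgvs_c=row["hgvs_c"],
                function_class=row["function_class"], variant_kind=row["variant_kind"],
            )
        )
    if not variants:
        raise PanelError(f"panel file {path} contains no variant definitions")
    return Panel(variants, version=version)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to TSV (normalized representation)."""
    lines = [f"# pgxkit DPWG variant panel", f"# panel_version={panel.version}", "\t".join(_COLUMNS)]
    for v in panel.variants:
        lines.append("\t".join([
            v.gene, v.star_label,
            v.chrom_37 or "", str(v.pos_37) if v.pos_37 is not None else "",
            v.chrom_38 or "", str(v.pos_38) if v.pos_38 is not None else "",
            v.ref, v.alt, v.hgvs_c, v.function_class, v.variant_kind,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- phenotype translation --------------------------------------------------


class PhenotypeRules:
    """Diplotype-to-phenotype translation table.

    Explicit (gene, allele pair) rules are consulted first; ``*`` is a
    wildcard matching any allele of the gene. Genes without an explicit rule
    fall back to the activity-score translation over function classes.
    """

    def __init__(self, explicit: dict[str, list[tuple[str, str, str]]], version: str = "unversioned"):
        self.explicit = explicit
        self.version = version

    @classmethod
    def load(cls, path: Optional[str | Path] = None) -> "PhenotypeRules":
        if path is None:
            path = _data_path("phenotype_rules.tsv")
        version = "unversioned"
        explicit: dict[str, list[tuple[str, str, str]]] = {}
        header_seen = False
        for raw in Path(path).read_text().splitlines():
            if raw.startswith("#"):
                if "guideline_version=" in raw:
                    version = raw.split("guideline_version=", 1)[1].strip()
                continue
            if not raw.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            gene, a, b, phenotype = (f.strip() for f in raw.split("\t"))
            if phenotype not in PHENOTYPES:
                raise PanelError(f"unknown phenotype code {phenotype!r} for {gene}")
            explicit.setdefault(gene, []).append((a, b, phenotype))
        return cls(explicit, version=version)

    @staticmethod
    def _pair_matches(rule: tuple[str, str, str], pair: tuple[str, str]) -> bool:
        a, b, _ = rule
        x, y = pair
        return ((a in ("*", x)) and (b in ("*", y))) or ((a in ("*", y)) and (b in ("*", x)))

    def translate(self, panel: Panel, gene: str, diplotype: tuple[str, str]) -> str:
        """Phenotype for an unordered star-allele pair.

        Raises :class:`PanelError` for a gene absent from both the explicit
        rules and the panel. Unknown allele function on either haplotype
        yields ``"unknown"``.
        """
        known_genes = set(self.explicit) | set(panel.genes) | {v.gene for v in panel.variants}
        if gene not in known_genes:
            raise PanelError(f"no phenotype rules for gene {gene!r}")
        if any(a in ("*?", "?") for a in diplotype):
            return "unknown"
        for rule in self.explicit.get(gene, []):
            if self._pair_matches(rule, diplotype):
                return rule[2]
        classes = [panel.function_class(gene, a) for a in diplotype]
        if "unknown" in classes:
            return "unknown"
        score = sum(ACTIVITY[c] for c in classes)
        if score == 0.0:
            return "PM"
        if score < 2.0:
            return "IM"
        if score == 2.0:
            return "NM"
        if score < 3.0:
            return "RM"
        return "UM"


def translate_phenotype(panel: Panel, rules: PhenotypeRules, gene: str, diplotype: tuple[str, str]) -> str:
    return rules.translate(panel, gene, diplotype)


# -- recommendations --------------------------------------------------------


@dataclass(frozen=True)
class Recommendation:
    gene: str
    phenotypes: tuple[str, ...]
    drug: str
    action_text: str
    dose_fraction: Optional[float] = None


class Recommendations:
    """DPWG drug recommendation bundle."""

    DRUG_GROUPS = frozenset({"oral contraceptives"})

    def __init__(self, rows: list[Recommendation], version: str = "unversioned"):
        self.rows = rows
        self.version = version
        seen = set()
        for r in rows:
            key = (r.gene, r.phenotypes, r.drug)
            if key in seen:
                raise PanelError(f"duplicate recommendation {key}")
            seen.add(key)

    @classmethod
    def load(cls, path: Optional[str | Path] = None) -> "Recommendations":
        if path is None:
            path = _data_path("recommendations.tsv")
        version = "unversioned"
        rows: list[Recommendation] = []
        header_seen = False
        for raw in Path(path).read_text().splitlines():
            if raw.startswith("#"):
                if "guideline_version=" in raw:
                    version = raw.split("guideline_version=", 1)[1].strip()
                continue
            if not raw.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            fields = raw.split("\t")
            gene, phenotypes, drug, action = (f.strip() for f in fields[:4])
            dose = float(fields[4]) if len(fields) > 4 and fields[4].strip() else None
            rows.append(Recommendation(gene, tuple(phenotypes.split("|")), drug, action, dose))
        return cls(rows, version=version)

    @property
    def drugs(self) -> set[str]:
        """Individually covered drugs (drug-group entries excluded)."""
        return {r.drug for r in self.rows} - self.DRUG_GROUPS

    def lookup(self, gene: str, phenotype: str) -> list[Recommendation]:
        return [r for r in self.rows if r.gene == gene and phenotype in r.phenotypes]
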