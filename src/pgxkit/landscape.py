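"""Cohort-level pharmacogene landscape statistics.

Given classified sites with allele counts, this module builds per-gene
relative allele-frequency tables. Because short-read data are unphased, the
number of wildtype (*1) alleles is inferred by subtracting all detected
variant alleles of a gene from the total allele number under the assumption
that variants in the same gene occur in trans; co-occurring variants on one
haplotype therefore lead to an underestimate of wildtype alleles, which is
floored at zero and flagged rather than treated as an error.

Interval estimates use the continuity-corrected Wilson score interval
(Newcombe method 4), a conservative interval whose empirical coverage at the
95% level stays at or above the nominal level for the proportions seen here.

Minor allele frequency bins follow the three-way partition used for summary
tables: rare (MAF < 0.1%), low (0.1% <= MAF <= 5%) and common (MAF > 5%).
The two boundary points are assigned to the middle bin, a deterministic
choice that is immaterial at cohort scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats

from pgxkit.panel import _data_path

MAF_BINS = ("rare", "low", "common")
RARE_BOUND = 0.001   # MAF below this is "rare"
COMMON_BOUND = 0.05  # MAF above this is "common"


def wilson_cc_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Newcombe's method 4: the Wilson score interval with Yates continuity
    correction, clipped to [0, 1]; the lower bound is exactly 0 when x = 0
    and the upper bound exactly 1 when x = n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, n={n}]")
    z = stats.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    p = x / n
    q = 1.0 - p
    denom = 2.0 * (n + z * z)
    if x == 0:
        low = 0.0
    else:
        rad = z * z - 2.0 - 1.0 / n + 4.0 * p * (n * q + 1.0)
        low = (2.0 * n * p + z * z - 1.0 - z * math.sqrt(max(rad, 0.0))) / denom
    if x == n:
        high = 1.0
    else:
        rad = z * z + 2.0 - 1.0 / n + 4.0 * p * (n * q - 1.0)
        high = (2.0 * n * p + z * z + 1.0 + z * math.sqrt(max(rad, 0.0))) / denom
    return (max(0.0, low), min(1.0, high))


def maf_bin(ac: int, an: int) -> str:
    """Assign a site to its minor-allele-frequency bin.

    MAF is min(ac, an - ac)/an so that majority alternate alleles (e.g.
    CYP3A5*3) are binned by their minor frequency.
    """
    if an <= 0:
        raise ValueError("an must be positive")
    maf = min(ac, an - ac) / an
    if maf < RARE_BOUND:
        return "rare"
    if maf <= COMMON_BOUND:
        return "low"
    return "common"


def infer_wildtype(an: int, acs: Iterable[int]) -> tuple[int, bool]:
    """Wildtype allele count under the trans assumption.

    Returns ``(wildtype_count, overflow)``: ``an`` minus the sum of detected
    variant alleles, floored at zero. ``overflow`` is True when detected
    alleles exceed ``an`` (variants must then co-occur in cis, violating the
    trans assumption).
    """
    if an <= 0:
        raise ValueError("an must be positive (pass the cohort allele number explicitly)")
    total = sum(acs)
    wt = an - total
    return (max(wt, 0), wt < 0)


@dataclass
class GeneLandscape:
    """Per-gene relative allele-frequency table with an inferred *1 row."""

    gene: str
    an: int
    table: pd.DataFrame  # allele, ac, an, freq, ci_low, ci_high, category, novelty
    wildtype_overflow: bool = False
    notes: tuple[str, ...] = ()

    @property
    def wildtype_row(self) -> pd.Series:
        return self.table[self.table["allele"] == "*1"].iloc[0]


def build_gene_landscape(gene: str, classified: pd.DataFrame,
                         an: Optional[int] = None, conf: float = 0.95) -> GeneLandscape:
    """Build the allele-frequency landscape of one gene.

    ``classified`` is a classification table (see
    :func:`pgxkit.classify.classify_records`) restricted or restrictable to
    ``gene``. Allele numbers are harmonized to the maximum AN of the gene's
    sites (with a note) when they differ. Conservation — wildtype plus all
    variant alleles equals AN — holds by construction and is asserted.
    """
    sub = classified[classified["gene"] == gene].copy()
    notes: list[str] = []
    if sub.empty:
        if an is None:
            raise ValueError(f"no records for {gene}: an must be given explicitly")
    else:
        max_an = int(sub["an"].max())
        if an is None:
            an = max_an
        if sub["an"].nunique() > 1 or max_an != an:
            notes.append(f"allele numbers harmonized to an={an}")
    rows = []
    for _, r in sub.iterrows():
        label = r["star_label"] if pd.notna(r.get("star_label")) and r.get("star_label") else \
            f"{r['chrom']}:{r['pos']}{r['ref']}>{r['alt']}"
        low, high = wilson_cc_interval(int(r["ac"]), an, conf)
        rows.append({"allele": label, "ac": int(r["ac"]), "an": an,
                     "freq": int(r["ac"]) / an, "ci_low": low, "ci_high": high,
                     "category": r["category"], "novelty": r["novelty"]})
    wt, overflow = infer_wildtype(an, [r["ac"] for r in rows])
    low, high = wilson_cc_interval(wt, an, conf)
    rows.insert(0, {"allele": "*1", "ac": wt, "an": an, "freq": wt / an,
                    "ci_low": low, "ci_high": high, "category": "wildtype", "novelty": "n_a"})
    if overflow:
        notes.append("wildtype_overflow: detected alleles exceed AN; wildtype floored at 0")
    table = pd.DataFrame(rows)
    total = int(table["ac"].sum())
    if not overflow:
        assert total == an, f"allele conservation violated for {gene}: {total} != {an}"
        assert abs(table["freq"].sum() - 1.0) < 1e-9
    return GeneLandscape(gene=gene, an=an, table=table,
                         wildtype_overflow=overflow, notes=tuple(notes))


# -- cohort summaries ---------------------------------------------------------

_SUMMARY_GROUPS = {
    "novel_lof_missense": lambda d: d["category"].isin(["lof", "damaging_missense"]) & (d["novelty"] == "novel"),
    "known_lof_missense": lambda d: d["category"].isin(["lof", "damaging_missense"]) & (d["novelty"] == "known"),
    "dpwg": lambda d: d["category"] == "dpwg",
}


def summarize_cohort(classified: pd.DataFrame) -> pd.DataFrame:
    """Summary-table counts: variant and allele totals per group and MAF bin.

    For each variant group (novel LOF/missense, known LOF/missense, DPWG
    panel variants) the table reports the number of distinct variants, the
    summed allele counts, and the percentage of variants per MAF bin.
    Only detected variants (ac > 0) are tabulated.
    """
    rows = []
    detected = classified[classified["ac"] > 0].copy()
    if not detected.empty:
        detected["maf_bin"] = [maf_bin(int(a), int(n)) for a, n in zip(detected["ac"], detected["an"])]
    for group, mask_fn in _SUMMARY_GROUPS.items():
        sub = detected[mask_fn(detected)] if not detected.empty else detected
        n_total = len(sub)
        rows.append({"group": group, "maf_bin": "total", "n_variants": n_total,
                     "n_alleles": int(sub["ac"].sum()) if n_total else 0,
                     "pct_variants": 100.0 if n_total else 0.0})
        for b in ("common", "low", "rare"):
            nb = int((sub["maf_bin"] == b).sum()) if n_total else 0
            rows.append({"group": group, "maf_bin": b, "n_variants": nb,
                         "n_alleles": int(sub.loc[sub["maf_bin"] == b, "ac"].sum()) if n_total else 0,
                         "pct_variants": 100.0 * nb / n_total if n_total else 0.0})
    return pd.DataFrame(rows)


def dpwg_fraction(classified: pd.DataFrame) -> tuple[float, pd.Series]:
    """Share of detected alleles that carry a panel (DPWG) label.

    Returns the overall percentage and a per-gene Series. Only detected
    alleles in the three relevant categories enter the denominator.
    """
    det = classified[(classified["ac"] > 0)
                     & classified["category"].isin(["dpwg", "lof", "damaging_missense"])]
    total = det["ac"].sum()
    if total == 0:
        raise ValueError("no detected alleles")
    overall = 100.0 * det.loc[det["category"] == "dpwg", "ac"].sum() / total
    per_gene = det.groupby("gene").apply(
        lambda g: 100.0 * g.loc[g["category"] == "dpwg", "ac"].sum() / g["ac"].sum(),
        include_groups=False)
    return float(overall), per_gene


# -- fixed in-house CYP2D6 allele table --------------------------------------


def load_inhouse_cyp2d6() -> tuple[pd.DataFrame, int]:
    """Bundled in-house CYP2D6 star-allele counts and the cohort allele number."""
    path = _data_path("cyp2d6_inhouse_alleles.tsv")
    an = None
    for line in path.read_text().splitlines():
        if line.startswith("#") and "total_alleles=" in line:
            an = int(line.split("total_alleles=", 1)[1].strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    if an is None:
        an = int(2 * 547)
    return df, an


def cyp2d6_function_share(counts: Optional[Mapping[str, int]] = None,
                          functions: Optional[Mapping[str, str]] = None,
                          an: Optional[int] = None) -> float:
    """Percentage of CYP2D6 alleles with decreased or no function.

    With no arguments, uses the bundled in-house allele counts: the summed
    counts of the tabulated decreased/no-function alleles over the cohort's
    total allele number.
    """
    if counts is None:
        df, an = load_inhouse_cyp2d6()
        counts = dict(zip(df["allele"], df["count"]))
        functions = dict(zip(df["allele"], df["function_class"]))
    if functions is None or an is None:
        raise ValueError("functions and an are required with explicit counts")
    impaired = sum(int(c) for a, c in counts.items()
                   if functions.get(a) in ("decreased", "no_function"))
    return 100.0 * impaired / an
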