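"""CYP2D6 diplotype nomenclature parsing and concordance scoring.

CYP2D6 diplotypes from short-read callers and reference consensus genotypes
use a compact grammar::

    DIPLOTYPE := HAPLOTYPE "/" HAPLOTYPE
    HAPLOTYPE := COMPONENT ("+" COMPONENT)*
    COMPONENT := "*" LABEL ["x" N]                  e.g.  *2x2, *10, *4N
                | "(" "*" LABEL ["x" N] ["+"] ")"   e.g.  (*36+)

``+`` joins tandem arrangements (hybrid alleles such as *68 lying upstream
of *4 on one chromosome), ``xN`` denotes N copies of an allele, and a
parenthesized component marks a segment the consensus annotates as part of
the haplotype. Suballele letters (*13C) and caller-specific labels (*4N) are
opaque: they are compared at the printed granularity, never collapsed to a
core allele.

Scoring is phase-insensitive: a call is correct when its expanded allele
multiset equals the consensus multiset, after applying any sample-specific
accepted alternate allele pairs (e.g. *1 and *106 where the consensus lists
*1 but the allele was manually confirmed as *106). Parenthesized consensus
segments are treated as required for concordance — the interpretation
consistent with the published per-sample verdicts — while the parser records
the annotation for display. Footnote annotations on caller output are
honoured: a separately detected hybrid allele is appended to that caller's
multiset, whereas a "possible duplication" without an allele assignment
contributes nothing.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from pgxkit.panel import _data_path


class DiplotypeParseError(ValueError):
    """Text not in the diplotype grammar."""


@dataclass(frozen=True)
class Component:
    """One star-allele component of a haplotype."""

    label: str            # includes the leading "*", e.g. "*68", "*13C", "*4N"
    copies: int = 1
    optional: bool = False  # parenthesized in the consensus notation

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise DiplotypeParseError(f"copy count must be positive: {self.label}x{self.copies}")


@dataclass(frozen=True)
class Haplotype:
    components: tuple[Component, ...]


@dataclass(frozen=True)
class Diplotype:
    """Structured diplotype; also used for consensus genotypes."""

    haplotypes: tuple[Haplotype, Haplotype]


# star-allele labels are digits with an optional uppercase suballele/variant
# suffix (*2, *13C, *4N, *106); lowercase "x" and "×" denote copy counts
_LABEL = r"\d+[A-Z]*"
_COMPONENT_RE = re.compile(
    rf"""\(\*(?P<plabel>{_LABEL})(?:[x×](?P<pcopies>\d+))?\+?\)   # (*36+) style
      | \*(?P<label>{_LABEL})(?:[x×](?P<copies>\d+))?             # *2x2 style
    """,
    re.VERBOSE,
)


def _parse_haplotype(text: str) -> Haplotype:
    components: list[Component] = []
    i = 0
    while i < len(text):
        m = _COMPONENT_RE.match(text, i)
        if m is None:
            raise DiplotypeParseError(f"cannot parse haplotype {text!r} at offset {i}")
        if m.group("plabel") is not None:
            components.append(Component("*" + m.group("plabel"),
                                        int(m.group("pcopies") or 1), optional=True))
        else:
            components.append(Component("*" + m.group("label"),
                                        int(m.group("copies") or 1), optional=False))
        i = m.end()
        if i < len(text):
            if text[i] == "+":
                i += 1
                if i == len(text):
                    raise DiplotypeParseError(f"dangling '+' in {text!r}")
            elif not components[-1].optional:
                # a parenthesized segment carries its tandem '+' inside the
                # parens, so "(*36+)*10" needs no separator
                raise DiplotypeParseError(f"expected '+' between components in {text!r}")
    if not components:
        raise DiplotypeParseError("empty haplotype")
    return Haplotype(tuple(components))


def parse_diplotype(text: str) -> Diplotype:
    """Parse a diplotype string like ``*2x2/*71`` or ``(*36+)*10/*41``."""
    if not isinstance(text, str) or "/" not in text:
        raise DiplotypeParseError(f"not a diplotype: {text!r}")
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise DiplotypeParseError(f"expected exactly two haplotypes: {text!r}")
    return Diplotype((_parse_haplotype(parts[0]), _parse_haplotype(parts[1])))


def render(d: Diplotype) -> str:
    """Inverse of :func:`parse_diplotype` (uses ``x`` for copy counts)."""
    haps = []
    for h in d.haplotypes:
        parts = []
        for c in h.components:
            body = c.label if c.copies == 1 else f"{c.label}x{c.copies}"
            parts.append(f"({body}+)" if c.optional else body)
        haps.append("+".join(parts).replace("+)+", "+)"))
    return "/".join(haps)


def allele_multiset(d: Diplotype, include_optional: bool = True) -> Counter:
    """Phase-insensitive expansion to a star-label multiset.

    ``xN`` contributes N copies; parenthesized (consensus-annotated)
    components are included by default, matching the required-segment
    scoring interpretation.
    """
    ms: Counter = Counter()
    for h in d.haplotypes:
        for c in h.components:
            if c.optional and not include_optional:
                continue
            ms[c.label] += c.copies
    return ms


def _canonicalize(ms: Counter, alternates: Iterable[frozenset]) -> Counter:
    """Map accepted-alternate labels onto one canonical representative."""
    mapping: dict[str, str] = {}
    for pair in alternates:
        a, b = sorted(pair)
        mapping[b] = a
    out: Counter = Counter()
    for label, n in ms.items():
        out[mapping.get(label, label)] += n
    return out


@dataclass(frozen=True)
class Verdict:
    correct: bool
    reason: str


def score_call(call: Diplotype | str, consensus: Diplotype | str,
               alternates: Iterable[frozenset] = (),
               attach: Iterable[str] = (),
               dup_unassigned: bool = False) -> Verdict:
    """Score one caller diplotype against a consensus genotype.

    Correct iff the expanded allele multisets match (haplotype order and
    phase are ignored) after canonicalizing accepted alternate pairs.
    ``attach`` lists hybrid alleles the caller reported outside its diplotype
    string; they are appended to the call multiset. An unassigned-duplication
    flag (``dup_unassigned``) contributes nothing.
    """
    if isinstance(call, str):
        call = parse_diplotype(call)
    if isinstance(consensus, str):
        consensus = parse_diplotype(consensus)
    call_ms = allele_multiset(call)
    for label in attach:
        call_ms[label] += 1
    cons_ms = allele_multiset(consensus)
    alternates = list(alternates)
    call_ms = _canonicalize(call_ms, alternates)
    cons_ms = _canonicalize(cons_ms, alternates)
    if call_ms == cons_ms:
        return Verdict(True, "allele multisets match")
    missing = cons_ms - call_ms
    extra = call_ms - cons_ms
    return Verdict(False, f"missing={dict(missing)} extra={dict(extra)}")


# -- fixture scoring ----------------------------------------------------------

CALLERS = ("astrolabe", "aldy", "stargazer")


def load_call_matrix(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load a caller-comparison matrix TSV (bundled GeT-RM fixture by default)."""
    if path is None:
        path = _data_path("getrm_cyp2d6_calls.tsv")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = ["sample", "consensus", *CALLERS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"call matrix lacks columns: {missing}")
    if "annotations" not in df.columns:
        df["annotations"] = ""
    return df


def _parse_annotations(text: str) -> dict:
    """Decode the fixture's annotation tokens."""
    out = {"attach": {}, "dup_unassigned": set(), "alternates": [], "notes": {}}
    for token in filter(None, (t.strip() for t in str(text).split(";"))):
        if token.startswith("hybrid:"):
            caller, label = token[len("hybrid:"):].split("=")
            out["attach"].setdefault(caller, []).append(label)
        elif token.startswith("dup_unassigned:"):
            out["dup_unassigned"].add(token.split(":", 1)[1])
        elif token.startswith("alt="):
            a, b = token[len("alt="):].split("|")
            out["alternates"].append(frozenset({a, b}))
        elif token.startswith("note:"):
            caller, note = token[len("note:"):].split("=", 1)
            out["notes"][caller] = note
        else:
            raise ValueError(f"unknown annotation token {token!r}")
    return out


def score_table(matrix: Optional[pd.DataFrame] = None) -> tuple[dict[str, int], pd.DataFrame]:
    """Score every caller column of a call matrix against its consensus.

    Returns ``(totals, verdicts)``: correct-call totals per caller and a
    per-sample verdict table with reasons.
    """
    if matrix is None:
        matrix = load_call_matrix()
    rows = []
    for _, row in matrix.iterrows():
        ann = _parse_annotations(row.get("annotations", ""))
        for caller in CALLERS:
            verdict = score_call(
                row[caller], row["consensus"],
                alternates=ann["alternates"],
                attach=ann["attach"].get(caller, ()),
                dup_unassigned=caller in ann["dup_unassigned"],
            )
            rows.append({"sample": row["sample"], "caller": caller,
                         "call": row[caller], "consensus": row["consensus"],
                         "correct": verdict.correct, "reason": verdict.reason})
    verdicts = pd.DataFrame(rows)
    totals = {c: int(verdicts.loc[verdicts["caller"] == c, "correct"].sum()) for c in CALLERS}
    return totals, verdicts
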