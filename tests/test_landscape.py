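"""Allele-frequency aggregation, MAF bins, wildtype inference and CC-Wilson CIs."""

import numpy as np
import pandas as pd
import pytest
from oracles import wilson_cc_reference

from pgxkit.landscape import (
    build_gene_landscape,
    cyp2d6_function_share,
    dpwg_fraction,
    infer_wildtype,
    load_inhouse_cyp2d6,
    maf_bin,
    summarize_cohort,
    wilson_cc_interval,
)


class TestWilson:
    def test_boundaries(self):
        assert wilson_cc_interval(0, 10)[0] == 0.0
        assert wilson_cc_interval(10, 10)[1] == 1.0

    @pytest.mark.parametrize("x,n", [(5, 10), (1, 10), (0, 10), (10, 10), (1, 1094),
                                     (50, 1094), (1023, 1094), (7, 100), (250, 500)])
    def test_matches_independent_reference(self, x, n):
        got = wilson_cc_interval(x, n)
        ref = wilson_cc_reference(x, n)
        assert got[0] == pytest.approx(ref[0], abs=1e-6)
        assert got[1] == pytest.approx(ref[1], abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_cc_interval(5, 0)
        with pytest.raises(ValueError):
            wilson_cc_interval(-1, 10)
        with pytest.raises(ValueError):
            wilson_cc_interval(11, 10)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.5])
    def test_empirical_coverage_conservative(self, p):
        """Over 2,000 binomial draws the 95% CC interval covers p >= 93%."""
        rng = np.random.default_rng(2024)
        n = 200
        draws = rng.binomial(n, p, size=2000)
        intervals = {x: wilson_cc_interval(int(x), n) for x in np.unique(draws)}
        covered = sum(intervals[x][0] <= p <= intervals[x][1] for x in draws)
        assert covered / 2000 >= 0.93


class TestMafBin:
    @pytest.mark.parametrize(
        ("ac", "an", "expected"),
        [
            (1, 1094, "rare"),       # singleton in a 547-genome cohort, ~0.091%
            (60, 1000, "common"),
            (1, 1000, "low"),        # exactly 0.1% sits in the middle bin
            (50, 1000, "low"),       # exactly 5% sits in the middle bin
            (51, 1000, "common"),
            (1023, 1094, "common"),  # majority allele binned by its minor frequency
            (1093, 1094, "rare"),
            (0, 1000, "rare"),
        ],
    )
    def test_binning(self, ac, an, expected):
        assert maf_bin(ac, an) == expected

    def test_zero_an_is_error(self):
        with pytest.raises(ValueError):
            maf_bin(0, 0)

    def test_agrees_with_bruteforce_oracle_on_grid(self):
        def oracle(ac, an):
            maf = min(ac, an - ac) / an
            if maf > 0.05:
                return "common"
            if maf >= 0.001:
                return "low"
            return "rare"

        an = 1094
        for ac in range(0, an + 1, 7):
            assert maf_bin(ac, an) == oracle(ac, an)


class TestInferWildtype:
    def test_subtraction(self):
        assert infer_wildtype(1094, [100, 50]) == (944, False)

    def test_overflow_floors_at_zero(self):
        assert infer_wildtype(100, [80, 40]) == (0, True)

    def test_empty_input_requires_an(self):
        assert infer_wildtype(1094, []) == (1094, False)
        with pytest.raises(ValueError):
            infer_wildtype(0, [])


class TestGeneLandscape:
    def test_conservation_on_synthetic_cohort(self, classified500, panel):
        for gene in panel.genes:
            gl = build_gene_landscape(gene, classified500)
            assert int(gl.table["ac"].sum()) == gl.an
            assert gl.table["freq"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_wildtype_not_most_frequent_for_cyp3a5(self, classified500):
        """A majority variant allele leaves *1 as a minority inferred allele."""
        gl = build_gene_landscape("CYP3A5", classified500)
        top = gl.table.loc[gl.table["freq"].idxmax(), "allele"]
        assert top == "*3"
        assert gl.wildtype_row["freq"] < 0.5

    def test_overflow_flagged_not_fatal(self):
        df = pd.DataFrame([
            {"chrom": "1", "pos": 1, "ref": "A", "alt": "T", "gene": "G1",
             "star_label": "*2", "ac": 70, "an": 100, "category": "dpwg", "novelty": "n_a"},
            {"chrom": "1", "pos": 2, "ref": "A", "alt": "T", "gene": "G1",
             "star_label": "*3", "ac": 60, "an": 100, "category": "dpwg", "novelty": "n_a"},
        ])
        gl = build_gene_landscape("G1", df)
        assert gl.wildtype_overflow
        assert gl.wildtype_row["ac"] == 0


class TestCohortSummary:
    def test_empty_cohort_all_zero(self):
        empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "gene", "star_label",
                                      "ac", "an", "category", "novelty"]).astype({"ac": int})
        table = summarize_cohort(empty)
        assert (table["n_variants"] == 0).all()
        assert (table["n_alleles"] == 0).all()

    def test_bin_counts_match_generator_truth(self, cohort500, classified500):
        _, cohort, _ = cohort500
        table = summarize_cohort(classified500).set_index(["group", "maf_bin"])
        truth = cohort.truth_sites
        detected = truth[truth["ac"] > 0]
        novel = detected[detected["novelty"] == "novel"]
        assert table.loc[("novel_lof_missense", "total"), "n_variants"] == len(novel)
        expected_bins = novel.apply(lambda r: maf_bin(int(r["ac"]), int(r["an"])), axis=1)
        for b in ("rare", "low", "common"):
            assert table.loc[("novel_lof_missense", b), "n_variants"] == (expected_bins == b).sum()
        assert table.loc[("dpwg", "total"), "n_variants"] == \
            (detected["category"] == "dpwg").sum()


class TestDpwgFraction:
    def test_all_dpwg_is_100(self):
        df = pd.DataFrame([{"gene": "G", "ac": 5, "an": 10, "category": "dpwg", "novelty": "n_a"}])
        assert dpwg_fraction(df)[0] == 100.0

    def test_no_dpwg_is_0(self):
        df = pd.DataFrame([{"gene": "G", "ac": 5, "an": 10, "category": "lof", "novelty": "novel"}])
        assert dpwg_fraction(df)[0] == 0.0

    def test_no_alleles_is_error(self):
        df = pd.DataFrame([{"gene": "G", "ac": 0, "an": 10, "category": "dpwg", "novelty": "n_a"}])
        with pytest.raises(ValueError):
            dpwg_fraction(df)

    def test_synthetic_cohort_close_to_generator_truth(self, cohort500, classified500):
        _, cohort, _ = cohort500
        truth = cohort.truth_sites
        det = truth[truth["ac"] > 0]
        expected = 100.0 * det.loc[det["category"] == "dpwg", "ac"].sum() / det["ac"].sum()
        observed, per_gene = dpwg_fraction(classified500)
        assert observed == pytest.approx(expected, abs=1e-9)
        assert observed > 95.0  # known/common panel alleles dominate
        assert set(per_gene.index) <= set(truth["gene"].unique())


class TestCyp2d6Share:
    def test_bundled_share_rounds_to_thirty_percent(self):
        share = cyp2d6_function_share()
        df, an = load_inhouse_cyp2d6()
        impaired = df.loc[df["function_class"].isin(["decreased", "no_function"]), "count"].sum()
        assert share == pytest.approx(100.0 * impaired / an)
        assert round(share / 10) * 10 == 30

    def test_explicit_counts(self):
        share = cyp2d6_function_share({"*4": 10, "*1": 90}, {"*4": "no_function", "*1": "normal"}, an=100)
        assert share == 10.0

    def test_explicit_counts_require_functions_and_an(self):
        with pytest.raises(ValueError):
            cyp2d6_function_share({"*4": 1})
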