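"""DE filters, Fisher exact test vs exhaustive enumeration, enrichment
ratios, overlaps, TPM and the bootstrap median CI."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agestrat import (
    AgeAssignment,
    CountsMatrix,
    DEFlagTable,
    ExpressionTable,
    ValidationError,
    enrichment_table,
    filter_rsd,
    fisher_two_sided,
    flag_de,
    median_ci,
    overlap_counts,
    tpm,
)

# --- independent oracle: exact two-sided Fisher by enumeration --------------


def fisher_oracle(a, b, c, d):
    """Sum exact hypergeometric probabilities of all tables with the same
    margins whose probability is <= that of the observed table, in exact
    rational arithmetic."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)

    def prob(x):
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return float(sum((prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs),
                     Fraction(0)))


# --- DE flagging ------------------------------------------------------------


def _expr(rows, condition="heat"):
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"])
    return ExpressionTable(condition=condition, records=df)


class TestFlagDE:
    @pytest.mark.parametrize(
        "log2fc,fdr,expected",
        [
            (2.3, 1e-4, "up"),
            (1.0, 1e-9, "none"),   # |log2FC| cutoff is strict
            (-3.0, 0.02, "none"),  # FDR cutoff fails
            (-1.5, 0.005, "down"),
            (1.5, 0.01, "none"),   # FDR cutoff is strict
        ],
    )
    def test_strict_cutoffs(self, log2fc, fdr, expected):
        table = flag_de(_expr([("g", log2fc, fdr)]))
        assert table.flags.loc[0, "direction"] == expected
        assert table.flags.loc[0, "is_de"] == (expected != "none")

    @given(
        log2fc=st.floats(-8, 8, allow_nan=False),
        fdr=st.floats(0, 1, allow_nan=False),
        dl=st.floats(0, 1),
        df_=st.floats(0, 0.009),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_relaxing_cutoffs_never_unflags(self, log2fc, fdr, dl, df_):
        strict = flag_de(_expr([("g", log2fc, fdr)]), lfc_cut=1.0, fdr_cut=0.01)
        loose = flag_de(_expr([("g", log2fc, fdr)]), lfc_cut=1.0 - dl,
                        fdr_cut=0.01 + df_)
        if strict.flags.loc[0, "is_de"]:
            assert loose.flags.loc[0, "is_de"]


# --- replicate-noise filter -------------------------------------------------


def _counts(gene_rows, samples):
    genes = [r[0] for r in gene_rows]
    lengths = pd.Series([r[1] for r in gene_rows], index=genes)
    counts = pd.DataFrame([r[2:] for r in gene_rows], index=genes, columns=samples)
    cond = {s: s.split(":")[0] for s in samples}
    rep = {s: s.split(":")[1] for s in samples}
    return CountsMatrix(counts=counts, lengths=lengths,
                        sample_condition=cond, sample_replicate=rep)


class TestFilterRSD:
    SAMPLES = ["ref:1", "ref:2", "ref:3"]

    def test_constant_replicates_retained(self):
        cm = _counts([("g", 100, 10, 10, 10)], self.SAMPLES)
        assert filter_rsd(cm) == {"g"}

    def test_noisy_replicates_removed(self):
        # sd/mean of (0.1, 5, 20) is about 1.24
        cm = _counts([("g", 100, 0.1, 5, 20)], self.SAMPLES)
        assert filter_rsd(cm) == set()

    def test_all_zero_replicates_removed(self):
        cm = _counts([("g", 100, 0, 0, 0)], self.SAMPLES)
        assert filter_rsd(cm) == set()

    def test_single_replicate_is_error(self):
        cm = _counts([("g", 100, 10)], ["ref:1"])
        with pytest.raises(ValidationError, match="ref"):
            filter_rsd(cm)


# --- Fisher exact -----------------------------------------------------------


class TestFisher:
    def test_degenerate_margin_gives_one(self):
        assert fisher_two_sided(0, 10, 0, 90) == 1.0

    def test_perfect_separation(self):
        # only the two extreme tables are as improbable as the observed one
        expected = 2 / comb(20, 10)
        assert fisher_two_sided(10, 0, 0, 10) == pytest.approx(expected, rel=1e-9)

    def test_moderate_table_matches_enumeration(self):
        assert fisher_two_sided(4, 6, 6, 84) == pytest.approx(
            fisher_oracle(4, 6, 6, 84), abs=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 16, size=4)
            assert fisher_two_sided(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9)

    def test_negative_cell_is_error(self):
        with pytest.raises(ValidationError):
            fisher_two_sided(-1, 2, 3, 4)


# --- enrichment table -------------------------------------------------------


def _ages(group_sizes):
    """AgeAssignment list with groups labelled by age, oldest first."""
    labels = ["I", "II", "III", "IV", "V"][: len(group_sizes)]
    out, i = [], 0
    for depth, (label, size) in enumerate(zip(labels, group_sizes)):
        for _ in range(size):
            out.append(AgeAssignment(f"g{i}", label, "origin_single_copy",
                                     len(group_sizes) - depth, 1))
            i += 1
    return out


def _flags(de_genes, all_genes, condition="heat"):
    df = pd.DataFrame({
        "gene": all_genes,
        "is_de": [g in de_genes for g in all_genes],
        "direction": ["up" if g in de_genes else "none" for g in all_genes],
    })
    return DEFlagTable(condition=condition, flags=df)


class TestEnrichmentTable:
    def test_ratio_formula(self):
        ages = _ages([50, 950])
        genes = [a.gene for a in ages]
        de = set(genes[:10]) | set(genes[50:80])  # 10/50 in group I, 40/1000 overall
        table = enrichment_table(ages, _flags(de, genes))
        row = table.set_index("group").loc["I"]
        assert row["ratio"] == pytest.approx((10 / 50) / (40 / 1000))  # = 5.0
        assert row["n_group"] == 50 and row["de_group"] == 10

    def test_weighted_ratio_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sizes = rng.integers(5, 60, size=4)
            ages = _ages(list(sizes))
            genes = [a.gene for a in ages]
            de = {g for g in genes if rng.random() < 0.3}
            if not de:
                de = {genes[0]}
            table = enrichment_table(ages, _flags(de, genes))
            n_total = table["n_group"].sum()
            weighted = (table["n_group"] / n_total * table["ratio"]).sum()
            assert weighted == pytest.approx(1.0, rel=1e-12)

    def test_no_de_genes_reports_nan_ratio(self):
        ages = _ages([10, 10])
        genes = [a.gene for a in ages]
        table = enrichment_table(ages, _flags(set(), genes))
        assert table["ratio"].isna().all()
        assert len(table) == 2  # rows still emitted

    def test_groups_ordered_oldest_first(self):
        ages = _ages([5, 5, 5])
        genes = [a.gene for a in ages]
        table = enrichment_table(ages, _flags({genes[0]}, genes))
        assert table["group"].tolist() == ["I", "II", "III"]

    def test_missing_flags_is_error(self):
        ages = _ages([3])
        with pytest.raises(ValidationError):
            enrichment_table(ages, _flags(set(), ["g0", "g1"]))

    def test_scope_up_counts_only_upregulated(self):
        ages = _ages([4, 4])
        genes = [a.gene for a in ages]
        df = pd.DataFrame({
            "gene": genes,
            "is_de": [True, True] + [False] * 6,
            "direction": ["up", "down"] + ["none"] * 6,
        })
        flags = DEFlagTable(condition="c", flags=df)
        up = enrichment_table(ages, flags, scope="up")
        assert up.set_index("group").loc["I", "de_group"] == 1


class TestOverlapCounts:
    def test_three_condition_example(self):
        flags = [
            _flags({"g1", "g2"}, ["g1", "g2", "g3"], condition="A"),
            _flags({"g1"}, ["g1", "g2", "g3"], condition="B"),
            _flags({"g1", "g3"}, ["g1", "g2", "g3"], condition="C"),
        ]
        counts = overlap_counts(flags, ["g1", "g2", "g3"], direction="up")
        assert counts[("A", "B", "C")] == 1   # g1
        assert counts[("A",)] == 1            # g2
        assert counts[("C",)] == 1            # g3
        union = len({"g1", "g2", "g3"})
        assert sum(counts.values()) == union

    def test_disjoint_sets_have_empty_intersections(self):
        flags = [
            _flags({"g1"}, ["g1", "g2"], condition="A"),
            _flags({"g2"}, ["g1", "g2"], condition="B"),
        ]
        counts = overlap_counts(flags, ["g1", "g2"], direction="up")
        assert counts[("A", "B")] == 0

    def test_matches_per_gene_enumeration(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        sets = {c: {g for g in genes if rng.random() < 0.4} for c in "ABC"}
        flags = [_flags(sets[c], genes, condition=c) for c in "ABC"]
        counts = overlap_counts(flags, genes, direction="up")
        # brute force: classify each gene by its exact membership pattern
        expected: dict[tuple[str, ...], int] = {}
        for g in genes:
            combo = tuple(c for c in "ABC" if g in sets[c])
            if combo:
                expected[combo] = expected.get(combo, 0) + 1
        for combo, cnt in expected.items():
            assert counts[combo] == cnt
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_empty_subset_gives_zeros(self):
        flags = [
            _flags({"g1"}, ["g1"], condition="A"),
            _flags({"g1"}, ["g1"], condition="B"),
        ]
        counts = overlap_counts(flags, [], direction="up")
        assert all(v == 0 for v in counts.values())


class TestTPM:
    def test_two_gene_example(self):
        cm = _counts([("g1", 1000, 100), ("g2", 2000, 200)], ["ref:1"])
        mat = tpm(cm)
        assert mat["ref:1"].tolist() == pytest.approx([500000.0, 500000.0])

    def test_three_gene_example(self):
        # per-base rates 0.2, 0.1, 0.05 -> shares 4/7, 2/7, 1/7 of 1e6
        cm = _counts([("g1", 500, 100), ("g2", 1000, 100), ("g3", 2000, 100)],
                     ["ref:1"])
        mat = tpm(cm)
        assert mat["ref:1"].tolist() == pytest.approx(
            [4e6 / 7, 2e6 / 7, 1e6 / 7])

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(3)
        rows = [(f"g{i}", int(rng.integers(200, 5000)),
                 *rng.integers(0, 500, size=3)) for i in range(30)]
        cm = _counts(rows, ["ref:1", "ref:2", "heat:1"])
        mat = tpm(cm)
        assert np.allclose(mat.sum(axis=0), 1e6, rtol=1e-6)

    def test_empty_sample_is_error(self):
        cm = _counts([("g1", 100, 0)], ["ref:1"])
        with pytest.raises(ValidationError):
            tpm(cm)


class TestMedianCI:
    def test_constant_vector_collapses(self):
        assert median_ci([3.0] * 10, seed=1) == (3.0, 3.0, 3.0)

    def test_single_value_collapses(self):
        assert median_ci([7.5], seed=1) == (7.5, 7.5, 7.5)

    def test_deterministic_given_seed(self):
        x = list(np.random.default_rng(0).normal(size=40))
        assert median_ci(x, seed=99) == median_ci(x, seed=99)

    def test_interval_brackets_the_median(self):
        x = list(np.random.default_rng(1).normal(size=60))
        med, lo, hi = median_ci(x, seed=2)
        assert lo <= med <= hi

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            median_ci([])
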