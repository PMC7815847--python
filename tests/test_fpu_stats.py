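"""FPU arithmetic, the Fisher stand-in test, differential/distal calling and
DE-table intersection."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipaseq.site_calling import ParamSet
from ipaseq.fpu_stats import (
    call_differential_ipa,
    compute_fpu,
    cpsf_dependence,
    differential_site_usage,
    distal_usage_index,
    fpu_records,
    intersect_de_lists,
)

LIBS = ["UD.1", "UD.2", "DF.1", "DF.2"]


def _counts(rows, genes, libs=LIBS):
    counts = pd.DataFrame(
        rows, index=pd.Index([f"s{i}" for i in range(len(rows))], name="site_id"),
        columns=libs, dtype=float,
    )
    return counts, pd.Series(genes, index=counts.index)


# --- FPU -------------------------------------------------------------------


def test_fpu_single_site_gene_is_one():
    counts, genes = _counts([[7, 3, 12, 1]], ["g1"])
    fpu = compute_fpu(counts, genes)
    assert (fpu.loc["s0"] == 1.0).all()


def test_fpu_two_sites():
    counts, genes = _counts([[30] * 4, [70] * 4], ["g1", "g1"])
    fpu = compute_fpu(counts, genes)
    assert (fpu.loc["s0"] == 0.3).all() and (fpu.loc["s1"] == 0.7).all()


def test_fpu_zero_total_gene_is_na_per_library():
    counts, genes = _counts([[0, 5, 0, 2], [0, 5, 8, 2]], ["g1", "g1"])
    fpu = compute_fpu(counts, genes)
    assert fpu["UD.1"].isna().all()          # gene silent in this library only
    assert fpu["DF.1"].tolist() == [0.0, 1.0]


def test_fpu_negative_counts_rejected():
    counts, genes = _counts([[1, -1, 0, 0]], ["g1"])
    with pytest.raises(ValueError, match="negative"):
        compute_fpu(counts, genes)


@settings(max_examples=80, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fpu_normalizes_and_is_scale_invariant(seed):
    """Per gene per library FPU sums to 1; scaling a library's counts by any
    constant leaves every FPU unchanged (internal normalization)."""
    rng = np.random.default_rng(seed)
    n_sites = int(rng.integers(2, 30))
    n_libs = int(rng.integers(1, 5))
    counts = pd.DataFrame(
        rng.integers(0, 200, (n_sites, n_libs)).astype(float),
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"C.{j}" for j in range(n_libs)],
    )
    genes = pd.Series(
        [f"g{int(g)}" for g in rng.integers(0, max(1, n_sites // 2), n_sites)],
        index=counts.index,
    )
    fpu = compute_fpu(counts, genes)
    sums = fpu.groupby(genes).sum(min_count=1)
    totals = counts.groupby(genes).sum()
    expected = totals.where(totals > 0) / totals.where(totals > 0)
    assert np.allclose(sums.fillna(-1), expected.fillna(-1), atol=1e-9)
    scale = float(rng.uniform(0.1, 40))
    scaled = counts.copy()
    scaled.iloc[:, 0] *= scale
    fpu2 = compute_fpu(scaled, genes)
    assert np.allclose(fpu.fillna(-1), fpu2.fillna(-1), atol=1e-12)


def test_fpu_records_long_format():
    counts, genes = _counts([[30] * 4, [70] * 4], ["g1", "g1"])
    long = fpu_records(counts, genes)
    assert set(long.columns) == {"site_id", "gene_id", "library", "count", "gene_total", "fpu"}
    assert len(long) == 8
    row = long[(long.site_id == "s1") & (long.library == "UD.1")].iloc[0]
    assert row.fpu == 0.7 and row.gene_total == 100


# --- Fisher stand-in vs full enumeration -----------------------------------


def _fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the same margins whose probability <= P(observed)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    lo, hi = max(0, col1 - row2), min(col1, row1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def test_fisher_pvalues_match_enumeration_oracle():
    rng = np.random.default_rng(0)
    for _ in range(40):
        a, b = int(rng.integers(0, 25)), int(rng.integers(1, 25))
        c, d = int(rng.integers(0, 25)), int(rng.integers(1, 25))
        counts, genes = _counts(
            [[a, 0, c, 0], [b, 0, d, 0]], ["g1", "g1"]
        )
        diff = differential_site_usage(counts, genes, "UD", "DF")
        expected = _fisher_enumeration(a, b, c, d)
        assert diff.loc["s0", "p_value"] == pytest.approx(expected, rel=1e-9)


# --- differential usage ----------------------------------------------------


def test_differential_null_case():
    counts, genes = _counts([[10, 10, 10, 10], [90, 90, 90, 90]], ["g1", "g1"])
    diff = differential_site_usage(counts, genes, "UD", "DF")
    assert diff.loc["s0", "fc_threads"] == pytest.approx(1.0)
    assert diff.loc["s0", "p_value"] == pytest.approx(1.0)


def test_differential_shift_detected():
    counts, genes = _counts([[10, 10, 40, 40], [90, 90, 60, 60]], ["g1", "g1"])
    diff = differential_site_usage(counts, genes, "UD", "DF")
    assert diff.loc["s0", "fc_threads"] == pytest.approx(4.0, rel=1e-2)
    assert diff.loc["s0", "p_value"] < 0.01
    assert diff.loc["s0", "direction"] == "up"


def test_differential_one_condition_flagged():
    counts, genes = _counts([[0, 0, 20, 20], [0, 0, 80, 80]], ["g1", "g1"])
    diff = differential_site_usage(counts, genes, "UD", "DF")
    assert bool(diff.loc["s0", "one_condition"])
    assert diff.loc["s0", "fc_threads"] > 1  # eps-floored ratio


def test_differential_requires_both_conditions():
    counts, genes = _counts([[1, 1, 1, 1]], ["g1"])
    with pytest.raises(ValueError, match="KD"):
        differential_site_usage(counts, genes, "UD", "KD")


# --- IpA calling with RNA-seq validation -----------------------------------


def _site_table():
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "position": [100, 500],
            "strand": ["+", "+"],
            "gene_id": ["g1", "g1"],
            "category": ["intron", "utr3"],
        },
        index=pd.Index(["s0", "s1"], name="site_id"),
    )


def _window_counts(w, up, down):
    return pd.DataFrame(
        {"window_count": [w, 0], "upstream_count": [up, 0], "downstream_count": [down, 0]},
        index=pd.Index(["s0", "s1"], name="site_id"),
    )


def test_ipa_call_requires_rnaseq_agreement():
    """A 3x FPU change without a matching RNA-seq shift is not called, and the
    per-criterion flag shows which rule failed."""
    counts, genes = _counts([[30, 30, 10, 10], [70, 70, 90, 90]], ["g1", "g1"])
    diff = differential_site_usage(counts, genes, "UD", "DF")
    windows = {"UD": _window_counts(100, 80, 10), "DF": _window_counts(85, 70, 9)}
    result = call_differential_ipa(diff, _site_table(), windows, "UD", "DF", ParamSet())
    assert list(result.calls.index) == ["s0"]  # only the intronic site evaluated
    call = result.calls.loc["s0"]
    assert call["fc_threads_pass"] and not call["fc_rnaseq_pass"]
    assert not call["passed"]


def test_ipa_call_passes_with_concordant_rnaseq():
    counts, genes = _counts([[30, 30, 10, 10], [70, 70, 90, 90]], ["g1", "g1"])
    diff = differential_site_usage(counts, genes, "UD", "DF")
    windows = {"UD": _window_counts(90, 80, 10), "DF": _window_counts(30, 25, 8)}
    result = call_differential_ipa(diff, _site_table(), windows, "UD", "DF", ParamSet())
    call = result.calls.loc["s0"]
    assert call["passed"] and call["direction"] == "down"
    assert call["upstream_count"] == 80 and call["downstream_count"] == 10


def test_ipa_call_unevaluable_without_windows():
    counts, genes = _counts([[30, 30, 10, 10], [70, 70, 90, 90]], ["g1", "g1"])
    diff = differential_site_usage(counts, genes, "UD", "DF")
    empty = _window_counts(0, 0, 0).drop(index=["s0", "s1"])
    result = call_differential_ipa(diff, _site_table(), {"UD": empty, "DF": empty},
                                   "UD", "DF", ParamSet())
    assert len(result.calls) == 0 and result.n_unevaluable == 1


# --- CPSF dependence -------------------------------------------------------


def _calls_frame(direction="down"):
    return pd.DataFrame(
        {
            "gene_id": ["g1"],
            "direction": [direction],
            "fc_threads": [0.3 if direction == "down" else 3.0],
            "passed": [True],
        },
        index=pd.Index(["s0"], name="site_id"),
    )


def _kd_frame(fc):
    return pd.DataFrame({"fc_threads": [fc]}, index=pd.Index(["s0"], name="site_id"))


def test_cpsf_same_direction_retained():
    out = cpsf_dependence(_calls_frame("down"), _kd_frame(1 / 1.6), ParamSet())
    assert list(out.index) == ["s0"]
    assert out.loc["s0", "fc_knockdown"] == pytest.approx(1 / 1.6)


def test_cpsf_opposite_direction_excluded():
    out = cpsf_dependence(_calls_frame("down"), _kd_frame(1.8), ParamSet())
    assert len(out) == 0


def test_cpsf_missing_site_excluded():
    kd = _kd_frame(0.5).drop(index="s0")
    out = cpsf_dependence(_calls_frame("down"), kd, ParamSet())
    assert len(out) == 0


# --- distal usage ----------------------------------------------------------


def _utr_table(strand="+"):
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 2,
            "position": [100, 400],
            "strand": [strand] * 2,
            "gene_id": ["g1"] * 2,
            "category": ["utr3"] * 2,
        },
        index=pd.Index(["prox", "dist"], name="site_id"),
    )


def test_distal_fraction_shift_classified_lengthened():
    """Distal fractions 0.2 (A) vs 0.5 (B) give fc 2.5 -> lengthened."""
    counts = pd.DataFrame(
        {"UD.1": [80, 20], "UD.2": [80, 20], "DF.1": [50, 50], "DF.2": [50, 50]},
        index=pd.Index(["prox", "dist"], name="site_id"), dtype=float,
    )
    out = distal_usage_index(counts, _utr_table(), "UD", "DF", ParamSet())
    row = out.loc["g1"]
    assert row["distal_site"] == "dist"
    assert row["fc"] == pytest.approx(2.5, rel=1e-3)
    assert row["classification"] == "lengthened"


def test_distal_equal_fractions_unchanged():
    counts = pd.DataFrame(
        {lib: [50, 50] for lib in LIBS},
        index=pd.Index(["prox", "dist"], name="site_id"), dtype=float,
    )
    out = distal_usage_index(counts, _utr_table(), "UD", "DF", ParamSet())
    assert out.loc["g1", "classification"] == "unchanged"


def test_distal_minus_strand_uses_smallest_position():
    counts = pd.DataFrame(
        {lib: [20, 80] for lib in LIBS},
        index=pd.Index(["prox", "dist"], name="site_id"), dtype=float,
    )
    out = distal_usage_index(counts, _utr_table(strand="-"), "UD", "DF", ParamSet())
    assert out.loc["g1", "distal_site"] == "prox"  # 5'-most genomic = 3'-most on '-'


def test_distal_single_site_gene_excluded():
    table = _utr_table().iloc[[0]]
    counts = pd.DataFrame({lib: [50] for lib in LIBS},
                          index=pd.Index(["prox"], name="site_id"), dtype=float)
    out = distal_usage_index(counts, table, "UD", "DF", ParamSet())
    assert len(out) == 0


# --- DE-table intersection -------------------------------------------------


def _de(genes, log2fcs, pvals):
    return pd.DataFrame({"gene": genes, "log2fc": log2fcs, "pvalue": pvals})


def test_intersect_disjoint_tables():
    a = _de(["g1"], [2.0], [0.01])
    b = _de(["g2"], [2.0], [0.01])
    shared, venn = intersect_de_lists(a, b)
    assert shared == [] and venn["shared"] == 0


def test_intersect_toy_tables():
    a = _de(["g1", "g2", "g3", "g4", "g5"], [2.0, -2.0, 1.5, 0.5, 3.0],
            [0.01, 0.001, 0.01, 0.01, 0.06])
    b = _de(["g1", "g2", "g3", "g4", "g5"], [1.7, -1.2, 2.0, 2.0, 2.0],
            [0.04, 0.01, 0.2, 0.01, 0.01])
    shared, venn = intersect_de_lists(a, b)
    # g1: passes both; g2: passes both, same (negative) direction; g3: fc too
    # small in a and p too big in b; g4: fc too small in a; g5: p 0.06 in a
    assert shared == ["g1", "g2"]
    assert venn["shared"] == 2


def test_intersect_direction_must_agree():
    a = _de(["g1"], [2.0], [0.01])
    b = _de(["g1"], [-2.0], [0.01])
    shared, _ = intersect_de_lists(a, b)
    assert shared == []


def test_intersect_malformed_table_reports_columns():
    with pytest.raises(ValueError, match="pvalue"):
        intersect_de_lists(_de(["g"], [1.0], [0.1]).drop(columns="pvalue"),
                           _de(["g"], [1.0], [0.1]))
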