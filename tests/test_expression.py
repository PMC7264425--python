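"""FPKM arithmetic, change classification, BH adjustment, ddCt folds."""

import io
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from nlr_methylome.expression import (
    CtObservation,
    apply_de_filter,
    benjamini_hochberg,
    classify_expression_change,
    classify_expression_table,
    ddct_fold_change,
    ddct_table,
    fpkm,
    merge_fpkm_tables,
    read_ct_table,
)
import pandas as pd


@pytest.mark.parametrize(
    "count,length,total,expected",
    [
        (100, 1000, 10**7, 10.0),
        (0, 1234, 10**6, 0.0),
        (1, 500, 2 * 10**6, 1.0),
    ],
)
def test_fpkm_unit_arithmetic(count, length, total, expected):
    assert fpkm(count, length, total) == pytest.approx(expected)


def test_fpkm_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        fpkm(1, 0, 10**6)
    with pytest.raises(ValueError):
        fpkm(1, 1000, 0)
    with pytest.raises(ValueError):
        fpkm(-1, 1000, 10**6)


@settings(derandomize=True, max_examples=100)
@given(
    count=st.integers(0, 10**6),
    length=st.integers(1, 10**5),
    total=st.integers(1, 10**9),
    k=st.integers(1, 20),
)
def test_fpkm_linearity(count, length, total, k):
    assert fpkm(k * count, length, total) == pytest.approx(k * fpkm(count, length, total))
    assert fpkm(count, k * length, total) * k == pytest.approx(fpkm(count, length, total))


@pytest.mark.parametrize(
    "wt,mut,expected",
    [
        (2.0, 3.94, "up"),  # ratio 1.97
        (2.0, 1.9, "unchanged"),  # ratio 0.95, inside (0.9, 1.1)
        (0.5, 0.6, "not_expressed"),  # neither genotype reaches 1 FPKM
        (2.0, 2.2, "up"),  # ratio exactly 1.1: inclusive
        (2.0, 1.8, "down"),  # ratio exactly 0.9: inclusive
        (0.0, 5.0, "up"),  # silent wild type, expressed mutant
        (5.0, 0.0, "down"),
        (0.0, 0.0, "not_expressed"),
    ],
)
def test_expression_change_labels(wt, mut, expected):
    assert classify_expression_change(wt, mut) == expected


def test_expression_change_validation():
    with pytest.raises(ValueError):
        classify_expression_change(-1.0, 2.0)
    with pytest.raises(ValueError):
        classify_expression_change(1.0, 2.0, up_ratio=0.8)


@settings(derandomize=True, max_examples=200)
@given(wt=st.floats(0.01, 100), mut=st.floats(0.01, 100))
def test_swapping_genotypes_mirrors_labels(wt, mut):
    # keep away from the exact ratio boundaries, where the two float
    # divisions m/w and w/m can round to opposite sides
    assume(abs(mut / wt - 1.1) > 1e-6 and abs(mut / wt - 0.9) > 1e-6)
    forward = classify_expression_change(wt, mut, min_fpkm=0.0, up_ratio=1.1, down_ratio=0.9)
    backward = classify_expression_change(mut, wt, min_fpkm=0.0, up_ratio=1 / 0.9, down_ratio=1 / 1.1)
    mirror = {"up": "down", "down": "up", "unchanged": "unchanged"}
    assert backward == mirror[forward]


def test_classify_table_records_undefined_ratio_for_silent_wt():
    table = pd.DataFrame(
        {"gene_id": ["a", "b"], "fpkm_wt": [0.0, 2.0], "fpkm_mut": [3.0, 3.94]}
    )
    out = classify_expression_table(table)
    assert list(out["change"]) == ["up", "up"]
    assert math.isnan(out["ratio"].iloc[0])
    assert out["ratio"].iloc[1] == pytest.approx(1.97)


def bh_oracle(pvalues):
    """Brute-force step-up adjustment, independent of the implementation."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def test_benjamini_hochberg_worked_examples():
    np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])
    np.testing.assert_allclose(benjamini_hochberg([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


def test_benjamini_hochberg_matches_brute_force_oracle(rng):
    for _ in range(50):
        pvals = rng.random(int(rng.integers(1, 40))).tolist()
        np.testing.assert_allclose(benjamini_hochberg(pvals), bh_oracle(pvals), atol=1e-12)


@pytest.mark.parametrize(
    "fc,fdr,expected",
    [
        (2.5, 0.01, True),
        (2.0, 0.01, False),  # "more than twofold" is strict
        (0.3, 0.04, True),  # reciprocal direction
        (0.5, 0.04, False),
        (3.0, 0.05, True),  # FDR bound is inclusive
        (3.0, 0.051, False),
    ],
)
def test_de_filter(fc, fdr, expected):
    assert apply_de_filter(fc, fdr) is expected


def test_de_filter_rejects_nonpositive_fold_change():
    with pytest.raises(ValueError):
        apply_de_filter(0.0, 0.01)


def obs(t_test, r_test, t_ctrl, r_ctrl):
    return CtObservation("tx", (t_test,), (r_test,), (t_ctrl,), (r_ctrl,))


@pytest.mark.parametrize(
    "cts,expected",
    [
        ((25, 20, 24, 20), 0.5),  # ddCt = +1
        ((24, 20, 24, 20), 1.0),
        ((23, 20, 25, 20), 4.0),  # ddCt = 3 - 5 = -2
    ],
)
def test_ddct_worked_examples(cts, expected):
    assert ddct_fold_change(obs(*cts)) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(
    cts=st.tuples(*[st.floats(10, 35)] * 4),
    shift=st.floats(-5, 5),
)
def test_ddct_invariant_to_constant_cycle_offset(cts, shift):
    base = ddct_fold_change(obs(*cts))
    shifted = ddct_fold_change(obs(*(c + shift for c in cts)))
    assert shifted == pytest.approx(base, rel=1e-9)


def test_ddct_aggregates_replicates_by_mean():
    observation = CtObservation("tx", (25.0, 25.2, 24.8), (20.0,), (24.0,), (20.0,))
    assert ddct_fold_change(observation) == pytest.approx(0.5)


def test_ct_observation_requires_replicates_and_finite_values():
    with pytest.raises(ValueError):
        CtObservation("tx", (), (20.0,), (24.0,), (20.0,))
    with pytest.raises(ValueError):
        CtObservation("tx", (-1.0,), (20.0,), (24.0,), (20.0,))


def test_ct_table_roundtrip():
    csv = io.StringIO(
        "transcript_id,condition,role,replicate,ct\n"
        "tx1,test,target,1,25\n"
        "tx1,test,reference,1,20\n"
        "tx1,control,target,1,24\n"
        "tx1,control,reference,1,20\n"
    )
    table = ddct_table(read_ct_table(csv))
    assert table["fold_change"].iloc[0] == pytest.approx(0.5)


def test_merge_fpkm_tables_intersects_genes():
    wt = pd.DataFrame({"gene_id": ["a", "b"], "fpkm": [1.0, 2.0]})
    mut = pd.DataFrame({"gene_id": ["b", "c"], "fpkm": [3.0, 4.0]})
    merged = merge_fpkm_tables(wt, mut)
    assert list(merged["gene_id"]) == ["b"]
    assert merged.iloc[0]["fpkm_wt"] == 2.0 and merged.iloc[0]["fpkm_mut"] == 3.0
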