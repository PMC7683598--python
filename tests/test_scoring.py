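"""Alteration scoring: Z-score conventions, CDS lengths, mutation burden, CNA calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coregscan.scoring import (
    cds_length,
    cna_alteration_calls,
    median_zscores,
    mutation_burden,
    tumor_normal_zscores,
)


def _toy_expression():
    # 3 genes x (4 tumors + 4 normals); all values > 0 so everything is detected
    tumors = [f"T{i}" for i in range(4)]
    normals = [f"N{i}" for i in range(4)]
    data = {
        "gA": [5, 2.5, 1, 9, 1, 2, 3, 4],
        "gB": [10, 10, 10, 10, 10, 10, 10, 10],  # zero normal variance
        "gC": [8, 6, 7, 5, 4, 6, 8, 2],
    }
    return pd.DataFrame(data, index=tumors + normals).T, tumors, normals


def test_tumor_normal_zscores_match_hand_computation():
    expr, tumors, normals = _toy_expression()
    with pytest.warns(UserWarning, match="zero normal-sample variance"):
        z = tumor_normal_zscores(expr, tumors, normals)
    # gA normals 1,2,3,4: mean 2.5, sd (ddof=1) = 1.2909944
    sd = np.std([1, 2, 3, 4], ddof=1)
    assert z.loc["gA", "T0"] == pytest.approx((5 - 2.5) / sd)
    assert z.loc["gA", "T1"] == pytest.approx(0.0)  # tumor equals the normal mean
    # gC normals 4,6,8,2: mean 5, sd = 2.5819889
    assert z.loc["gC", "T3"] == pytest.approx((5 - 5) / np.std([4, 6, 8, 2], ddof=1))
    assert "gB" not in z.index  # zero-variance gene dropped


def test_detectability_boundary_is_strict_at_80_percent():
    # one gene detected in 79/100 samples, another in 80/100
    cols = [f"S{i}" for i in range(100)]
    low = [1.0] * 79 + [0.0] * 21
    ok = [1.0] * 80 + [0.0] * 20
    expr = pd.DataFrame([low, ok], index=["g79", "g80"], columns=cols)
    expr.loc["g79", cols[:4]] = [2, 3, 4, 5]  # give normals some variance
    expr.loc["g80", cols[:4]] = [2, 3, 4, 5]
    z = tumor_normal_zscores(expr, cols[4:], cols[:4], detect_threshold=0.80)
    assert "g80" in z.index and "g79" not in z.index


def test_tumor_normal_needs_two_normals():
    expr, tumors, normals = _toy_expression()
    with pytest.raises(ValueError, match="at least 2 normal"):
        tumor_normal_zscores(expr, tumors, normals[:1])


def test_tumor_normal_convergence_to_true_z(rng):
    # invariant: tumor at mu + k*sigma gives Z -> k as n_normals grows
    n = 10_000
    normals = [f"N{i}" for i in range(n)]
    values = 5.0 + 2.0 * rng.standard_normal(n)
    k = 1.7
    expr = pd.DataFrame([np.concatenate([[5.0 + k * 2.0], values])],
                        index=["g"], columns=["T0"] + normals)
    z = tumor_normal_zscores(expr, ["T0"], normals)
    assert z.loc["g", "T0"] == pytest.approx(k, abs=0.05)


def test_median_zscores_hand_example_and_equivariance():
    row = pd.DataFrame([[1, 2, 3, 4, 5]], index=["g"], columns=list("abcde"))
    z = median_zscores(row.astype(float))
    sd = np.std([1, 2, 3, 4, 5], ddof=1)
    assert z.loc["g", "e"] == pytest.approx((5 - 3) / sd)
    permuted = median_zscores(row[list("dceab")].astype(float))
    assert (permuted[list("abcde")].to_numpy() == z.to_numpy()).all()


def test_median_zscores_drops_constant_rows_and_errors_when_all_constant():
    m = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["flat", "ok"], dtype=float)
    with pytest.warns(UserWarning, match="constant"):
        z = median_zscores(m)
    assert list(z.index) == ["ok"]
    with pytest.raises(ValueError, match="constant"):
        median_zscores(m.loc[["flat"]])


@pytest.mark.parametrize(
    "exons, expected",
    [
        ([(100, 200)], 100),
        ([(100, 200), (150, 250)], 150),  # overlapping alternative exons merge
        ([(0, 10), (20, 30)], 20),
    ],
)
def test_cds_length_examples(exons, expected):
    assert cds_length(exons) == expected


@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 120)).map(
            lambda t: (t[0], t[0] + t[1])
        ),
        min_size=1,
        max_size=12,
    )
)
def test_cds_length_equals_base_membership_count(exons):
    covered = set()
    for s, e in exons:
        covered.update(range(s, e))
    assert cds_length(exons) == len(covered)


def test_cds_length_rejects_inverted_interval():
    with pytest.raises(ValueError, match="inverted"):
        cds_length([(10, 5)])


def _models(lengths):
    rows = []
    for gene, L in lengths.items():
        rows.append((gene, "chr1", "+", 0, "0", str(L)))
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss", "exon_starts", "exon_ends"])


def test_mutation_burden_formula_and_zero_genes():
    models = _models({"gA": 1000, "gB": 500})
    muts = pd.DataFrame(
        {"gene": ["gA"] * 4, "sample": ["s1", "s1", "s2", "s3"], "position": [1] * 4}
    )
    burden = mutation_burden(muts, models, n_tumors=10)
    assert burden.loc["gA", "normalized_score"] == pytest.approx(np.sqrt(4 / 1000))
    assert burden.loc["gB", "raw_count"] == 0 and burden.loc["gB", "normalized_score"] == 0


def test_mutation_burden_sample_split_invariance_and_length_scaling():
    muts1 = pd.DataFrame({"gene": ["g"] * 6, "sample": ["s1"] * 6, "position": range(6)})
    muts2 = muts1.assign(sample=["s1", "s2"] * 3)
    b1 = mutation_burden(muts1, _models({"g": 900}), n_tumors=10)
    b2 = mutation_burden(muts2, _models({"g": 900}), n_tumors=10)
    assert b1.loc["g", "normalized_score"] == b2.loc["g", "normalized_score"]
    b_double = mutation_burden(muts1, _models({"g": 1800}), n_tumors=10)
    assert b_double.loc["g", "normalized_score"] == pytest.approx(
        b1.loc["g", "normalized_score"] / np.sqrt(2)
    )


def test_mutation_burden_missing_model_errors():
    with pytest.raises(KeyError, match="ghost"):
        mutation_burden(
            pd.DataFrame({"gene": ["ghost"], "sample": ["s"], "position": [1]}),
            _models({"g": 100}),
            n_tumors=1,
        )


def test_cna_calls_match_brute_force(rng):
    codes = rng.integers(-2, 3, size=(5, 5))
    cna = pd.DataFrame(codes)
    amp, dele = cna_alteration_calls(cna, level="deep")
    assert amp.to_numpy().sum() == (codes == 2).sum()
    assert dele.to_numpy().sum() == (codes == -2).sum()
    amp_any, del_any = cna_alteration_calls(cna, level="any")
    assert amp_any.to_numpy().sum() == (codes >= 1).sum()
    assert del_any.to_numpy().sum() == (codes <= -1).sum()
    # -2 under deep is a deletion, never an amplification
    cna.iloc[0, 0] = -2
    amp, dele = cna_alteration_calls(cna, level="deep")
    assert dele.iloc[0, 0] and not amp.iloc[0, 0]


def test_cna_rejects_non_gistic_codes():
    with pytest.raises(ValueError, match="non-GISTIC"):
        cna_alteration_calls(pd.DataFrame([[3]]))
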