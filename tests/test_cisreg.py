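"""Peak-gene linking, state overlap, quartile DE, KS profiles, cascade algebra."""

import numpy as np
import pandas as pd
import pytest

from coregscan.cisreg import (
    annotate_peaks_to_genes,
    bound_and_regulated,
    correlation_profile,
    deg_significant,
    overlap_states,
    quartile_de,
)
from coregscan.pipeline import noiseless_de_table


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _models(rows):
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "strand", "tss", "exon_starts", "exon_ends"]
    )


def _states(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def brute_force_links(peaks, models, window):
    """O(n*m) all-pairs oracle for peak-TSS distances."""
    out = set()
    for p in peaks.itertuples(index=False):
        for g in models.itertuples(index=False):
            if p.chrom != g.chrom:
                continue
            a = int(g.tss)
            if p.start <= a < p.end:
                d = 0
            elif a < p.start:
                d = p.start - a
            else:
                d = a - (p.end - 1)
            if d <= window:
                out.add((p.name, g.gene, d))
    return out


def brute_force_state_overlap(peaks, states, min_overlap):
    kept = {}
    for p in peaks.itertuples(index=False):
        labels = set()
        for s in states.itertuples(index=False):
            if p.chrom != s.chrom:
                continue
            ov = min(p.end, s.end) - max(p.start, s.start)
            if ov >= min_overlap:
                labels.add(s.state)
        if labels:
            kept[p.name] = ";".join(sorted(labels))
    return kept


def test_window_boundary_linked_at_100kb_not_at_100kb_plus_one():
    models = _models([("g1", "chr1", "+", 200_000, "200000", "200100")])
    peaks = _peaks(
        [
            ("chr1", 99_900, 100_000, "exactly_100kb"),   # edge base 99,999 -> d = 100,001? no:
            ("chr1", 99_899, 99_999, "at_100001"),
            ("chr1", 199_990, 200_010, "overlapping_tss"),
        ]
    )
    links = annotate_peaks_to_genes(peaks, models, window=100_000)
    by_peak = links.set_index("peak")["distance"].to_dict()
    # nearest edge of [99900, 100000) is base 99,999: distance 100,001 -> no link
    assert "exactly_100kb" not in by_peak
    # peak [99899, 99999): nearest base 99,998 -> distance 100,002 -> no link
    assert "at_100001" not in by_peak
    assert by_peak["overlapping_tss"] == 0
    # a peak whose nearest base is exactly 100,000 away is linked
    peaks2 = _peaks([("chr1", 99_901, 100_001, "d_100000")])
    links2 = annotate_peaks_to_genes(peaks2, models, window=100_000)
    assert links2.set_index("peak")["distance"].to_dict() == {"d_100000": 100_000}


def test_links_match_brute_force_on_random_fixtures(rng):
    for _ in range(20):
        n_peaks = int(rng.integers(1, 60))
        n_genes = int(rng.integers(1, 20))
        peaks = _peaks(
            [
                ("chr1", s, s + int(rng.integers(50, 500)), f"p{i}")
                for i, s in enumerate(rng.integers(0, 800_000, size=n_peaks))
            ]
        )
        models = _models(
            [
                (f"g{i}", "chr1", "+", int(t), str(int(t)), str(int(t) + 100))
                for i, t in enumerate(rng.integers(0, 800_000, size=n_genes))
            ]
        )
        window = int(rng.choice([1_000, 50_000, 100_000]))
        got = {
            (r.peak, r.gene, r.distance)
            for r in annotate_peaks_to_genes(peaks, models, window).itertuples(index=False)
        }
        assert got == brute_force_links(peaks, models, window)


def test_larger_window_never_removes_links(rng):
    peaks = _peaks(
        [("chr1", s, s + 200, f"p{i}") for i, s in enumerate(rng.integers(0, 500_000, 30))]
    )
    models = _models(
        [(f"g{i}", "chr1", "+", int(t), str(int(t)), str(int(t) + 10))
         for i, t in enumerate(rng.integers(0, 500_000, 15))]
    )
    small = annotate_peaks_to_genes(peaks, models, window=10_000)
    large = annotate_peaks_to_genes(peaks, models, window=60_000)
    small_pairs = set(zip(small["peak"], small["gene"]))
    large_pairs = set(zip(large["peak"], large["gene"]))
    assert small_pairs <= large_pairs


def test_chromosome_handling():
    models = _models([("g1", "chr1", "+", 100, "100", "200")])
    orphan = _peaks([("chr9", 50, 150, "p1")])
    with pytest.warns(UserWarning, match="skipping"):
        links = annotate_peaks_to_genes(orphan, models, window=1000)
    assert links.empty
    mixed = _peaks([("1", 50, 150, "p1")])
    with pytest.raises(ValueError, match="naming"):
        annotate_peaks_to_genes(mixed, models, window=1000)


def test_state_overlap_half_open_boundaries():
    states = _states([("chr1", 200, 300, "Promoter")])
    touching = _peaks([("chr1", 100, 200, "touching")])
    assert overlap_states(touching, states).empty  # 0 bp shared
    one_bp = _peaks([("chr1", 100, 201, "one_bp")])
    kept = overlap_states(one_bp, states)
    assert list(kept["name"]) == ["one_bp"]
    assert kept.iloc[0]["states"] == "Promoter"


def test_state_overlap_matches_brute_force(rng):
    for _ in range(20):
        peaks = _peaks(
            [("chr1", s, s + int(rng.integers(10, 400)), f"p{i}")
             for i, s in enumerate(rng.integers(0, 50_000, size=int(rng.integers(1, 40))))]
        )
        states = _states(
            [("chr1", s, s + int(rng.integers(10, 600)), f"S{int(rng.integers(0, 4))}")
             for s in rng.integers(0, 50_000, size=int(rng.integers(1, 30)))]
        )
        min_ov = int(rng.choice([1, 5, 50]))
        kept = overlap_states(peaks, states, min_overlap=min_ov)
        expected = brute_force_state_overlap(peaks, states, min_ov)
        assert dict(zip(kept["name"], kept["states"])) == expected
        # raising min_overlap never adds peaks
        stricter = overlap_states(peaks, states, min_overlap=min_ov + 10)
        assert set(stricter["name"]) <= set(kept["name"])


def _cohort_matrix(rng, n_genes=200, n_samples=100):
    genes = ["IDX"] + [f"g{i}" for i in range(n_genes - 1)]
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=genes,
        columns=[f"s{i}" for i in range(n_samples)],
    )


def test_quartile_de_null_calibration_and_symmetry(rng):
    expr = _cohort_matrix(rng, n_genes=1000, n_samples=100)
    de = quartile_de(expr, "IDX")
    assert 0.02 <= (de["p"] < 0.05).mean() <= 0.09
    assert (de["FDR"] >= de["p"] - 1e-12).all()
    assert "IDX" not in set(de["gene"])
    # negating the index gene swaps the quartile groups exactly
    flipped = expr.copy()
    flipped.loc["IDX"] *= -1
    de2 = quartile_de(flipped, "IDX")
    merged = de.merge(de2, on="gene", suffixes=("_a", "_b"))
    assert np.allclose(merged["logFC_a"], -merged["logFC_b"])
    assert np.allclose(merged["p_a"], merged["p_b"])


def test_quartile_de_recovers_planted_shift(rng):
    expr = _cohort_matrix(rng, n_genes=300, n_samples=100)
    from coregscan.survival import quartile_groups

    hi = quartile_groups(expr.loc["IDX"])
    hi_samples = hi.index[hi == "upper"]
    expr.loc["planted", :] = rng.normal(size=expr.shape[1])
    expr.loc["planted", hi_samples] += 2.0
    de = quartile_de(expr, "IDX").set_index("gene")
    assert de.loc["planted", "FDR"] < 0.05
    assert de.loc["planted", "logFC"] > 0


def test_correlation_profile_identical_sets_and_ecdf_oracle(rng):
    expr = _cohort_matrix(rng, n_genes=120, n_samples=60)
    gene_set = [f"g{i}" for i in range(40)]
    prof_same = correlation_profile(expr, "IDX", gene_set, gene_set)
    assert prof_same.ks_statistic == 0.0 and prof_same.ks_p == 1.0
    background = [f"g{i}" for i in range(40, 110)]
    prof = correlation_profile(expr, "IDX", gene_set, background)
    # brute-force sup-difference of the two ECDFs
    a = prof.correlations.loc[gene_set].to_numpy()
    b = prof.correlations.loc[background].to_numpy()
    grid = np.concatenate([a, b])
    sup = max(
        abs((a <= x).mean() - (b <= x).mean()) for x in grid
    )
    assert prof.ks_statistic == pytest.approx(sup)


def test_correlation_profile_direction_and_constant_rows(rng):
    expr = _cohort_matrix(rng, n_genes=60, n_samples=50)
    # make a gene set genuinely co-expressed with the index gene
    for i in range(10):
        expr.loc[f"g{i}"] = expr.loc["IDX"] + 0.5 * rng.normal(size=expr.shape[1])
    expr.loc["g59"] = 1.0  # constant -> dropped
    prof = correlation_profile(
        expr, "IDX", [f"g{i}" for i in range(10)], [f"g{i}" for i in range(10, 60)]
    )
    assert prof.shift_direction == "more positive"
    assert prof.n_dropped_constant == 1


def test_bound_and_regulated_is_three_set_intersection(rng):
    genes = [f"g{i}" for i in range(40)]
    links = pd.DataFrame(
        {"peak": [f"p{i}" for i in range(25)], "gene": genes[:25], "distance": 10}
    )
    kd_sig = set(rng.choice(genes, 15, replace=False))
    co_sig = set(rng.choice(genes, 15, replace=False))
    de_kd = noiseless_de_table(genes, kd_sig, rng, "kd")
    de_co = noiseless_de_table(genes, co_sig, rng, "cohort")
    network = bound_and_regulated(links, de_kd, de_co)
    assert set(network["gene"]) == set(genes[:25]) & kd_sig & co_sig
    # sorted by |cohort logFC| and truncatable
    top = bound_and_regulated(links, de_kd, de_co, top_k=2)
    assert len(top) <= 2
    # empty inputs give an empty network, not an error
    assert bound_and_regulated(links, de_kd.iloc[0:0], de_co).empty


def test_deg_significance_rules():
    de = pd.DataFrame(
        {"gene": ["a", "b", "c"], "logFC": [2.0, 1.0, -2.0], "p": [1e-4] * 3,
         "FDR": [1e-3, 1e-3, 0.2]}
    )
    assert set(deg_significant(de, "fdr05_lfc1.5")["gene"]) == {"a"}
    assert set(deg_significant(de, "fdr05")["gene"]) == {"a", "b"}
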