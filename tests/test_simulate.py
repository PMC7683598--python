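"""Synthetic-data generator: truth consistency, null behavior, determinism."""

import numpy as np
import pandas as pd
import pytest

from coregscan.simulate import (
    CistromeConfig,
    KnockdownDEConfig,
    PlantedEffect,
    SimConfig,
    simulate_cistrome,
    simulate_cohort,
    simulate_knockdown_de,
    write_cohort,
)


def _true_z(cohort, cfg):
    """Tumor Z-scores against the empirical normal-sample distribution."""
    normals = cohort.normal_expression
    center, scale = normals.mean(axis=1), normals.std(axis=1, ddof=1)
    return cohort.tumor_expression.sub(center, axis=0).div(scale, axis=0)


def test_null_cohort_class_means_near_zero(small_cohort):
    cohort, truth = small_cohort
    assert not truth.gene_shifts
    z = _true_z(cohort, None)
    for cls in ("TF", "COA", "COR", "MIXED"):
        genes = [g for g, c in cohort.class_assignment.items() if c == cls]
        cells = z.loc[genes].to_numpy().ravel()
        se = cells.std(ddof=1) / np.sqrt(cells.size)
        assert abs(cells.mean()) < 3 * se + 0.01


def test_planted_shift_recovered_from_affected_cells():
    eff = PlantedEffect("COA", 0.30, 0.40, -1.0, "expression")
    cfg = SimConfig(n_genes=600, n_tumors=120, n_normals=40,
                    planted_effects=(eff,), seed=5)
    cohort, truth = simulate_cohort(cfg)
    z = _true_z(cohort, cfg)
    genes = sorted(truth.affected_genes["expression"])
    tumors = sorted(truth.affected_tumors["expression"])
    cells = z.loc[genes, tumors].to_numpy().ravel()
    se = cells.std(ddof=1) / np.sqrt(cells.size)
    assert cells.mean() == pytest.approx(-1.0, abs=3 * se + 0.02)
    assert all(truth.gene_shifts[g] == -1.0 for g in genes)
    # affected genes all belong to the target class
    assert {cohort.class_assignment[g] for g in genes} == {"COA"}


def test_cna_and_mutation_effects_enrich_affected_cells():
    cfg = SimConfig(
        n_genes=400, n_tumors=100, n_normals=10,
        planted_effects=(
            PlantedEffect("COR", 0.5, 0.5, -0.5, "cna"),
            PlantedEffect("COA", 0.5, 0.5, 20.0, "mutation"),
        ),
        mutation_rate_per_bp=2e-6,
        seed=7,
    )
    cohort, truth = simulate_cohort(cfg)
    cna_genes = sorted(truth.affected_genes["cna"])
    cna_tumors = sorted(truth.affected_tumors["cna"])
    affected_frac = (cohort.cna.loc[cna_genes, cna_tumors] == -2).to_numpy().mean()
    background_frac = (cohort.cna.drop(index=cna_genes) == -2).to_numpy().mean()
    assert affected_frac > 10 * background_frac
    mut_genes = truth.affected_genes["mutation"]
    per_gene = cohort.mutations.groupby("gene").size()
    hit_rate = per_gene.reindex(sorted(mut_genes), fill_value=0).mean()
    other = per_gene.reindex(
        [g for g in cohort.expression.index if g not in mut_genes], fill_value=0
    ).mean()
    assert hit_rate > 3 * other


def test_null_survival_halves_rarely_significant():
    from lifelines.statistics import logrank_test

    n_sig = 0
    for seed in range(50):
        cfg = SimConfig(n_genes=20, n_tumors=60, n_normals=4, seed=seed)
        cohort, _ = simulate_cohort(cfg)
        clin = cohort.clinical
        half = len(clin) // 2
        res = logrank_test(
            clin["time"][:half], clin["time"][half:],
            event_observed_A=clin["event"][:half],
            event_observed_B=clin["event"][half:],
        )
        n_sig += res.p_value < 0.05
    assert n_sig <= 5  # non-significant in >= 90% of 50 seeds


def test_mutation_rate_per_sample_invariant_to_cohort_size():
    from coregscan.simulate import exon_union_lengths

    # expected mutations per sample = rate * sum of CDS lengths, whatever
    # the cohort size; check both cohorts against the Poisson expectation
    for n_tumors in (100, 200):
        cfg = SimConfig(n_genes=300, n_tumors=n_tumors, n_normals=4,
                        mutation_rate_per_bp=2e-6, seed=3)
        cohort, _ = simulate_cohort(cfg)
        lam = 2e-6 * exon_union_lengths(cohort.gene_models).sum()
        expected = lam * n_tumors
        assert abs(len(cohort.mutations) - expected) < 4 * np.sqrt(expected)


def test_cohort_determinism_byte_identical(tmp_path):
    cfg = SimConfig(n_genes=100, n_tumors=30, n_normals=10,
                    planted_effects=(PlantedEffect("COR", 0.5, 0.5, -1.0),),
                    hazard_coefficients={"G00000": 0.5}, seed=21)
    for d in ("a", "b"):
        cohort, truth = simulate_cohort(cfg)
        write_cohort(cohort, truth, tmp_path / d)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_infeasible_effect_errors():
    with pytest.raises(ValueError):
        PlantedEffect("COA", 1.5, 0.5, -1.0)
    cfg = SimConfig(
        n_genes=100, n_tumors=10, n_normals=4,
        class_fractions={"TF": 0.1, "COA": 0.0, "COR": 0.1, "MIXED": 0.1},
        planted_effects=(PlantedEffect("COA", 0.5, 0.5, -1.0),),
        seed=0,
    )
    with pytest.raises(ValueError, match="COA"):
        simulate_cohort(cfg)


def test_shared_structure_seed_aligns_cohorts():
    eff = (PlantedEffect("COR", 0.4, 0.5, -2.0),)
    a, ta = simulate_cohort(SimConfig(n_genes=300, n_tumors=40, n_normals=10,
                                      planted_effects=eff, seed=1))
    b, tb = simulate_cohort(SimConfig(n_genes=300, n_tumors=40, n_normals=10,
                                      planted_effects=eff, seed=2, structure_seed=1))
    assert a.class_assignment == b.class_assignment
    assert ta.affected_genes == tb.affected_genes
    # but the sampled data differ
    assert not a.expression.equals(b.expression)


def test_cistrome_truth_genes_are_bound_in_states():
    from coregscan.cisreg import annotate_peaks_to_genes, overlap_states

    cfg = CistromeConfig(seed=4)
    peaks, states, models, truth = simulate_cistrome(cfg)
    retained = overlap_states(peaks, states)
    links = annotate_peaks_to_genes(retained, models, window=cfg.window)
    assert truth.bound_and_regulated_genes <= set(links["gene"])
    # decoys exist in both flavors: removed by state filter or by distance
    assert len(retained) < len(peaks)
    assert set(retained["name"]) - set(links["peak"])


def test_cistrome_zero_truth_genes():
    peaks, states, models, truth = simulate_cistrome(
        CistromeConfig(n_truth_genes=0, n_decoy_far=5, n_decoy_no_state=5, seed=0)
    )
    assert truth.bound_and_regulated_genes == set()
    assert len(peaks) == 10


def test_knockdown_de_skew_matches_configuration():
    cfg = KnockdownDEConfig(seed=9)
    table, truth = simulate_knockdown_de(cfg)
    down = table[table["gene"].isin(truth.de_down_genes)]["logFC"]
    up = table[table["gene"].isin(truth.de_up_genes)]["logFC"]
    assert len(down) == 1993 and len(up) == 1607
    assert down.mean() == pytest.approx(-1.11, abs=3 * down.std() / np.sqrt(len(down)))
    assert up.mean() == pytest.approx(0.83, abs=3 * up.std() / np.sqrt(len(up)))
    assert (table["FDR"] >= table["p"] - 1e-12).all()
    # determinism
    table2, _ = simulate_knockdown_de(KnockdownDEConfig(seed=9))
    pd.testing.assert_frame_equal(table, table2)


def test_knockdown_de_zero_degs_and_validation():
    from coregscan.cisreg import deg_significant

    table, truth = simulate_knockdown_de(KnockdownDEConfig(n_genes=100, n_down=0, n_up=0, seed=0))
    assert truth.de_down_genes == set() and truth.de_up_genes == set()
    assert deg_significant(table).empty
    with pytest.raises(ValueError):
        KnockdownDEConfig(n_genes=10, n_down=8, n_up=8)
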