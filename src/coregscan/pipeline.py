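"""End-to-end synthetic study: simulate -> score -> family-test -> filter ->
intersect -> survival screen -> cis-regulation cascade.

The default configuration plants (i) a broad corepressor down-shift (Z
shift -1 in 30% of COR genes, 40% of tumors), (ii) a strong focal
down-shift (Z shift -3 in 10% of COR genes, 60% of tumors) that survives
the frequent-alteration filter and drives tumor clustering, (iii) a
deep-deletion excess in COR genes, and (iv) one expression-linked hazard
gene. A second cohort with an independent seed but the same planted-effect
configuration supports cross-cohort intersection. The cistrome cascade
runs on its own synthetic chromosome with 20 planted bound-and-regulated
genes and noiseless significance flags.

Every stage writes a TSV under the output directory and contributes to one
machine-readable run report (JSON).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cisreg, filtering, scoring, survival
from .catalog import classify_genes, restrict_to_detected
from .family import panel_to_frame, run_family_panel
from .simulate import (
    CistromeConfig,
    KnockdownDEConfig,
    PlantedEffect,
    SimConfig,
    simulate_cistrome,
    simulate_cohort,
    simulate_knockdown_de,
    write_cohort,
)

__all__ = ["default_pipeline_config", "run_synthetic_pipeline"]


def default_pipeline_config(seed: int, n_genes: int = 6000, n_tumors: int = 200,
                            n_normals: int = 40) -> SimConfig:
    """Study configuration for one cohort of the synthetic pipeline."""
    hazard_gene = "G00000"
    return SimConfig(
        n_genes=n_genes,
        n_tumors=n_tumors,
        n_normals=n_normals,
        planted_effects=(
            PlantedEffect("COR", 0.30, 0.40, -1.0, "expression"),
            PlantedEffect("COR", 0.10, 0.60, -3.0, "expression"),
            PlantedEffect("COR", 0.30, 0.30, -0.3, "cna"),
        ),
        hazard_coefficients={hazard_gene: 1.0},
        seed=seed,
    )


def noiseless_de_table(genes, sig_genes, rng, contrast):
    """DE table in which exactly ``sig_genes`` are significant (FDR 1e-6, |logFC| 2)."""
    sig = set(sig_genes)
    sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in genes}
    return pd.DataFrame(
        {
            "gene": list(genes),
            "logFC": [2.0 * sign[g] if g in sig else 0.0 for g in genes],
            "p": [1e-8 if g in sig else 0.9 for g in genes],
            "FDR": [1e-6 if g in sig else 0.95 for g in genes],
            "contrast": contrast,
        }
    )


def run_synthetic_pipeline(
    seed: int,
    outdir: str | Path,
    B: int = 5000,
    n_genes: int = 6000,
    n_tumors: int = 200,
    n_normals: int = 40,
    write_inputs: bool = False,
) -> dict:
    """Run the whole synthetic study and return the machine-readable report."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "B": B, "n_genes": n_genes, "n_tumors": n_tumors}

    # -- simulate two cohorts ---------------------------------------------
    cfg_a = default_pipeline_config(seed, n_genes, n_tumors, n_normals)
    cfg_b = default_pipeline_config(seed + 1, n_genes, n_tumors, n_normals)
    # same genes altered in both cohorts, independent sampling noise
    cfg_b.structure_seed = seed
    cohort_a, truth_a = simulate_cohort(cfg_a)
    cohort_b, truth_b = simulate_cohort(cfg_b)
    if write_inputs:
        write_cohort(cohort_a, truth_a, outdir / "cohort_a")
        write_cohort(cohort_b, truth_b, outdir / "cohort_b")

    # -- catalog from the emitted annotations ------------------------------
    catalog = classify_genes(cohort_a.annotations, [cohort_a.tf_list])
    report["catalog_counts"] = {c.value: n for c, n in catalog.counts.items()}

    # -- scores -------------------------------------------------------------
    z_a = scoring.tumor_normal_zscores(
        cohort_a.expression, cohort_a.tumor_samples, cohort_a.normal_samples
    )
    z_b = scoring.tumor_normal_zscores(
        cohort_b.expression, cohort_b.tumor_samples, cohort_b.normal_samples
    )
    catalog_a = restrict_to_detected(catalog, z_a.index)
    _, deletions = scoring.cna_alteration_calls(cohort_a.cna, level="deep")
    del_fraction = deletions.mean(axis=1)
    burden = scoring.mutation_burden(
        cohort_a.mutations, cohort_a.gene_models, n_tumors=len(cohort_a.tumor_samples)
    )

    # -- family panel (mean-Z statistic; expression down/up + CNA deletions) -
    score_vectors = {
        ("cohort_a", "expression"): z_a.mean(axis=1),
        ("cohort_a", "cna_deletion_fraction"): del_fraction,
        ("cohort_a", "mutation_burden"): burden["normalized_score"],
    }
    class_sets = {
        c: catalog_a.genes_in(c) for c in ("TF", "COA", "COR", "MIXED")
    }
    panel = run_family_panel(
        score_vectors, class_sets, directions=("down", "up"), statistic="mean",
        B=B, seed=seed,
    )
    panel_df = panel_to_frame(panel)
    panel_df.to_csv(outdir / "family_panel.tsv", sep="\t", index=False)
    cor_down = panel_df.query(
        "`class` == 'COR' and data_type == 'expression' and direction == 'down'"
    ).iloc[0]
    cor_up = panel_df.query(
        "`class` == 'COR' and data_type == 'expression' and direction == 'up'"
    ).iloc[0]
    report["family"] = {
        "planted_class_down_p": float(cor_down["empirical_p"]),
        "planted_class_down_q": float(cor_down["q"]),
        "planted_class_up_q": float(cor_up["q"]),
        "min_attainable_p": 1.0 / (B + 1),
    }

    # -- frequent-alteration filter + clustering + outcome association -----
    spec = filtering.FILTER_PRESETS["figure-2.5"]
    filtered_a = filtering.frequent_alteration_filter(z_a, spec)
    filtered_b = filtering.frequent_alteration_filter(z_b, spec)
    (outdir / "filtered_genes_a.txt").write_text("\n".join(filtered_a) + "\n")
    labels = filtering.cluster_tumors(z_a.loc[filtered_a], k=2)
    grade = filtering.categorize_at_median(
        cohort_a.clinical.set_index("sample")["grade"].astype(float)
    )
    assoc = filtering.cluster_outcome_association(labels, grade)
    report["filter"] = {
        "n_filtered_a": len(filtered_a),
        "n_filtered_b": len(filtered_b),
        "chi_squared": assoc.chi_squared,
        "chi_squared_p": assoc.p,
        "report": assoc.report(),
    }

    # -- cross-cohort intersection -----------------------------------------
    inter = filtering.intersect_cohorts({"cohort_a": filtered_a, "cohort_b": filtered_b})
    inter.membership.to_csv(outdir / "intersection_membership.tsv", sep="\t")
    report["intersection"] = {
        "union_size": inter.union_size,
        "common_to_both": inter.size_of("cohort_a", "cohort_b"),
    }

    # -- survival screen ----------------------------------------------------
    hazard_gene = next(iter(cfg_a.hazard_coefficients))
    rng = np.random.default_rng(seed)
    others = [g for g in z_a.index if g != hazard_gene]
    screened = [hazard_gene] + sorted(
        rng.choice(np.array(others), size=99, replace=False).tolist()
    )
    screen = survival.logrank_screen(
        cohort_a.tumor_expression, cohort_a.clinical, genes=screened
    )
    screen.to_csv(outdir / "survival_screen.tsv", sep="\t", index=False)
    ranked = screen.dropna(subset=["q"]).sort_values(["q", "p"], kind="mergesort")
    report["survival"] = {
        "n_screened": int(screen["p"].notna().sum()),
        "hazard_gene": hazard_gene,
        "hazard_gene_rank": int((ranked["gene"] == hazard_gene).to_numpy().argmax()) + 1,
        "hazard_gene_q": float(screen.set_index("gene").loc[hazard_gene, "q"]),
    }

    # -- cis-regulation cascade ---------------------------------------------
    cis_cfg = CistromeConfig(seed=seed)
    peaks, states, cis_models, cis_truth = simulate_cistrome(cis_cfg)
    retained = cisreg.overlap_states(peaks, states, min_overlap=1)
    links = cisreg.annotate_peaks_to_genes(retained, cis_models, window=cis_cfg.window)
    de_rng = np.random.default_rng(seed + 7)
    truth_genes = sorted(cis_truth.bound_and_regulated_genes)
    de_kd = noiseless_de_table(cis_models["gene"], truth_genes, de_rng, "knockdown_vs_control")
    de_cohort = noiseless_de_table(cis_models["gene"], truth_genes, de_rng, "index_quartile")
    network = cisreg.bound_and_regulated(links, de_kd, de_cohort)
    network.to_csv(outdir / "bound_and_regulated.tsv", sep="\t", index=False)
    report["cascade"] = {
        "n_peaks": int(len(peaks)),
        "n_peaks_in_states": int(len(retained)),
        "n_links": int(len(links)),
        "n_planted": len(truth_genes),
        "n_recovered": int(len(network)),
        "recovered_exactly": sorted(network["gene"]) == truth_genes,
        "n_up": int((network["logFC_cohort"] > 0).sum()),
        "n_down": int((network["logFC_cohort"] < 0).sum()),
    }

    # -- correlation profile (co-shifted genes vs background) ----------------
    strong = sorted(
        g for g, s in truth_a.gene_shifts.items() if s <= -3.0 and g in z_a.index
    )
    index_gene = strong[0]
    gene_set = strong[1:]
    background = sorted(
        rng.choice(
            np.array([g for g in z_a.index if g not in truth_a.gene_shifts]),
            size=200, replace=False,
        ).tolist()
    )
    profile = cisreg.correlation_profile(
        cohort_a.tumor_expression.loc[
            sorted(set(gene_set) | set(background) | {index_gene})
        ],
        index_gene,
        gene_set,
        background,
    )
    report["correlation"] = {
        "index_gene": index_gene,
        "ks_D": profile.ks_statistic,
        "ks_p": profile.ks_p,
        "shift_direction": profile.shift_direction,
    }

    # -- knockdown DE generator at its defaults ------------------------------
    de_table, de_truth = simulate_knockdown_de(KnockdownDEConfig(seed=seed))
    down = de_table[de_table["gene"].isin(de_truth.de_down_genes)]
    up = de_table[de_table["gene"].isin(de_truth.de_up_genes)]
    report["knockdown_de"] = {
        "n_down": int(len(down)),
        "n_up": int(len(up)),
        "mean_logFC_down": float(down["logFC"].mean()),
        "mean_logFC_up": float(up["logFC"].mean()),
    }

    report["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
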