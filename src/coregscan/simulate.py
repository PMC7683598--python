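"""Synthetic multi-omic cohorts and cistrome fixtures with known planted structure.

The generator emulates the inputs of a tumor-cohort gene-family study:

* a matched expression / copy-number / mutation / clinical cohort with a
  configurable number of tumors and adjacent-normal samples;
* class labels (TF, COA, COR, MIXED) for a configurable fraction of genes,
  emitted both as ground truth and as the annotation tables and canonical
  TF lists the catalog builder consumes;
* planted class-level effects (expression down-shifts in Z-score units,
  copy-number deep events, mutation-rate multipliers) restricted to a
  fraction of the class genes and a fraction of the tumors;
* exponential proportional-hazards survival times driven by the expression
  of designated hazard genes, with independent censoring;
* a synthetic cistrome — binding peaks, labeled chromatin-state segments
  and gene models on one synthetic chromosome — in which a designated
  subset of genes is bound-and-regulated by construction;
* a knockdown differential-expression table with a configurable down/up
  skew.

Everything is driven by one integer seed and is byte-reproducible: the same
config written twice produces identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import GeneClass, TfList

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "CistromeConfig",
    "KnockdownDEConfig",
    "Cohort",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_cistrome",
    "simulate_knockdown_de",
    "write_cohort",
    "write_cistrome",
    "write_de_table",
]

_DATA_TYPES = ("expression", "cna", "mutation")

#: Genome-wide class fractions implied by catalog sizes of 2662 TFs, 766
#: coactivators, 599 corepressors and 511 mixed coregulators over a ~20k
#: protein-coding genome.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "TF": 0.133,
    "COA": 0.038,
    "COR": 0.030,
    "MIXED": 0.026,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A class-level alteration planted into one data type.

    ``effect_size`` is interpreted per data type: an additive shift in
    normal-sample SD units for expression (so affected cells have true mean
    Z equal to ``effect_size``); the probability that an affected cell
    carries a GISTIC deep event (sign picks deletion vs amplification) for
    copy number; a multiplicative factor on the per-bp Poisson mutation
    rate for mutation.
    """

    target_class: str
    affected_gene_fraction: float
    affected_tumor_fraction: float
    effect_size: float
    data_type: str = "expression"

    def __post_init__(self) -> None:
        if not (0 < self.affected_gene_fraction <= 1):
            raise ValueError("affected_gene_fraction must be in (0, 1]")
        if not (0 < self.affected_tumor_fraction <= 1):
            raise ValueError("affected_tumor_fraction must be in (0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.data_type not in _DATA_TYPES:
            raise ValueError(f"data_type must be one of {_DATA_TYPES}")
        if self.data_type == "mutation" and self.effect_size <= 0:
            raise ValueError("mutation effects are rate multipliers and must be > 0")
        if self.data_type == "cna" and not (0 < abs(self.effect_size) <= 1):
            raise ValueError("cna effects are deep-event probabilities; |effect| in (0, 1]")
        GeneClass(self.target_class)  # validates


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults mimic a local-tumor cohort: ~500 tumors with ~50 matched
    normals, a somatic exome rate of one mutation per Mb per tumor, and a
    GISTIC code background dominated by neutral calls.
    """

    n_genes: int = 10_000
    n_tumors: int = 498
    n_normals: int = 52
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    planted_effects: Sequence[PlantedEffect] = ()
    mutation_rate_per_bp: float = 1e-6
    gistic_background_probs: Sequence[float] = (0.01, 0.09, 0.80, 0.09, 0.01)
    hazard_coefficients: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 1500.0  # per day; median null progression ~2.8 y
    censoring_rate: float = 0.6
    seed: int = 0
    #: Seed for the cohort-invariant structure (class labels, gene models,
    #: which genes carry each planted effect). Two configs sharing a
    #: structure_seed but differing in seed emulate independent cohorts of
    #: the same disease, with the same genes altered in both.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumors, self.n_normals) <= 0:
            raise ValueError("n_genes, n_tumors and n_normals must be positive")
        fr = dict(self.class_fractions)
        if any(not (0 <= f <= 1) for f in fr.values()) or sum(fr.values()) > 1 + 1e-9:
            raise ValueError("class fractions must lie in [0, 1] and sum to <= 1")
        probs = np.asarray(self.gistic_background_probs, dtype=float)
        if probs.shape != (5,) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("gistic_background_probs must be a 5-vector summing to 1")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class Cohort:
    """One matched multi-omic cohort.

    ``expression`` holds genes x samples raw values covering both tumors
    and normals; ``clinical`` has one row per tumor with survival time,
    event flag, grade and the paired-normal sample (if any).
    """

    expression: pd.DataFrame
    tumor_samples: list[str]
    normal_samples: list[str]
    cna: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    gene_models: pd.DataFrame
    class_assignment: dict[str, str]
    annotations: pd.DataFrame
    tf_list: TfList

    @property
    def tumor_expression(self) -> pd.DataFrame:
        return self.expression[self.tumor_samples]

    @property
    def normal_expression(self) -> pd.DataFrame:
        return self.expression[self.normal_samples]


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated dataset, for recovery tests."""

    seed: int
    affected_genes: dict[str, set[str]] = field(default_factory=dict)  # data_type -> genes
    affected_tumors: dict[str, set[str]] = field(default_factory=dict)
    gene_shifts: dict[str, float] = field(default_factory=dict)  # expression only
    hazard_coefficients: dict[str, float] = field(default_factory=dict)
    bound_and_regulated_genes: set[str] = field(default_factory=set)
    de_down_genes: set[str] = field(default_factory=set)
    de_up_genes: set[str] = field(default_factory=set)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "affected_genes": {k: sorted(v) for k, v in self.affected_genes.items()},
            "affected_tumors": {k: sorted(v) for k, v in self.affected_tumors.items()},
            "gene_shifts": {g: float(s) for g, s in sorted(self.gene_shifts.items())},
            "hazard_coefficients": {
                g: float(c) for g, c in sorted(self.hazard_coefficients.items())
            },
            "bound_and_regulated_genes": sorted(self.bound_and_regulated_genes),
            "de_down_genes": sorted(self.de_down_genes),
            "de_up_genes": sorted(self.de_up_genes),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _assign_classes(
    genes: list[str], fractions: Mapping[str, float], rng: np.random.Generator
) -> dict[str, str]:
    """Randomly assign class labels to genes according to the fractions."""
    order = rng.permutation(len(genes))
    assignment: dict[str, str] = {}
    cursor = 0
    for cls in ("TF", "COA", "COR", "MIXED"):
        k = int(round(fractions.get(cls, 0.0) * len(genes)))
        for idx in order[cursor : cursor + k]:
            assignment[genes[idx]] = cls
        cursor += k
    return assignment


def _make_gene_models(
    genes: list[str], rng: np.random.Generator, chrom: str = "chr1", spacing: int = 20_000
) -> pd.DataFrame:
    """Lay genes along one synthetic chromosome with random exon structure."""
    rows = []
    for i, gene in enumerate(genes):
        start = i * spacing + int(rng.integers(0, spacing // 4))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = 1 + int(rng.poisson(4))
        exon_starts, exon_ends = [], []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(80, 300))
            exon_starts.append(pos)
            exon_ends.append(pos + length)
            pos += length + int(rng.integers(100, 1500))
        tss = exon_starts[0] if strand == "+" else exon_ends[-1] - 1
        rows.append(
            (
                gene,
                chrom,
                strand,
                tss,
                ",".join(map(str, exon_starts)),
                ",".join(map(str, exon_ends)),
            )
        )
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "strand", "tss", "exon_starts", "exon_ends"]
    )


def _annotations_from_classes(
    assignment: Mapping[str, str], rng: np.random.Generator
) -> tuple[pd.DataFrame, TfList]:
    """Emit annotation records and a TF list that reproduce the class labels.

    A random tenth of TF genes also receives a positive-regulation term, so
    the catalog builder's TF-over-coregulator precedence is exercised.
    """
    rows = []
    tf_genes = []
    for gene in sorted(assignment):
        cls = assignment[gene]
        if cls == "TF":
            tf_genes.append(gene)
            if rng.random() < 0.1:
                rows.append(
                    (gene, f"SYN:POS:{gene}", "positive regulation of transcription", "positive")
                )
        elif cls == "COA":
            rows.append((gene, f"SYN:COA:{gene}", "transcription co-activator activity", "coactivator"))
        elif cls == "COR":
            rows.append((gene, f"SYN:COR:{gene}", "transcription co-repressor activity", "corepressor"))
        elif cls == "MIXED":
            rows.append(
                (gene, f"SYN:POS:{gene}", "positive regulation of transcription", "positive")
            )
            rows.append(
                (gene, f"SYN:NEG:{gene}", "negative regulation of transcription", "negative")
            )
    annotations = pd.DataFrame(rows, columns=["gene", "term_id", "term_label", "polarity"])
    return annotations, TfList(source="synthetic_canonical", genes=frozenset(tf_genes))


def _pick_affected(
    pool: list[str], fraction: float, rng: np.random.Generator, what: str
) -> list[str]:
    if not pool:
        raise ValueError(f"no {what} available to plant an effect into")
    k = int(round(fraction * len(pool)))
    if k > len(pool):
        raise ValueError(f"infeasible fraction: {k} affected {what} exceed pool of {len(pool)}")
    k = max(k, 1)
    return sorted(rng.choice(np.array(pool), size=k, replace=False).tolist())


def exon_union_lengths(gene_models: pd.DataFrame) -> pd.Series:
    """Per-gene CDS length as the genomic union of exon intervals."""
    from .scoring import cds_length  # local import to avoid a cycle

    out = {}
    for rec in gene_models.itertuples(index=False):
        starts = [int(x) for x in str(rec.exon_starts).split(",")]
        ends = [int(x) for x in str(rec.exon_ends).split(",")]
        out[rec.gene] = cds_length(list(zip(starts, ends)))
    return pd.Series(out, name="cds_length")


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SyntheticTruth]:
    """Generate one matched expression/CNA/mutation/clinical cohort.

    Expression for gene g is N(mu_g, sd_g) in every sample, with planted
    expression effects adding ``effect_size * sd_g`` to affected
    (gene, tumor) cells — so the true tumor-vs-normal Z shift of an
    affected cell is exactly ``effect_size``.  Survival is exponential
    proportional hazards with linear predictor sum(coef_g * Z_g) over the
    configured hazard genes, using the generative (true) standardization.
    """
    rng = np.random.default_rng(config.seed)
    structure_seed = config.structure_seed if config.structure_seed is not None else config.seed
    rng_s = np.random.default_rng(structure_seed)
    genes = _gene_names(config.n_genes)
    tumors = [f"T{i:04d}" for i in range(config.n_tumors)]
    normals = [f"N{i:04d}" for i in range(config.n_normals)]

    assignment = _assign_classes(genes, config.class_fractions, rng_s)
    gene_models = _make_gene_models(genes, rng_s)
    annotations, tf_list = _annotations_from_classes(assignment, rng_s)

    unknown_hazard = set(config.hazard_coefficients) - set(genes)
    if unknown_hazard:
        raise ValueError(f"hazard coefficients reference unknown genes: {sorted(unknown_hazard)[:5]}")

    truth = SyntheticTruth(
        seed=config.seed, hazard_coefficients=dict(config.hazard_coefficients)
    )

    mu = rng.normal(8.0, 2.0, size=config.n_genes)
    sd = rng.uniform(0.5, 2.0, size=config.n_genes)
    n_samples = config.n_tumors + config.n_normals
    values = mu[:, None] + sd[:, None] * rng.standard_normal((config.n_genes, n_samples))

    gene_index = {g: i for i, g in enumerate(genes)}
    tumor_index = {s: j for j, s in enumerate(tumors)}
    class_pools = {
        cls: sorted(g for g, c in assignment.items() if c == cls)
        for cls in ("TF", "COA", "COR", "MIXED")
    }

    # -- planted effects ---------------------------------------------------
    cna_extra: list[tuple[list[str], list[str], float]] = []
    mut_multipliers: list[tuple[list[str], list[str], float]] = []
    for eff in config.planted_effects:
        pool = class_pools[eff.target_class]
        aff_genes = _pick_affected(pool, eff.affected_gene_fraction, rng_s, f"{eff.target_class} genes")
        aff_tumors = _pick_affected(tumors, eff.affected_tumor_fraction, rng, "tumors")
        truth.affected_genes.setdefault(eff.data_type, set()).update(aff_genes)
        truth.affected_tumors.setdefault(eff.data_type, set()).update(aff_tumors)
        gi = [gene_index[g] for g in aff_genes]
        tj = [tumor_index[s] for s in aff_tumors]
        if eff.data_type == "expression":
            values[np.ix_(gi, tj)] += eff.effect_size * sd[gi][:, None]
            for g in aff_genes:
                truth.gene_shifts[g] = truth.gene_shifts.get(g, 0.0) + eff.effect_size
        elif eff.data_type == "cna":
            cna_extra.append((aff_genes, aff_tumors, eff.effect_size))
        else:
            mut_multipliers.append((aff_genes, aff_tumors, eff.effect_size))

    expression = pd.DataFrame(values, index=genes, columns=tumors + normals)

    # -- copy number -------------------------------------------------------
    codes = rng.choice(
        np.array([-2, -1, 0, 1, 2]),
        size=(config.n_genes, config.n_tumors),
        p=np.asarray(config.gistic_background_probs, dtype=float),
    )
    for aff_genes, aff_tumors, effect in cna_extra:
        gi = [gene_index[g] for g in aff_genes]
        tj = [tumor_index[s] for s in aff_tumors]
        hit = rng.random((len(gi), len(tj))) < abs(effect)
        block = codes[np.ix_(gi, tj)]
        block[hit] = -2 if effect < 0 else 2
        codes[np.ix_(gi, tj)] = block
    cna = pd.DataFrame(codes, index=genes, columns=tumors)

    # -- mutations ---------------------------------------------------------
    cds = exon_union_lengths(gene_models).reindex(genes)
    lam = config.mutation_rate_per_bp * cds.to_numpy()[:, None] * np.ones((1, config.n_tumors))
    for aff_genes, aff_tumors, mult in mut_multipliers:
        gi = [gene_index[g] for g in aff_genes]
        tj = [tumor_index[s] for s in aff_tumors]
        lam[np.ix_(gi, tj)] *= mult
    counts = rng.poisson(lam)
    g_idx, s_idx = np.nonzero(counts)
    mut_rows = []
    spans = {
        rec.gene: (int(str(rec.exon_starts).split(",")[0]), int(str(rec.exon_ends).split(",")[-1]))
        for rec in gene_models.itertuples(index=False)
    }
    for gi_, sj in zip(g_idx.tolist(), s_idx.tolist()):
        gene, sample = genes[gi_], tumors[sj]
        lo, hi = spans[gene]
        for _ in range(int(counts[gi_, sj])):
            mut_rows.append(
                (gene, sample, int(rng.integers(lo, hi)), "Missense_Mutation")
            )
    mutations = pd.DataFrame(
        mut_rows, columns=["gene", "sample", "position", "class"]
    ).sort_values(["gene", "sample", "position"], kind="mergesort").reset_index(drop=True)

    # -- survival ----------------------------------------------------------
    eta = np.zeros(config.n_tumors)
    for g, coef in config.hazard_coefficients.items():
        z = (expression.loc[g, tumors].to_numpy() - mu[gene_index[g]]) / sd[gene_index[g]]
        eta += coef * z
    hazard = config.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        cens_rate = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        censor_time = rng.exponential(1.0 / cens_rate, size=config.n_tumors)
    else:
        censor_time = np.full(config.n_tumors, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # grade enriched in tumors carrying the planted expression effect, so
    # cluster/grade association is recoverable
    affected_t = truth.affected_tumors.get("expression", set())
    base_p = np.array([0.35, 0.40, 0.15, 0.10])
    shift_p = np.array([0.15, 0.30, 0.30, 0.25])
    grades = np.array([6, 7, 8, 9])
    grade = np.array(
        [
            rng.choice(grades, p=shift_p if s in affected_t else base_p)
            for s in tumors
        ]
    )
    n_pairs = min(config.n_tumors, config.n_normals)
    pair = [normals[i] if i < n_pairs else "" for i in range(config.n_tumors)]
    clinical = pd.DataFrame(
        {
            "sample": tumors,
            "time": np.round(time, 2),
            "event": event,
            "grade": grade,
            "normal_pair": pair,
        }
    )

    cohort = Cohort(
        expression=expression,
        tumor_samples=tumors,
        normal_samples=normals,
        cna=cna,
        mutations=mutations,
        clinical=clinical,
        gene_models=gene_models,
        class_assignment=assignment,
        annotations=annotations,
        tf_list=tf_list,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# cistrome fixtures
# ---------------------------------------------------------------------------

DEFAULT_STATE_LABELS = (
    "Promoter",
    "Active_Enhancer",
    "Poised_Enhancer",
    "Transcribed",
    "Heterochromatin",
)


@dataclass
class CistromeConfig:
    """Synthetic chromosome layout for peak / chromatin-state fixtures.

    The gene-bearing region is followed by a gene-free tail so that decoy
    peaks can be placed beyond the annotation window of every gene.
    """

    n_genes: int = 60
    n_truth_genes: int = 20
    n_decoy_far: int = 30
    n_decoy_no_state: int = 10
    window: int = 100_000
    gene_spacing: int = 20_000
    peak_width: int = 400
    state_segment: int = 2_000
    state_gap: int = 1_000
    state_labels: Sequence[str] = DEFAULT_STATE_LABELS
    chrom: str = "chrS"
    seed: int = 0

    @property
    def chrom_length(self) -> int:
        return self.n_genes * self.gene_spacing + self.window + 600_000

    def __post_init__(self) -> None:
        if self.n_truth_genes > self.n_genes:
            raise ValueError("more truth genes requested than genes exist")
        if self.window >= self.chrom_length:
            raise ValueError("annotation window is larger than the chromosome")


def simulate_cistrome(
    config: CistromeConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Place peaks, chromatin-state segments and gene models on one chromosome.

    Every truth gene receives at least one peak that lies within the
    annotation window of its TSS and overlaps a state segment by >= 1 bp.
    Decoys are either placed in the gene-free tail beyond the window of all
    genes, or inside state gaps (zero state overlap).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"CG{i:04d}" for i in range(config.n_genes)]
    gene_models = _make_gene_models(
        genes, rng, chrom=config.chrom, spacing=config.gene_spacing
    )
    tss = gene_models.set_index("gene")["tss"].astype(int)

    # tile the whole chromosome: segment, gap, segment, gap ...
    period = config.state_segment + config.state_gap
    seg_rows = []
    pos = 0
    i = 0
    while pos + config.state_segment <= config.chrom_length:
        label = config.state_labels[int(rng.integers(0, len(config.state_labels)))]
        seg_rows.append((config.chrom, pos, pos + config.state_segment, label))
        pos += period
        i += 1
    states = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])

    truth_genes = sorted(
        rng.choice(np.array(genes), size=config.n_truth_genes, replace=False).tolist()
    ) if config.n_truth_genes else []

    peak_rows = []
    pid = 0
    for gene in truth_genes:
        a = int(tss[gene])
        # choose a state segment whose start sits comfortably inside the window
        lo = max(0, a - config.window + config.peak_width + period)
        hi = min(config.chrom_length - period, a + config.window - config.peak_width - period)
        seg_start = (lo // period) * period
        if seg_start < lo:
            seg_start += period
        if seg_start > hi:
            seg_start = (a // period) * period  # fall back to the TSS-local segment
        start = seg_start + int(rng.integers(0, max(1, config.state_segment - config.peak_width)))
        peak_rows.append((config.chrom, start, start + config.peak_width, f"peak_{pid:04d}", 100, "."))
        pid += 1

    gene_region_end = config.n_genes * config.gene_spacing
    far_lo = gene_region_end + config.window + 2 * period
    for _ in range(config.n_decoy_far):
        # inside a state segment (so only the distance filter removes it)
        seg_start = (int(rng.integers(far_lo, config.chrom_length - period)) // period) * period
        start = seg_start + int(rng.integers(0, max(1, config.state_segment - config.peak_width)))
        peak_rows.append((config.chrom, start, start + config.peak_width, f"peak_{pid:04d}", 50, "."))
        pid += 1
    for _ in range(config.n_decoy_no_state):
        # inside a gap within the gene region (so only the state filter removes it)
        seg_start = (int(rng.integers(0, gene_region_end)) // period) * period
        gap_lo = seg_start + config.state_segment
        start = gap_lo + int(rng.integers(0, max(1, config.state_gap - config.peak_width)))
        peak_rows.append((config.chrom, start, start + config.peak_width, f"peak_{pid:04d}", 50, "."))
        pid += 1

    peaks = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    truth = SyntheticTruth(seed=config.seed, bound_and_regulated_genes=set(truth_genes))
    return peaks, states, gene_models, truth


# ---------------------------------------------------------------------------
# knockdown differential expression
# ---------------------------------------------------------------------------


@dataclass
class KnockdownDEConfig:
    """Shape of the synthetic knockdown DE table.

    Defaults reproduce a coactivator-knockdown skew: more genes down than
    up (1993 vs 1607) and a stronger mean fold change for down-regulated
    genes (-1.11) than up-regulated ones (+0.83).
    """

    n_genes: int = 15_000
    n_down: int = 1993
    n_up: int = 1607
    mean_logfc_down: float = -1.11
    mean_logfc_up: float = 0.83
    genes: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, 0) < 0 or self.n_down < 0 or self.n_up < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_down + self.n_up > self.n_genes:
            raise ValueError("more DEGs requested than genes exist")
        if self.mean_logfc_down > 0 or self.mean_logfc_up < 0:
            raise ValueError("mean_logfc_down must be <= 0 and mean_logfc_up >= 0")


def simulate_knockdown_de(
    config: KnockdownDEConfig, contrast: str = "knockdown_vs_control"
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a DE result table (gene, logFC, p, FDR) with planted DEGs.

    Down/up log-fold-changes are gamma-distributed with the configured
    means (shape 2); DEG p-values are log-uniform in [1e-8, 1e-2] and null
    p-values uniform, then BH-adjusted together.
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes) if config.genes is not None else _gene_names(config.n_genes)
    if len(genes) != config.n_genes:
        raise ValueError("genes list length must equal n_genes")
    order = rng.permutation(config.n_genes)
    down = [genes[i] for i in order[: config.n_down]]
    up = [genes[i] for i in order[config.n_down : config.n_down + config.n_up]]

    logfc = rng.normal(0.0, 0.15, size=config.n_genes)
    p = rng.uniform(0.0, 1.0, size=config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    if down:
        logfc[[gene_pos[g] for g in down]] = -rng.gamma(
            2.0, abs(config.mean_logfc_down) / 2.0, size=len(down)
        )
        p[[gene_pos[g] for g in down]] = 10 ** -rng.uniform(2, 8, size=len(down))
    if up:
        logfc[[gene_pos[g] for g in up]] = rng.gamma(
            2.0, config.mean_logfc_up / 2.0, size=len(up)
        )
        p[[gene_pos[g] for g in up]] = 10 ** -rng.uniform(2, 8, size=len(up))

    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"gene": genes, "logFC": logfc, "p": p, "FDR": fdr, "contrast": contrast}
    )
    truth = SyntheticTruth(seed=config.seed, de_down_genes=set(down), de_up_genes=set(up))
    return table, truth


# ---------------------------------------------------------------------------
# writers (byte-stable: fixed column order, fixed float format)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6g"


def write_cohort(cohort: Cohort, truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t", float_format=_FLOAT_FMT)
    cohort.cna.to_csv(outdir / "cna.tsv", sep="\t")
    cohort.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(
        outdir / "clinical.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    cohort.gene_models.to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
    cohort.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    (outdir / "tf_list.txt").write_text("\n".join(sorted(cohort.tf_list.genes)) + "\n")
    truth.to_yaml(outdir / "truth.yaml")


def write_cistrome(
    peaks: pd.DataFrame,
    states: pd.DataFrame,
    gene_models: pd.DataFrame,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks.to_csv(outdir / "peaks.bed", sep="\t", index=False, header=False)
    states.to_csv(outdir / "states.bed", sep="\t", index=False, header=False)
    gene_models.to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
    truth.to_yaml(outdir / "truth.yaml")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
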