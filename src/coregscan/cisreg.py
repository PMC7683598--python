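"""Peak-to-gene annotation, chromatin-state overlap and the bound-and-regulated cascade.

The cascade mirrors a coactivator cistrome analysis: binding peaks are
first required to overlap a chromatin-state segment by at least 1 bp, the
retained peaks are annotated to every gene whose TSS lies within a fixed
window (100 kb by default), and the linked genes are intersected with two
differential-expression tables — knockdown-vs-control in a cell line and
upper-vs-lower index-gene quartile in the tumor cohort — to yield the
bound-and-regulated gene network.

Coordinates are 0-based half-open. Distance between a peak interval and a
gene anchor point is 0 when the anchor falls inside the peak and the gap
in bases otherwise, so with a 100,000 bp window an anchor 100,000 bp from
the nearest peak edge is linked and one 100,001 bp away is not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .survival import quartile_groups

__all__ = [
    "annotate_peaks_to_genes",
    "overlap_states",
    "quartile_de",
    "correlation_profile",
    "CorrelationProfile",
    "bound_and_regulated",
    "deg_significant",
    "DEG_RULES",
    "read_bed",
]

logger = logging.getLogger(__name__)

#: DEG significance rule-sets: (max FDR, min |logFC|).
DEG_RULES: dict[str, tuple[float, float]] = {
    "fdr05_lfc1.5": (0.05, 1.5),
    "fdr05": (0.05, 0.0),
}


def read_bed(path, n_fields: int | None = None) -> pd.DataFrame:
    """Read a BED3/BED4/BED6 file into a validated interval frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return validate_intervals(df)


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"inverted/empty interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def _check_chrom_naming(a, b) -> None:
    """Reject mixed 'chr1' / '1' conventions between two interval sources."""
    pref_a = {str(c).startswith("chr") for c in a}
    pref_b = {str(c).startswith("chr") for c in b}
    if len(pref_a | pref_b) > 1:
        raise ValueError("mixed chromosome naming conventions ('chr1' vs '1')")


def _point_interval_distance(anchor: int, start: int, end: int) -> int:
    """Gap in bases between a point and a half-open interval (0 if inside)."""
    if start <= anchor < end:
        return 0
    if anchor < start:
        return start - anchor
    return anchor - (end - 1)


def annotate_peaks_to_genes(
    peaks: pd.DataFrame,
    gene_models: pd.DataFrame,
    window: int = 100_000,
    anchor: str = "tss",
) -> pd.DataFrame:
    """Link every peak to every gene whose anchor lies within ``window`` bp.

    ``anchor='tss'`` measures to the transcription start site;
    ``anchor='body'`` measures to the nearest edge of the gene span.
    Returns one row per (peak, gene) pair with the distance in bp. Peaks on
    chromosomes absent from the gene models are skipped with a warning.
    """
    if anchor not in ("tss", "body"):
        raise ValueError("anchor must be 'tss' or 'body'")
    peaks = validate_intervals(peaks)
    _check_chrom_naming(peaks["chrom"].unique(), gene_models["chrom"].unique())

    known = set(gene_models["chrom"])
    orphan = sorted(set(peaks["chrom"]) - known)
    if orphan:
        warnings.warn(f"skipping peaks on chromosomes without gene models: {orphan}")
        peaks = peaks[peaks["chrom"].isin(known)]

    # one tree of window-extended peak intervals per chromosome; querying a
    # gene anchor point then yields exactly the peaks within `window`
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        tree = IntervalTree()
        for rec in sub.itertuples(index=False):
            tree.addi(rec.start - window, rec.end + window, (rec.name, rec.start, rec.end))
        trees[chrom] = tree

    rows = []
    for rec in gene_models.itertuples(index=False):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        if anchor == "tss":
            anchors = [int(rec.tss)]
        else:
            starts = [int(x) for x in str(rec.exon_starts).split(",")]
            ends = [int(x) for x in str(rec.exon_ends).split(",")]
            anchors = [min(starts), max(ends) - 1]
        seen = {}
        for a in anchors:
            for iv in tree[a]:
                peak_name, ps, pe = iv.data
                d = _point_interval_distance(a, ps, pe)
                if d <= window and d < seen.get(peak_name, window + 1):
                    seen[peak_name] = d
        for peak_name, d in seen.items():
            rows.append({"peak": peak_name, "gene": rec.gene, "distance": d})
    out = pd.DataFrame(rows, columns=["peak", "gene", "distance"])
    return out.sort_values(["peak", "gene"], kind="mergesort").reset_index(drop=True)


def overlap_states(
    peaks: pd.DataFrame, states: pd.DataFrame, min_overlap: int = 1
) -> pd.DataFrame:
    """Retain peaks overlapping >= ``min_overlap`` bp of any state segment.

    All overlapping state labels are attached (semicolon-joined, sorted).
    With half-open intervals, touching segments share 0 bp and are dropped
    at the default 1 bp requirement.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    peaks = validate_intervals(peaks)
    states = validate_intervals(states)
    _check_chrom_naming(peaks["chrom"].unique(), states["chrom"].unique())

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in states.groupby("chrom"):
        tree = IntervalTree()
        for rec in sub.itertuples(index=False):
            tree.addi(rec.start, rec.end, rec.state)
        trees[chrom] = tree

    keep_rows = []
    for rec in peaks.itertuples(index=False):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        labels = set()
        for iv in tree.overlap(rec.start, rec.end):
            ov = min(rec.end, iv.end) - max(rec.start, iv.begin)
            if ov >= min_overlap:
                labels.add(iv.data)
        if labels:
            row = rec._asdict()
            row["states"] = ";".join(sorted(labels))
            keep_rows.append(row)
    columns = list(peaks.columns) + ["states"]
    return pd.DataFrame(keep_rows, columns=columns).reset_index(drop=True)


def quartile_de(
    expr_matrix: pd.DataFrame,
    index_gene: str,
    exclude_index: bool = True,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Differential expression between upper- and lower-quartile tumors.

    Tumors are split on the index gene's expression; every other gene is
    tested with a two-sided Wilcoxon rank-sum test, logFC is the upper
    minus lower group mean (log-scale input assumed), and FDR is BH over
    the tested genes. A rank-based test stands in for a count-model DE fit;
    with Z-scored or log cohort expression it targets the same location
    shift.
    """
    if index_gene not in expr_matrix.index:
        raise KeyError(f"index gene {index_gene!r} not in expression matrix")
    groups = quartile_groups(expr_matrix.loc[index_gene])
    lo = groups.index[groups == "lower"]
    hi = groups.index[groups == "upper"]
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("degenerate quartile groups on the index gene")
    genes = [g for g in expr_matrix.index if not (exclude_index and g == index_gene)]
    lo_m = expr_matrix.loc[genes, lo].to_numpy(dtype=float)
    hi_m = expr_matrix.loc[genes, hi].to_numpy(dtype=float)
    stat, p = stats.ranksums(hi_m, lo_m, axis=1)
    logfc = hi_m.mean(axis=1) - lo_m.mean(axis=1)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": genes,
            "logFC": logfc,
            "p": p,
            "FDR": fdr,
            "contrast": contrast or f"{index_gene}_upper_vs_lower_quartile",
        }
    )


@dataclass
class CorrelationProfile:
    """Correlations of a gene set with an index gene vs a background set."""

    correlations: pd.Series  # per gene, over the union of both sets
    gene_set: list[str]
    background_set: list[str]
    ks_statistic: float
    ks_p: float
    shift_direction: str  # 'more positive' | 'more negative' | 'none'
    n_dropped_constant: int


def correlation_profile(
    expr_matrix: pd.DataFrame,
    index_gene: str,
    gene_set,
    background_set,
    method: str = "spearman",
) -> CorrelationProfile:
    """Per-gene correlation with the index gene, and a two-sample KS test.

    The KS test compares the gene set's correlation distribution against
    the background set's; ``shift_direction`` reports the sign of the mean
    difference, mirroring the more-positive / more-negative reading of a
    cumulative-correlation plot. Constant rows yield undefined correlations
    and are excluded, with the count reported.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if expr_matrix.shape[1] < 10:
        raise ValueError("need at least 10 samples for correlation profiles")
    gene_set = sorted(set(gene_set))
    background_set = sorted(set(background_set))
    for name, genes in (("gene_set", gene_set), ("background_set", background_set)):
        absent = sorted(set(genes) - set(expr_matrix.index))
        if absent:
            raise KeyError(f"{name} genes absent from matrix: {absent[:5]}")
    index_values = expr_matrix.loc[index_gene].to_numpy(dtype=float)

    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    union = sorted(set(gene_set) | set(background_set))
    cors = {}
    dropped = 0
    for gene in union:
        values = expr_matrix.loc[gene].to_numpy(dtype=float)
        if np.ptp(values) == 0 or np.ptp(index_values) == 0:
            dropped += 1
            continue
        cors[gene] = float(corr_fn(index_values, values)[0])
    correlations = pd.Series(cors, name=f"corr_with_{index_gene}")

    a = correlations.reindex([g for g in gene_set if g in cors]).to_numpy()
    b = correlations.reindex([g for g in background_set if g in cors]).to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("no usable genes left in one of the sets")
    if sorted(a.tolist()) == sorted(b.tolist()):
        ks_stat, ks_p = 0.0, 1.0  # identical samples: no distributional shift
    else:
        ks_stat, ks_p = stats.ks_2samp(a, b)
    delta = float(a.mean() - b.mean())
    direction = "none" if delta == 0 else ("more positive" if delta > 0 else "more negative")
    return CorrelationProfile(
        correlations=correlations,
        gene_set=gene_set,
        background_set=background_set,
        ks_statistic=float(ks_stat),
        ks_p=float(ks_p),
        shift_direction=direction,
        n_dropped_constant=dropped,
    )


def deg_significant(
    de: pd.DataFrame, rule: str | tuple[float, float] = "fdr05_lfc1.5"
) -> pd.DataFrame:
    """Rows of a DE table passing a (max FDR, min |logFC|) significance rule."""
    max_fdr, min_lfc = DEG_RULES[rule] if isinstance(rule, str) else rule
    return de[(de["FDR"] < max_fdr) & (de["logFC"].abs() > min_lfc)]


def bound_and_regulated(
    links: pd.DataFrame,
    de_knockdown: pd.DataFrame,
    de_cohort: pd.DataFrame,
    rule: str | tuple[float, float] = "fdr05_lfc1.5",
    top_k: int | None = None,
) -> pd.DataFrame:
    """Genes that are bound (linked to a peak) and regulated in both contrasts.

    The output is the three-way intersection of the linked genes with the
    significant genes of the knockdown and cohort DE tables, annotated with
    both logFCs and directions and the number of supporting peaks, sorted
    by |cohort logFC| (descending) and optionally truncated to ``top_k``.
    Empty inputs yield an empty network, not an error.
    """
    columns = [
        "gene", "n_peaks", "min_distance",
        "logFC_knockdown", "direction_knockdown",
        "logFC_cohort", "direction_cohort",
    ]
    if len(links) == 0 or len(de_knockdown) == 0 or len(de_cohort) == 0:
        logger.info("bound_and_regulated: an input table is empty; returning empty network")
        return pd.DataFrame(columns=columns)
    sig_kd = deg_significant(de_knockdown, rule).set_index("gene")
    sig_co = deg_significant(de_cohort, rule).set_index("gene")
    linked = set(links["gene"])
    genes = sorted(linked & set(sig_kd.index) & set(sig_co.index))
    per_gene = links.groupby("gene")
    rows = []
    for g in genes:
        sub = per_gene.get_group(g)
        rows.append(
            {
                "gene": g,
                "n_peaks": int(sub["peak"].nunique()),
                "min_distance": int(sub["distance"].min()),
                "logFC_knockdown": float(sig_kd.loc[g, "logFC"]),
                "direction_knockdown": "up" if sig_kd.loc[g, "logFC"] > 0 else "down",
                "logFC_cohort": float(sig_co.loc[g, "logFC"]),
                "direction_cohort": "up" if sig_co.loc[g, "logFC"] > 0 else "down",
            }
        )
    out = pd.DataFrame(rows, columns=columns)
    out = out.reindex(
        out["logFC_cohort"].abs().sort_values(ascending=False, kind="mergesort").index
    ).reset_index(drop=True)
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out
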