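"""Per-gene alteration scores: Z-scores, GISTIC calls, mutation burden.

Two Z-score conventions are supported. Cohorts with adjacent-normal samples
standardize each tumor value against the normal-sample distribution of the
same gene (``tumor_vs_normal``); cohorts without normals center each gene
at its median across samples (``median_centered``). Mutation burden is the
square-root of the gene-length-normalized mutation count, damping the
dependence on cohort size.

All genomic intervals are 0-based half-open.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "tumor_normal_zscores",
    "median_zscores",
    "cds_length",
    "gene_cds_lengths",
    "mutation_burden",
    "cna_alteration_calls",
    "parse_exons",
]

GISTIC_CODES = (-2, -1, 0, 1, 2)


def _detected_mask(
    matrix: pd.DataFrame, threshold: float, floor: float
) -> pd.Series:
    """Genes 'detectible' in at least ``threshold`` of samples.

    A value counts as detected when it is non-missing and strictly above
    the expression floor.
    """
    detected = matrix.notna() & (matrix > floor)
    return detected.mean(axis=1) >= threshold


def tumor_normal_zscores(
    expression: pd.DataFrame,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    detect_threshold: float = 0.80,
    detect_floor: float = 0.0,
) -> pd.DataFrame:
    """Standardize tumor expression against the matched-normal distribution.

    Z_gs = (x_gs - mean over normals) / SD over normals (n-1 denominator).
    Genes detected in fewer than ``detect_threshold`` of all samples, and
    genes with zero normal-sample variance, are dropped (the latter with a
    warning).
    """
    tumor_samples, normal_samples = list(tumor_samples), list(normal_samples)
    if len(normal_samples) < 2:
        raise ValueError("tumor-vs-normal Z-scores need at least 2 normal samples")
    missing = (set(tumor_samples) | set(normal_samples)) - set(expression.columns)
    if missing:
        raise KeyError(f"samples absent from expression matrix: {sorted(missing)[:5]}")

    keep = _detected_mask(
        expression[tumor_samples + normal_samples], detect_threshold, detect_floor
    )
    matrix = expression.loc[keep]
    normals = matrix[normal_samples]
    center = normals.mean(axis=1)
    scale = normals.std(axis=1, ddof=1)
    nonzero = scale > 0
    if (~nonzero).any():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} gene(s) with zero normal-sample variance"
        )
    z = matrix.loc[nonzero, tumor_samples].sub(center[nonzero], axis=0).div(
        scale[nonzero], axis=0
    )
    z.attrs["convention"] = "tumor_vs_normal"
    z.attrs["detect_threshold"] = detect_threshold
    return z


def median_zscores(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-centered Z-scores: Z = (x - row median) / row SD (ddof=1)."""
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    center = matrix.median(axis=1)
    scale = matrix.std(axis=1, ddof=1)
    nonzero = scale > 0
    if not nonzero.any():
        raise ValueError("all gene rows are constant; Z-scores undefined")
    if (~nonzero).any():
        warnings.warn(f"dropping {int((~nonzero).sum())} constant gene row(s)")
    z = matrix.loc[nonzero].sub(center[nonzero], axis=0).div(scale[nonzero], axis=0)
    z.attrs["convention"] = "median_centered"
    return z


def cds_length(exons: Iterable[tuple[int, int]]) -> int:
    """Length of the genomic union of exon intervals (overlap counted once)."""
    exons = sorted((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValueError("gene model has no exons")
    total = 0
    cur_s, cur_e = exons[0]
    if cur_s >= cur_e:
        raise ValueError(f"inverted or empty exon interval [{cur_s}, {cur_e})")
    for s, e in exons[1:]:
        if s >= e:
            raise ValueError(f"inverted or empty exon interval [{s}, {e})")
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def parse_exons(rec) -> list[tuple[int, int]]:
    """Exon intervals from a gene-model row with comma-joined starts/ends."""
    starts = [int(x) for x in str(rec.exon_starts).split(",")]
    ends = [int(x) for x in str(rec.exon_ends).split(",")]
    if len(starts) != len(ends):
        raise ValueError(f"gene {rec.gene}: exon_starts/exon_ends length mismatch")
    return list(zip(starts, ends))


def gene_cds_lengths(gene_models: pd.DataFrame) -> pd.Series:
    """CDS length per gene from a gene-model table."""
    return pd.Series(
        {rec.gene: cds_length(parse_exons(rec)) for rec in gene_models.itertuples(index=False)},
        name="cds_length",
    )


def mutation_burden(
    mutations: pd.DataFrame,
    gene_models: pd.DataFrame,
    n_tumors: int,
    mode: str = "sqrt_total_rate",
) -> pd.DataFrame:
    """Gene-length-normalized mutation burden per gene.

    The default score is sqrt(total mutation count / CDS length); the
    square root damps the growth of summed counts with cohort size. The
    pre-sqrt rate is always reported. ``mode='per_tumor_rate'`` instead
    divides the rate by the number of tumors (an alternative reading of
    length-plus-cohort normalization).

    Genes with no mutations are present with score 0; a mutation in a gene
    lacking a model is an error.
    """
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    if mode not in ("sqrt_total_rate", "per_tumor_rate"):
        raise ValueError(f"unknown mode {mode!r}")
    lengths = gene_cds_lengths(gene_models)
    counts = (
        mutations.groupby("gene").size() if len(mutations) else pd.Series(dtype=int)
    )
    orphans = sorted(set(counts.index) - set(lengths.index))
    if orphans:
        raise KeyError(f"mutations in genes without a gene model: {orphans[:10]}")
    counts = counts.reindex(lengths.index, fill_value=0).astype(int)
    rate = counts / lengths
    if mode == "sqrt_total_rate":
        score = np.sqrt(rate)
    else:
        score = rate / n_tumors
    return pd.DataFrame(
        {
            "raw_count": counts,
            "cds_length": lengths,
            "rate": rate,
            "normalized_score": score,
        }
    )


def cna_alteration_calls(
    cna: pd.DataFrame, level: str = "deep"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boolean amplification / deletion calls from GISTIC codes.

    ``deep``: amplification = +2, deletion = -2. ``any``: amplification =
    code >= 1, deletion = code <= -1.
    """
    values = cna.to_numpy()
    bad = ~np.isin(values, GISTIC_CODES)
    if bad.any():
        offender = values[bad].flat[0]
        raise ValueError(f"CNA matrix contains non-GISTIC code {offender!r}")
    if level == "deep":
        amp, dele = cna == 2, cna == -2
    elif level == "any":
        amp, dele = cna >= 1, cna <= -1
    else:
        raise ValueError(f"level must be 'deep' or 'any', got {level!r}")
    return amp, dele
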