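"""Family-wide alteration tests by random-set resampling.

Given a per-gene alteration score vector over a cohort's detected-gene
universe and a gene class (e.g. corepressors), the test compares a class
statistic against the distribution of the same statistic over B random
gene sets of equal size drawn without replacement from the universe. The
empirical p-value uses the add-one estimator (r + 1) / (B + 1), so its
floor is exactly 1 / (B + 1) — with the conventional B = 100,000 draws the
smallest attainable p is about 1e-05.

Three class statistics are available: ``proportion_beyond_threshold`` (the
fraction of class genes altered beyond a Z threshold in the stated
direction, default t = 2), ``mean`` (mean class score) and ``mean_rank``
(mean rank of class scores within the universe). Ties between the observed
and resampled statistic count as at-least-as-extreme, which is
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FamilyTestResult",
    "family_alteration_test",
    "run_family_panel",
    "enrichment_vs_geneset",
    "panel_to_frame",
    "neglog10_q_matrix",
]

STATISTICS = ("proportion_beyond_threshold", "mean", "mean_rank")
DIRECTIONS = ("up", "down", "two_sided")

# cap on the number of random-key cells materialized at once when sampling
_MAX_CELLS = 40_000_000


@dataclass
class FamilyTestResult:
    """One family-wide test: observed statistic vs resampled null."""

    class_name: str
    cohort: str
    data_type: str
    direction: str
    statistic: str
    threshold: float
    class_size: int
    universe_size: int
    observed: float
    null_mean: float
    null_sd: float
    n_resamples: int
    empirical_p: float
    q: float = float("nan")
    skipped: bool = False

    @property
    def neglog10_q(self) -> float:
        return float(-np.log10(self.q)) if self.q == self.q and self.q > 0 else float("nan")


def _sample_subsets(
    rng: np.random.Generator, B: int, n: int, k: int
) -> Iterable[np.ndarray]:
    """Yield blocks of B' x k index arrays, each row a uniform k-subset of n.

    Rows are generated by partial selection on iid uniform keys, which is a
    uniform draw without replacement within each row.
    """
    if k == n:
        yield np.tile(np.arange(n), (B, 1))
        return
    rows_per_block = max(1, _MAX_CELLS // n)
    done = 0
    while done < B:
        b = min(rows_per_block, B - done)
        keys = rng.random((b, n))
        yield np.argpartition(keys, k - 1, axis=1)[:, :k]
        done += b


def _statistic(
    values: np.ndarray, statistic: str, direction: str, threshold: float, axis=None
):
    """Class statistic on score values (1-D observed or 2-D null draws)."""
    if statistic == "proportion_beyond_threshold":
        if direction == "down":
            hit = values < -threshold
        elif direction == "up":
            hit = values > threshold
        else:
            hit = np.abs(values) > threshold
        return hit.mean(axis=axis)
    # 'mean' and 'mean_rank' both reduce to a mean (ranks precomputed)
    return values.mean(axis=axis)


def _orientation(statistic: str, direction: str) -> int:
    """+1 if larger statistics are more extreme, -1 if smaller are.

    The proportion statistic already encodes direction in its indicator, so
    larger is always more extreme; for mean / mean_rank the direction picks
    the tail.
    """
    if statistic == "proportion_beyond_threshold":
        return 1
    if direction == "down":
        return -1
    if direction == "up":
        return 1
    raise ValueError(
        "two_sided direction is only defined for the proportion statistic"
    )


def family_alteration_test(
    scores: pd.Series,
    class_genes: Iterable[str],
    statistic: str = "proportion_beyond_threshold",
    direction: str = "down",
    threshold: float = 2.0,
    B: int = 100_000,
    seed: int | np.random.Generator = 0,
    class_name: str = "",
    cohort: str = "",
    data_type: str = "expression",
) -> FamilyTestResult:
    """Empirical p-value for a gene class against equal-size random sets.

    ``scores`` is the per-gene alteration vector over the cohort's detected
    universe (its index must be duplicate-free and finite). The null is
    built from B subsets of the universe, each drawn without replacement,
    and empirical_p = (1 + #{draws at least as extreme}) / (B + 1).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if B < 100:
        raise ValueError("B must be >= 100 resamples")
    if scores.index.has_duplicates:
        raise ValueError("score vector universe contains duplicate genes")
    values = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("score vector contains non-finite values")

    class_genes = sorted(set(class_genes))
    universe = set(scores.index)
    outside = [g for g in class_genes if g not in universe]
    if outside:
        raise ValueError(f"class genes absent from the universe: {outside[:5]}")
    k, n = len(class_genes), len(values)
    if k < 2:
        raise ValueError("class must contain at least 2 genes")
    if k > n:
        raise ValueError("class is larger than the universe")

    if statistic == "mean_rank":
        values = stats.rankdata(values)
    class_idx = scores.index.get_indexer(class_genes)
    observed = float(_statistic(values[class_idx], statistic, direction, threshold))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sign = _orientation(statistic, direction)
    # ties must count as at-least-as-extreme; a float tolerance keeps exact
    # ties (e.g. a draw reproducing the class set, summed in another order)
    # from being lost to rounding
    tie_tol = 1e-9 * max(1.0, abs(observed))
    extreme = 0
    total = 0
    s1 = 0.0
    s2 = 0.0
    for idx in _sample_subsets(rng, B, n, k):
        null = np.asarray(
            _statistic(values[idx], statistic, direction, threshold, axis=1), dtype=float
        )
        extreme += int((sign * null >= sign * observed - tie_tol).sum())
        total += null.size
        s1 += float(null.sum())
        s2 += float((null**2).sum())
    assert total == B
    null_mean = s1 / B
    null_var = max(s2 / B - null_mean**2, 0.0)
    empirical_p = (1 + extreme) / (B + 1)

    return FamilyTestResult(
        class_name=class_name,
        cohort=cohort,
        data_type=data_type,
        direction=direction,
        statistic=statistic,
        threshold=threshold,
        class_size=k,
        universe_size=n,
        observed=observed,
        null_mean=null_mean,
        null_sd=float(np.sqrt(null_var)),
        n_resamples=B,
        empirical_p=empirical_p,
    )


def run_family_panel(
    score_vectors: Mapping[tuple[str, str], pd.Series],
    class_sets: Mapping[str, Iterable[str]],
    directions: Sequence[str] = ("down", "up"),
    statistic: str = "proportion_beyond_threshold",
    threshold: float = 2.0,
    B: int = 100_000,
    seed: int = 0,
) -> list[FamilyTestResult]:
    """Run every (class x cohort/data-type x direction) test and apply BH FDR.

    ``score_vectors`` maps (cohort, data_type) to a per-gene score vector
    over that cohort's detected universe; ``class_sets`` maps class name to
    its gene set (restrict catalogs to detected genes first). Classes that
    end up empty or singleton in a cohort's universe are flagged skipped
    rather than silently dropped. FDR is Benjamini-Hochberg across the
    whole panel.
    """
    if not score_vectors:
        raise ValueError("no score vectors supplied")
    rng = np.random.default_rng(seed)
    results: list[FamilyTestResult] = []
    for (cohort, data_type), scores in score_vectors.items():
        universe = set(scores.index)
        for class_name, genes in class_sets.items():
            in_universe = sorted(set(genes) & universe)
            for direction in directions:
                if len(in_universe) < 2:
                    results.append(
                        FamilyTestResult(
                            class_name=class_name,
                            cohort=cohort,
                            data_type=data_type,
                            direction=direction,
                            statistic=statistic,
                            threshold=threshold,
                            class_size=len(in_universe),
                            universe_size=len(universe),
                            observed=float("nan"),
                            null_mean=float("nan"),
                            null_sd=float("nan"),
                            n_resamples=0,
                            empirical_p=float("nan"),
                            skipped=True,
                        )
                    )
                    continue
                results.append(
                    family_alteration_test(
                        scores,
                        in_universe,
                        statistic=statistic,
                        direction=direction,
                        threshold=threshold,
                        B=B,
                        seed=rng,
                        class_name=class_name,
                        cohort=cohort,
                        data_type=data_type,
                    )
                )

    tested = [r for r in results if not r.skipped]
    if tested:
        qs = multipletests([r.empirical_p for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, qs):
            r.q = float(q)
    return results


def enrichment_vs_geneset(
    class_genes: Iterable[str], reference_set: Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided upper-tail hypergeometric p for class/reference overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    class_genes = set(class_genes) & universe
    reference = set(reference_set) & universe
    overlap = len(class_genes & reference)
    return float(
        stats.hypergeom.sf(
            overlap - 1, len(universe), len(reference), len(class_genes)
        )
    )


def panel_to_frame(results: Sequence[FamilyTestResult]) -> pd.DataFrame:
    """One row per test: the TSV-ready panel result table."""
    rows = []
    for r in results:
        rows.append(
            {
                "class": r.class_name,
                "cohort": r.cohort,
                "data_type": r.data_type,
                "direction": r.direction,
                "statistic": r.statistic,
                "threshold": r.threshold,
                "class_size": r.class_size,
                "universe_size": r.universe_size,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "B": r.n_resamples,
                "empirical_p": r.empirical_p,
                "q": r.q,
                "neglog10_q": r.neglog10_q,
                "skipped": r.skipped,
            }
        )
    return pd.DataFrame(rows)


def neglog10_q_matrix(results: Sequence[FamilyTestResult]) -> pd.DataFrame:
    """Classes x (cohort/data-type/direction) matrix of -log10 q, for plotting."""
    df = panel_to_frame([r for r in results if not r.skipped])
    if df.empty:
        return pd.DataFrame()
    df["column"] = df["cohort"] + "/" + df["data_type"] + "/" + df["direction"]
    return df.pivot(index="class", columns="column", values="neglog10_q")
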