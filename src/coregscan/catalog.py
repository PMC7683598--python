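"""Mutually exclusive gene-class catalogs for transcription factors and coregulators.

Genes are partitioned into four disjoint classes from two kinds of evidence:

* membership in one or more canonical transcription-factor lists -> ``TF``;
* Gene-Ontology-style term annotations whose labels match configurable
  phrase lists for positive / negative control of transcription.  Of the
  genes not on a TF list, exclusively positive evidence -> ``COA``
  (coactivator), exclusively negative -> ``COR`` (corepressor), both ->
  ``MIXED`` (context-dependent coregulator).

TF-list membership takes precedence over coregulator evidence, so the
classes are disjoint by construction.  Gene identity is the upper-cased
symbol; synonym resolution is deliberately not performed — callers supply
harmonized symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneClass",
    "Polarity",
    "TfList",
    "GeneClassCatalog",
    "DEFAULT_PHRASES",
    "load_annotations",
    "assign_polarity",
    "classify_genes",
    "restrict_to_detected",
]


class GeneClass(str, Enum):
    TF = "TF"
    COA = "COA"
    COR = "COR"
    MIXED = "MIXED"


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    COACTIVATOR = "coactivator"
    COREPRESSOR = "corepressor"


#: Default phrase lists used to assign a polarity to an annotation term label.
#: Matching is case-insensitive substring matching.
DEFAULT_PHRASES: dict[Polarity, tuple[str, ...]] = {
    Polarity.POSITIVE: (
        "positive control of transcription",
        "positive regulation of transcription",
    ),
    Polarity.NEGATIVE: (
        "negative control of transcription",
        "negative regulation of transcription",
    ),
    Polarity.COACTIVATOR: ("co-activator", "coactivator"),
    Polarity.COREPRESSOR: ("co-repressor", "corepressor"),
}

#: Which polarities count as positive- vs negative-regulation evidence.
_POSITIVE_EVIDENCE = {Polarity.POSITIVE, Polarity.COACTIVATOR}
_NEGATIVE_EVIDENCE = {Polarity.NEGATIVE, Polarity.COREPRESSOR}

_ANNOT_COLUMNS = ["gene", "term_id", "term_label", "polarity"]


@dataclass(frozen=True)
class TfList:
    """A canonical transcription-factor list (e.g. UniProt- or FANTOM-style)."""

    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"TF list {self.source!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    @classmethod
    def from_file(cls, path: str | Path, source: str | None = None) -> "TfList":
        """Read a newline-delimited gene-symbol file."""
        path = Path(path)
        genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        return cls(source=source or path.stem, genes=frozenset(genes))


@dataclass
class GeneClassCatalog:
    """Disjoint gene -> class assignment with per-gene provenance."""

    assignment: dict[str, GeneClass]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [g for g in self.assignment if not self.provenance.get(g)]
        if missing:
            raise ValueError(
                f"{len(missing)} assigned genes lack provenance (e.g. {missing[:3]})"
            )

    @property
    def counts(self) -> dict[GeneClass, int]:
        out = {c: 0 for c in GeneClass}
        for cls in self.assignment.values():
            out[cls] += 1
        return out

    def genes_in(self, cls: GeneClass | str) -> set[str]:
        cls = GeneClass(cls)
        return {g for g, c in self.assignment.items() if c is cls}

    def __len__(self) -> int:
        return len(self.assignment)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, self.assignment[g].value, ";".join(self.provenance[g]))
            for g in sorted(self.assignment)
        ]
        return pd.DataFrame(rows, columns=["gene", "class", "provenance"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneClassCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        assignment = {g: GeneClass(c) for g, c in zip(df["gene"], df["class"])}
        provenance = {g: p.split(";") for g, p in zip(df["gene"], df["provenance"])}
        return cls(assignment=assignment, provenance=provenance)


def assign_polarity(
    term_label: str, phrases: Mapping[Polarity, Sequence[str]] = DEFAULT_PHRASES
) -> Polarity | None:
    """Match a term label against the phrase lists (case-insensitive substring).

    Returns the first matching polarity in the fixed order positive,
    negative, coactivator, corepressor, or ``None`` if nothing matches.
    """
    label = term_label.lower()
    for pol in (Polarity.POSITIVE, Polarity.NEGATIVE, Polarity.COACTIVATOR, Polarity.COREPRESSOR):
        if any(p.lower() in label for p in phrases.get(pol, ())):
            return pol
    return None


def load_annotations(
    path: str | Path,
    phrases: Mapping[Polarity, Sequence[str]] = DEFAULT_PHRASES,
) -> pd.DataFrame:
    """Read an annotation TSV (gene, term_id, term_label[, polarity]).

    If the polarity column is absent it is derived from the term label via
    :func:`assign_polarity`; records matching no phrase are dropped (they
    carry no classification evidence).  Duplicate (gene, term_id) pairs
    collapse to one record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "term_id", "term_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    if "polarity" not in df.columns:
        df["polarity"] = df["term_label"].map(lambda s: p.value if (p := assign_polarity(s, phrases)) else None)
        df = df.dropna(subset=["polarity"])
    return normalize_annotations(df)


def normalize_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize an in-memory annotation table."""
    if df.empty:
        raise ValueError("annotation table is empty")
    df = df.copy()
    if (df["gene"].astype(str).str.strip() == "").any():
        raise ValueError("annotation table contains empty gene symbols")
    df["gene"] = df["gene"].astype(str).str.upper()
    valid = {p.value for p in Polarity}
    bad = df.loc[~df["polarity"].isin(valid)]
    if not bad.empty:
        rec = bad.iloc[0]
        raise ValueError(
            f"unknown polarity {rec['polarity']!r} for gene {rec['gene']!r}, "
            f"term {rec['term_id']!r} ({len(bad)} offending records)"
        )
    df = df.drop_duplicates(subset=["gene", "term_id"])
    return df.reset_index(drop=True)[_ANNOT_COLUMNS]


def classify_genes(
    annotations: pd.DataFrame,
    tf_lists: Iterable[TfList] = (),
    phrases: Mapping[Polarity, Sequence[str]] = DEFAULT_PHRASES,
) -> GeneClassCatalog:
    """Partition genes into disjoint TF / COA / COR / MIXED classes.

    Precedence: membership in any TF list wins; remaining genes with both
    positive and negative transcription-control evidence are MIXED,
    exclusively positive are COA, exclusively negative are COR.  Genes with
    no evidence at all are left unassigned.  The result is independent of
    record and list order.
    """
    annotations = normalize_annotations(annotations)

    tf_lists = list(tf_lists)
    assignment: dict[str, GeneClass] = {}
    provenance: dict[str, list[str]] = {}

    tf_sources: dict[str, list[str]] = {}
    for tfl in sorted(tf_lists, key=lambda t: t.source):
        for g in tfl.genes:
            tf_sources.setdefault(g, []).append(tfl.source)

    pos_terms: dict[str, set[str]] = {}
    neg_terms: dict[str, set[str]] = {}
    for rec in annotations.itertuples(index=False):
        pol = Polarity(rec.polarity)
        if pol in _POSITIVE_EVIDENCE:
            pos_terms.setdefault(rec.gene, set()).add(rec.term_id)
        elif pol in _NEGATIVE_EVIDENCE:
            neg_terms.setdefault(rec.gene, set()).add(rec.term_id)

    for gene, sources in tf_sources.items():
        assignment[gene] = GeneClass.TF
        prov = [f"tf_list:{s}" for s in sources]
        # flag coregulator evidence overridden by TF precedence
        if gene in pos_terms or gene in neg_terms:
            prov.append("coregulator_evidence_superseded")
        provenance[gene] = prov

    for gene in sorted(set(pos_terms) | set(neg_terms)):
        if gene in assignment:
            continue
        has_pos, has_neg = gene in pos_terms, gene in neg_terms
        if has_pos and has_neg:
            assignment[gene] = GeneClass.MIXED
        elif has_pos:
            assignment[gene] = GeneClass.COA
        else:
            assignment[gene] = GeneClass.COR
        terms = sorted(pos_terms.get(gene, set()) | neg_terms.get(gene, set()))
        provenance[gene] = [f"term:{t}" for t in terms]

    return GeneClassCatalog(assignment=assignment, provenance=provenance)


def restrict_to_detected(
    catalog: GeneClassCatalog, detected_genes: Iterable[str]
) -> GeneClassCatalog:
    """Restrict a catalog to the genes detected in a cohort.

    Raises if no catalog gene at all is detected (the cohort is unusable for
    family testing); a single empty class is allowed and simply counts 0.
    """
    detected = {str(g).upper() for g in detected_genes}
    if not detected:
        raise ValueError("detected gene set is empty")
    assignment = {g: c for g, c in catalog.assignment.items() if g in detected}
    if not assignment:
        raise ValueError("no catalog gene is detected in the cohort; cohort unusable")
    provenance = {g: list(catalog.provenance[g]) for g in assignment}
    return GeneClassCatalog(assignment=assignment, provenance=provenance)
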