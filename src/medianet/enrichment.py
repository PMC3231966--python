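"""Top-k functional-annotation scoring of index rankings.

Given a protein→term annotation map, the proteins best ranked by a
structural index are scored for functional coherence: the fraction of the
top k carrying a term, a one-sided hypergeometric over-representation
p-value against a background set, and the Spearman correlation between
per-protein p-values and the index itself.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy import stats

from .nullmodel import spearman

logger = logging.getLogger("medianet")

__all__ = [
    "AnnotationMap",
    "read_annotation_map",
    "top_k",
    "term_ratio",
    "enrichment_pvalue",
    "protein_pvalues",
    "index_function_correlation",
    "adjust_pvalues",
]


class AnnotationMap:
    """Protein→terms map with its inverse (term→proteins) kept consistent.

    Terms annotating no protein are absent from both directions.
    """

    def __init__(self, pairs):
        self._by_protein: dict[str, set] = {}
        self._by_term: dict[str, set] = {}
        for protein, term in pairs:
            self._by_protein.setdefault(protein, set()).add(term)
            self._by_term.setdefault(term, set()).add(protein)

    def terms_of(self, protein: str) -> frozenset:
        return frozenset(self._by_protein.get(protein, ()))

    def proteins_of(self, term: str) -> frozenset:
        return frozenset(self._by_term.get(term, ()))

    @property
    def proteins(self) -> frozenset:
        return frozenset(self._by_protein)

    @property
    def terms(self) -> frozenset:
        return frozenset(self._by_term)

    def __len__(self) -> int:
        return sum(len(t) for t in self._by_protein.values())


def read_annotation_map(path) -> AnnotationMap:
    """Read 'protein_id<TAB>term_id' lines into an :class:`AnnotationMap`."""
    pairs = []
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'protein_id\\tterm_id'")
            pairs.append((fields[0], fields[1]))
    return AnnotationMap(pairs)


def top_k(table: pd.DataFrame, index: str, k: int = 30) -> list:
    """The k proteins with the largest values of one index column.

    Ties are broken by ascending protein identifier (stable and
    deterministic).  If k exceeds the table size the full ranking is
    returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if index not in table.columns:
        raise KeyError(f"no index column {index!r}")
    if k > len(table):
        logger.warning("top_k: k=%d exceeds N=%d; returning all", k, len(table))
        k = len(table)
    ranked = table[index].sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])


def term_ratio(proteins: list, term: str, ann: AnnotationMap) -> float:
    """Fraction of the listed proteins annotated with the term."""
    if not proteins:
        raise ValueError("protein list is empty")
    hits = ann.proteins_of(term)
    return sum(p in hits for p in proteins) / len(proteins)


def enrichment_pvalue(proteins, term: str, background, ann: AnnotationMap) -> float:
    """One-sided hypergeometric over-representation p-value.

    Probability of drawing at least the observed number of term-annotated
    proteins when |proteins| are drawn without replacement from the
    background set.
    """
    background = set(background)
    if not background:
        raise ValueError("background set is empty")
    proteins = list(proteins)
    if not set(proteins) <= background:
        raise ValueError("proteins must be a subset of the background")
    annotated = ann.proteins_of(term) & background
    observed = sum(p in annotated for p in proteins)
    M, K, n = len(background), len(annotated), len(proteins)
    return float(stats.hypergeom.sf(observed - 1, M, K, n))


def protein_pvalues(
    proteins,
    background,
    ann: AnnotationMap,
    aggregate: str = "min",
) -> dict:
    """Per-protein functional-fit p-value within an evaluated top-k set.

    Each protein's score aggregates the enrichment p-values (computed over
    the whole top-k list) of the terms annotating it: the minimum by
    default, optionally the mean or Fisher's combined-probability value.
    Proteins with no annotated term get p = 1.
    """
    if aggregate not in ("min", "mean", "fisher"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    proteins = list(proteins)
    terms = set()
    for p in proteins:
        terms |= ann.terms_of(p)
    term_p = {t: enrichment_pvalue(proteins, t, background, ann) for t in terms}
    out = {}
    for p in proteins:
        ps = [term_p[t] for t in ann.terms_of(p)]
        if not ps:
            out[p] = 1.0
        elif aggregate == "min":
            out[p] = min(ps)
        elif aggregate == "mean":
            out[p] = sum(ps) / len(ps)
        else:
            out[p] = float(stats.combine_pvalues(ps, method="fisher").pvalue)
    return out


def index_function_correlation(table: pd.DataFrame, pvals: dict, index: str) -> float:
    """Spearman rho between per-protein p-values and an index column.

    Computed over the proteins shared between the table and the p-value map
    (at least 3 required); undefined correlations are NaN, never 0.
    """
    shared = sorted(set(table.index) & set(pvals))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared proteins")
    x = [pvals[p] for p in shared]
    y = table.loc[shared, index].to_numpy(dtype=float)
    return spearman(x, y)


def adjust_pvalues(pvals: dict) -> dict:
    """Benjamini–Hochberg adjustment of a name→p-value map (optional step)."""
    if not pvals:
        return {}
    names = sorted(pvals)
    adj = stats.false_discovery_control([pvals[n] for n in names], method="bh")
    return dict(zip(names, (float(a) for a in adj)))
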