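"""Hypergeometric over-representation analysis of gene sets against a
term-annotation background, and comparison of enriched-term sets.

The background is the set of annotated genes; p-values are upper-tail
hypergeometric probabilities P(X >= k) with no multiple-testing correction
by default (Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnnotationMap:
    gene2terms: Mapping[str, frozenset[str]]
    term_names: Mapping[str, str] = field(default_factory=dict)
    namespace: str = "biological_process"

    @property
    def background(self) -> frozenset[str]:
        return frozenset(self.gene2terms)

    def term2genes(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene2terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return {t: frozenset(g) for t, g in out.items()}


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    k: int  # selected genes with the term
    n: int  # selected annotated genes
    K: int  # background genes with the term
    N: int  # background size
    p: float
    p_adjusted: float
    significant: bool


def read_annotation(path: str | Path, namespace: str = "biological_process") -> AnnotationMap:
    """Two-column TSV (gene, term), optional third column term_name."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#").dropna(how="all")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs at least two columns (gene, term)")
    gene2terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene, term = row[0], row[1]
        gene2terms.setdefault(gene, set()).add(term)
        if df.shape[1] >= 3 and isinstance(row[2], str):
            term_names[term] = row[2]
    return AnnotationMap(
        gene2terms={g: frozenset(t) for g, t in gene2terms.items()},
        term_names=term_names,
        namespace=namespace,
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def enrich(
    selected: AbstractSet[str],
    annotation: AnnotationMap,
    alpha: float = 0.01,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``selected`` against the
    annotated background; results sorted by p-value.

    Selected genes outside the background are dropped with a warning.
    Significance is strict ``p < alpha`` on the raw p-value, or on the
    Benjamini-Hochberg adjusted one when ``adjust`` is set.
    """
    background = annotation.background
    n_dropped = len(set(selected) - background)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} selected gene(s) not in the annotated background were dropped",
            stacklevel=2,
        )
    sel = set(selected) & background
    if not sel:
        raise ValueError("no selected genes remain after intersecting with the background")
    N = len(background)
    n = len(sel)
    t2g = annotation.term2genes()
    terms = sorted(t2g)
    ks = np.array([len(t2g[t] & sel) for t in terms])
    Ks = np.array([len(t2g[t]) for t in terms])
    pvals = stats.hypergeom.sf(ks - 1, N, Ks, n)
    padj = _bh_adjust(pvals) if adjust else pvals.copy()
    results = [
        EnrichmentResult(
            term=t,
            name=annotation.term_names.get(t, ""),
            k=int(k),
            n=n,
            K=int(K),
            N=N,
            p=float(p),
            p_adjusted=float(pa),
            significant=bool((pa if adjust else p) < alpha),
        )
        for t, k, K, p, pa in zip(terms, ks, Ks, pvals, padj)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term", "name", "k", "n", "K", "N", "p", "p_adjusted", "significant"]
    return pd.DataFrame([r.__dict__ for r in results], columns=cols)


def compare_term_sets(
    a: AbstractSet[str], b: AbstractSet[str]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(shared, only_a, only_b) exact set comparison of enriched-term sets."""
    a, b = frozenset(a), frozenset(b)
    return a & b, a - b, b - a
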