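"""Joint virus+host RSCU PCA and circle-based selection of host genes with
virus-like codon usage, plus the missing-tRNA codon report.

The PCA is computed on the stacked (host genes + viruses) 59-column RSCU
matrix with column mean-centering and no variance scaling, matching R's
``prcomp`` defaults.  Axis signs are fixed so that each axis's
largest-magnitude loading is positive, making score tables reproducible
across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import hypot
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cub_metrics import RSCU_OVER, RscuVector
from .genetic_code import RSCU_CODONS


@dataclass(frozen=True)
class PcaProjection:
    scores: pd.DataFrame  # index: id; columns pc1..pck
    variance_explained: tuple[float, ...]  # full spectrum, non-increasing
    loadings: pd.DataFrame  # 59 x k
    virus_ids: frozenset[str]
    host_ids: frozenset[str]


@dataclass(frozen=True)
class SelectionCircle:
    center: tuple[float, float]
    radius: float
    member_virus_ids: tuple[str, ...]


@dataclass(frozen=True)
class SimilaritySelection:
    circle: SelectionCircle
    selected_gene_ids: tuple[str, ...]


def rscu_pca(
    host_rscu: pd.DataFrame, virus_rscu: pd.DataFrame, n_components: int = 4
) -> PcaProjection:
    """PCA of the stacked host+virus RSCU matrix (mean-centered, unscaled)."""
    for df in (host_rscu, virus_rscu):
        missing = set(RSCU_CODONS) - set(df.columns)
        if missing:
            raise ValueError(f"RSCU matrix missing codon columns: {sorted(missing)}")
    overlap = set(host_rscu.index) & set(virus_rscu.index)
    if overlap:
        raise ValueError(f"ids present in both matrices: {sorted(overlap)}")
    stacked = pd.concat(
        [host_rscu[list(RSCU_CODONS)], virus_rscu[list(RSCU_CODONS)]], axis=0
    )
    n = len(stacked)
    if n < 2:
        raise ValueError("need at least 2 rows for PCA")
    x = stacked.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic axis signs: largest-magnitude loading positive
    for j in range(len(s)):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    var = s**2 / max(float((s**2).sum()), np.finfo(float).tiny)
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=stacked.index,
        columns=[f"pc{j + 1}" for j in range(k)],
    )
    loadings = pd.DataFrame(
        vt[:k].T, index=list(RSCU_CODONS), columns=[f"pc{j + 1}" for j in range(k)]
    )
    return PcaProjection(
        scores=scores,
        variance_explained=tuple(float(v) for v in var),
        loadings=loadings,
        virus_ids=frozenset(virus_rscu.index),
        host_ids=frozenset(host_rscu.index),
    )


def _score_xy(projection: PcaProjection, seq_id: str) -> tuple[float, float]:
    if seq_id not in projection.scores.index:
        raise KeyError(f"id {seq_id!r} not in projection")
    row = projection.scores.loc[seq_id]
    return float(row["pc1"]), float(row["pc2"])


def cluster_circle(projection: PcaProjection, virus_ids: Sequence[str]) -> SelectionCircle:
    """Circle centered at the mean (PC1, PC2) of the listed viruses, with the
    minimal radius (given that center) covering all of them."""
    if not virus_ids:
        raise ValueError("virus_ids must be non-empty")
    pts = [_score_xy(projection, v) for v in virus_ids]
    a = sum(p[0] for p in pts) / len(pts)
    b = sum(p[1] for p in pts) / len(pts)
    radius = max(hypot(x - a, y - b) for x, y in pts)
    return SelectionCircle(center=(a, b), radius=radius, member_virus_ids=tuple(virus_ids))


def select_similar_genes(
    projection: PcaProjection, circle: SelectionCircle
) -> SimilaritySelection:
    """Host genes whose (PC1, PC2) falls inside the closed disk."""
    a, b = circle.center
    r2 = circle.radius**2
    selected = []
    for gene_id in projection.scores.index:
        if gene_id in projection.virus_ids:
            continue
        x, y = _score_xy(projection, gene_id)
        if (x - a) ** 2 + (y - b) ** 2 <= r2:
            selected.append(gene_id)
    return SimilaritySelection(circle=circle, selected_gene_ids=tuple(selected))


def per_virus_circle(
    projection: PcaProjection, virus_id: str, radius: float = 0.3
) -> SimilaritySelection:
    """Selection around a single virus's score with a fixed radius."""
    center = _score_xy(projection, virus_id)
    circle = SelectionCircle(center=center, radius=radius, member_virus_ids=(virus_id,))
    return select_similar_genes(projection, circle)


def missing_trna_codon_report(
    rscu_vectors: Mapping[str, RscuVector] | Iterable[tuple[str, RscuVector]],
    trna_table: Mapping[str, int],
) -> pd.DataFrame:
    """RSCU usage of codons whose cognate tRNA copy number is zero.

    One row per (sequence, zero-copy codon) with the RSCU value, class and an
    over-representation flag (RSCU > 1.6).
    """
    if isinstance(rscu_vectors, Mapping):
        items = list(rscu_vectors.items())
    else:
        items = list(rscu_vectors)
    zero_codons = sorted(c for c, n in trna_table.items() if n == 0)
    rows = []
    for seq_id, vec in items:
        for codon in zero_codons:
            if codon not in vec.values:
                continue
            v = vec.values[codon]
            rows.append(
                {
                    "id": seq_id,
                    "codon": codon,
                    "rscu": v,
                    "class": vec.classes[codon],
                    "over_represented": v > RSCU_OVER,
                }
            )
    return pd.DataFrame(rows, columns=["id", "codon", "rscu", "class", "over_represented"])


def read_trna_table(path: str) -> dict[str, int]:
    """Two-column TSV (codon, copy_number) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    if not {"codon", "copy_number"} <= set(df.columns):
        raise ValueError("tRNA table needs 'codon' and 'copy_number' columns")
    return dict(zip(df["codon"].str.upper(), df["copy_number"].astype(int)))
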