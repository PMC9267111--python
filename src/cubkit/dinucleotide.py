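"""Relative dinucleotide abundance (odds ratios) over whole coding sequences.

rho_xy = f_xy / (f_x * f_y) with f_xy counted over all L-1 overlapping
windows of the linear sequence (codon boundaries and the stop codon
included, no circularization) and f_x the mononucleotide frequency over L.
A pair is over-represented when rho > 1.23 and under-represented when
rho < 0.78 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .genetic_code import BASES, DINUCLEOTIDES
from .seqio import CodingSequence

DINUC_OVER = 1.23
DINUC_UNDER = 0.78


@dataclass(frozen=True)
class DinucleotideProfile:
    id: str
    rho: Mapping[str, Optional[float]]
    classes: Mapping[str, Optional[str]]


def classify_rho(value: float) -> str:
    if value > DINUC_OVER:
        return "over"
    if value < DINUC_UNDER:
        return "under"
    return "normal"


def dinucleotide_abundance(seq: CodingSequence) -> DinucleotideProfile:
    s = seq.sequence
    if len(s) < 2:
        raise ValueError(f"{seq.id}: sequence shorter than 2 nt")
    n = len(s)
    mono = {b: s.count(b) / n for b in BASES}
    pair_counts = {d: 0 for d in DINUCLEOTIDES}
    for i in range(n - 1):
        pair = s[i : i + 2]
        if pair in pair_counts:
            pair_counts[pair] += 1
    rho: dict[str, Optional[float]] = {}
    classes: dict[str, Optional[str]] = {}
    for d in DINUCLEOTIDES:
        denom = mono[d[0]] * mono[d[1]]
        if denom == 0:
            rho[d] = None
            classes[d] = None
        else:
            f_xy = pair_counts[d] / (n - 1)
            rho[d] = f_xy / denom
            classes[d] = classify_rho(rho[d])
    return DinucleotideProfile(id=seq.id, rho=rho, classes=classes)


def dinucleotide_table(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-sequence table: 16 rho columns followed by 16 class columns."""
    rows = []
    for s in seqs:
        prof = dinucleotide_abundance(s)
        row: dict[str, object] = {"id": s.id}
        row.update({f"rho_{d}": prof.rho[d] for d in DINUCLEOTIDES})
        row.update({f"class_{d}": prof.classes[d] for d in DINUCLEOTIDES})
        rows.append(row)
    cols = ["id"] + [f"rho_{d}" for d in DINUCLEOTIDES] + [f"class_{d}" for d in DINUCLEOTIDES]
    return pd.DataFrame(rows, columns=cols)


def group_summary(table: pd.DataFrame, groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean ± sd of each rho column per group label (e.g. genome type or family)."""
    df = table.copy()
    df["group"] = df["id"].map(groups)
    rho_cols = [c for c in df.columns if c.startswith("rho_")]
    agg = df.groupby("group", dropna=True)[rho_cols].agg(["mean", "std"])
    agg.columns = [f"{col}_{stat}" for col, stat in agg.columns]
    return agg.reset_index()
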