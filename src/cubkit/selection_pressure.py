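"""Mutation-versus-selection diagnostics.

PR2 coordinates pool third-position counts over the eight four-codon sets;
the neutrality fit is an ordinary least-squares regression of GC12 on GC3
with an optional 1.5×IQR outlier filter; the ENc–GC3s table flags sequences
strictly below the expected-ENc curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cub_metrics import CodonCountTable, expected_enc
from .genetic_code import PR2_QUARTET_PREFIXES


@dataclass(frozen=True)
class Pr2Point:
    id: str
    at_bias: Optional[float]  # A3/(A3+T3) over four-codon families
    gc_bias: Optional[float]  # G3/(G3+C3)


@dataclass(frozen=True)
class NeutralityFit:
    host: str
    slope: float
    intercept: float
    r: float
    n_used: int
    removed_ids: tuple[str, ...]


@dataclass(frozen=True)
class EncGc3sPoint:
    id: str
    gc3s: float  # percent
    enc: float
    expected: float
    below_curve: bool


def pr2_point(counts: CodonCountTable, seq_id: str = "") -> Pr2Point:
    """PR2 biases from third-position counts pooled over the eight quartets."""
    third = {b: 0 for b in "ACGT"}
    for prefix in PR2_QUARTET_PREFIXES:
        for b in "ACGT":
            third[b] += counts.counts[prefix + b]
    at = third["A"] + third["T"]
    gc = third["G"] + third["C"]
    return Pr2Point(
        id=seq_id,
        at_bias=third["A"] / at if at else None,
        gc_bias=third["G"] / gc if gc else None,
    )


def pr2_table(points: Iterable[Pr2Point]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": p.id, "at_bias": p.at_bias, "gc_bias": p.gc_bias} for p in points],
        columns=["id", "at_bias", "gc_bias"],
    )


def _iqr_fences(x: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def neutrality_fit(
    points: Sequence[tuple[str, float, float]],
    outlier_rule: str = "iqr1.5",
    host: str = "",
) -> NeutralityFit:
    """OLS regression of GC12 on GC3 over (id, gc12, gc3) triples.

    ``outlier_rule='iqr1.5'`` removes points whose GC12 or GC3 lies outside
    the 1.5×IQR fences of its own variable; ``'none'`` keeps everything.
    """
    if outlier_rule not in ("none", "iqr1.5"):
        raise ValueError(f"unknown outlier rule {outlier_rule!r}")
    ids = np.array([p[0] for p in points])
    gc12 = np.asarray([p[1] for p in points], dtype=float)
    gc3 = np.asarray([p[2] for p in points], dtype=float)
    keep = np.ones(len(ids), dtype=bool)
    if outlier_rule == "iqr1.5" and len(ids) >= 4:
        lo12, hi12 = _iqr_fences(gc12)
        lo3, hi3 = _iqr_fences(gc3)
        keep = (gc12 >= lo12) & (gc12 <= hi12) & (gc3 >= lo3) & (gc3 <= hi3)
    removed = tuple(ids[~keep])
    gc12, gc3 = gc12[keep], gc3[keep]
    if len(gc3) < 3:
        raise ValueError(f"need at least 3 points after outlier removal, have {len(gc3)}")
    if np.ptp(gc3) == 0:
        raise ValueError("zero variance in GC3")
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        host=host,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n_used=int(len(gc3)),
        removed_ids=removed,
    )


def enc_gc3s_table(
    profiles: Iterable[tuple[str, float, float]]
) -> list[EncGc3sPoint]:
    """Expected-ENc comparison for (id, gc3s_percent, enc) entries.

    ``below_curve`` uses strict inequality: boundary points are not below.
    """
    out = []
    for seq_id, gc3s_pct, enc_val in profiles:
        exp = expected_enc(gc3s_pct / 100.0)
        out.append(
            EncGc3sPoint(
                id=seq_id,
                gc3s=gc3s_pct,
                enc=enc_val,
                expected=exp,
                below_curve=enc_val < exp,
            )
        )
    return out


def pearson(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Sample correlation and two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
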