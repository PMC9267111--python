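"""Nucleotide composition and positional GC statistics.

Whole-sequence base percentages are computed over the complete CDS including
the stop codon.  Positional GC statistics exclude codons as follows:

* GC1, GC2, GC3: ATG, TGG and the three stop codons are dropped;
* GC3 additionally drops the isoleucine codons ATT, ATC, ATA;
* GC3s is restricted to codons of amino acids with at least two synonymous
  codons (Met, Trp and stops excluded) — the CodonW convention.

A statistic whose exclusion set empties the codon list is reported as
``None`` (missing), never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .genetic_code import CODON_TO_AA, DEGENERACY, STOP_CODONS
from .seqio import CodingSequence

_GC = frozenset("GC")
_ILE_CODONS = ("ATA", "ATC", "ATT")
_EXCLUDED_GC12 = frozenset(("ATG", "TGG") + STOP_CODONS)
_EXCLUDED_GC3 = _EXCLUDED_GC12 | frozenset(_ILE_CODONS)


@dataclass(frozen=True)
class CompositionProfile:
    id: str
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    gc_pct: float
    gc1: Optional[float]
    gc2: Optional[float]
    gc3: Optional[float]
    gc12: Optional[float]
    gc3s: Optional[float]


def nucleotide_composition(seq: CodingSequence) -> tuple[float, float, float, float, float]:
    """(A%, C%, G%, T%, GC%) over the full CDS, stop codon included."""
    s = seq.sequence
    if not s:
        raise ValueError(f"{seq.id}: empty sequence")
    n = len(s)
    a = 100.0 * s.count("A") / n
    c = 100.0 * s.count("C") / n
    g = 100.0 * s.count("G") / n
    t = 100.0 * s.count("T") / n
    return a, c, g, t, g + c


def _gc_fraction_at(codons: list[str], pos: int) -> Optional[float]:
    if not codons:
        return None
    hits = sum(1 for c in codons if c[pos] in _GC)
    return 100.0 * hits / len(codons)


def positional_gc(
    seq: CodingSequence,
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """(GC1, GC2, GC3, GC12) with the neutrality-plot codon exclusions."""
    codons = seq.codons()
    kept12 = [c for c in codons if c not in _EXCLUDED_GC12]
    kept3 = [c for c in codons if c not in _EXCLUDED_GC3]
    gc1 = _gc_fraction_at(kept12, 0)
    gc2 = _gc_fraction_at(kept12, 1)
    gc3 = _gc_fraction_at(kept3, 2)
    gc12 = (gc1 + gc2) / 2.0 if gc1 is not None and gc2 is not None else None
    return gc1, gc2, gc3, gc12


def gc3s(seq: CodingSequence) -> Optional[float]:
    """Third-position G+C percentage over synonymously-coded codons only."""
    kept = [
        c
        for c in seq.codons()
        if c in CODON_TO_AA and DEGENERACY[CODON_TO_AA[c]] >= 2
    ]
    return _gc_fraction_at(kept, 2)


def composition_profile(seq: CodingSequence) -> CompositionProfile:
    a, c, g, t, gc = nucleotide_composition(seq)
    gc1, gc2, gc3, gc12 = positional_gc(seq)
    return CompositionProfile(
        id=seq.id,
        a_pct=a,
        c_pct=c,
        g_pct=g,
        t_pct=t,
        gc_pct=gc,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=gc12,
        gc3s=gc3s(seq),
    )


def composition_table(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    """One row per sequence with every CompositionProfile field (None -> NaN)."""
    rows = [composition_profile(s).__dict__ for s in seqs]
    return pd.DataFrame(rows, columns=list(CompositionProfile.__dataclass_fields__))
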