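"""Codon counting, RSCU, Wright's effective number of codons and the
expected ENc–GC3s curve.

ENc follows the CodonW conventions: six-fold families are kept whole, a
family with fewer than two counted codons (or a zero homozygosity estimate)
borrows the mean of the observed families in its degeneracy class, and an
unobservable three-fold class (Ile) is estimated as the mean of the two- and
four-fold class averages.  The final value is capped at 61; the raw value is
kept for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    ENC_CLASSES,
    RSCU_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
)
from .seqio import CodingSequence

RSCU_OVER = 1.6
RSCU_UNDER = 0.6


@dataclass(frozen=True)
class CodonCountTable:
    """Counts of the 61 sense codons (stop codons are never keyed)."""

    counts: Mapping[str, int]
    total: int

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "CodonCountTable":
        bad = set(counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in count table: {sorted(bad)}")
        full = {c: int(counts.get(c, 0)) for c in SENSE_CODONS}
        if any(v < 0 for v in full.values()):
            raise ValueError("negative codon count")
        return cls(counts=full, total=sum(full.values()))


@dataclass(frozen=True)
class RscuVector:
    """59 RSCU values with over/normal/under/absent classes."""

    values: Mapping[str, float]
    classes: Mapping[str, str]


@dataclass(frozen=True)
class EncValue:
    enc: Optional[float]
    raw: Optional[float]
    family_homozygosities: Mapping[int, Optional[float]] = field(default_factory=dict)


def count_codons(seq: CodingSequence) -> CodonCountTable:
    """Tally frame-0 codons of a validated CDS; the terminal stop is dropped."""
    codons = seq.codons()
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError(f"{seq.id}: internal stop codon {c}")
        if c not in counts:
            raise ValueError(f"{seq.id}: unexpected codon {c!r}")
        counts[c] += 1
    return CodonCountTable(counts=counts, total=sum(counts.values()))


def pool_counts(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    pooled = {c: 0 for c in SENSE_CODONS}
    for t in tables:
        for c, v in t.counts.items():
            pooled[c] += v
    return CodonCountTable(counts=pooled, total=sum(pooled.values()))


def classify_rscu(value: float, observed_family: bool) -> str:
    if not observed_family:
        return "absent"
    if value > RSCU_OVER:
        return "over"
    if value < RSCU_UNDER:
        return "under"
    return "normal"


def rscu(counts: CodonCountTable) -> RscuVector:
    """Relative synonymous codon usage over the 59 informative codons.

    RSCU of codon j in a family of size k is ``x_j / (sum(x)/k)``.  Families
    with zero total get value 0 and class ``absent`` so that downstream
    matrices stay complete while absence remains auditable.
    """
    values: dict[str, float] = {}
    classes: dict[str, str] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa in ("M", "W"):
            continue
        k = len(codons)
        fam_total = sum(counts.counts[c] for c in codons)
        for c in codons:
            if fam_total == 0:
                values[c] = 0.0
                classes[c] = "absent"
            else:
                v = counts.counts[c] * k / fam_total
                values[c] = v
                classes[c] = classify_rscu(v, True)
    return RscuVector(values=values, classes=classes)


def rscu_table(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-sequence RSCU matrix; columns are the fixed 59-codon order."""
    rows = {}
    for s in seqs:
        rows[s.id] = rscu(count_codons(s)).values
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=list(RSCU_CODONS))


def _family_homozygosity(counts: CodonCountTable, codons: tuple[str, ...]) -> Optional[float]:
    n = sum(counts.counts[c] for c in codons)
    if n < 2:
        return None
    s = sum((counts.counts[c] / n) ** 2 for c in codons)
    f = (n * s - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc(counts: CodonCountTable) -> EncValue:
    """Wright's effective number of codons.

    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk is the mean homozygosity
    of the observed families in the k-fold degeneracy class.
    """
    class_means: dict[int, Optional[float]] = {}
    for k, aas in ENC_CLASSES.items():
        fs = [
            f
            for aa in aas
            if (f := _family_homozygosity(counts, AA_TO_CODONS[aa])) is not None
        ]
        class_means[k] = sum(fs) / len(fs) if fs else None
    if class_means[3] is None and class_means[2] is not None and class_means[4] is not None:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    if any(class_means[k] is None for k in (2, 3, 4, 6)):
        return EncValue(enc=None, raw=None, family_homozygosities=class_means)
    raw = (
        2.0
        + 9.0 / class_means[2]
        + 1.0 / class_means[3]
        + 5.0 / class_means[4]
        + 3.0 / class_means[6]
    )
    return EncValue(enc=min(raw, 61.0), raw=raw, family_homozygosities=class_means)


def enc_table(seqs: Iterable[CodingSequence]) -> pd.DataFrame:
    rows = []
    for s in seqs:
        e = enc(count_codons(s))
        rows.append({"id": s.id, "enc": e.enc, "enc_raw": e.raw})
    return pd.DataFrame(rows, columns=["id", "enc", "enc_raw"])


def expected_enc(gc3s_fraction: float) -> float:
    """Expected ENc at synonymous third-position G+C fraction ``s`` in [0, 1]:
    ``2 + s + 29 / (s**2 + (1 - s)**2)``."""
    s = gc3s_fraction
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))
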