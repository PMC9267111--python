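"""Reading, labelling and validating coding sequences.

Inclusion criteria for a CDS: longer than ``min_length_nt`` nucleotides
(strict), length divisible by three, ATG start, stop-codon end, no internal
stop codons and no bases outside {A, C, G, T}.  Failures are reported, never
raised, so that a whole input set can be screened in one pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .genetic_code import BASES, STOP_CODONS

VIRUS = "virus"
HOST = "host"

GENOME_TYPES = ("(+)ssRNA", "(-)ssRNA", "dsRNA")

#: fixed order of validation failure codes
FAILURE_REASONS = (
    "too_short",
    "no_start",
    "no_stop",
    "internal_stop",
    "not_multiple_of_3",
    "degenerate_base",
)


@dataclass(frozen=True)
class CodingSequence:
    """A single labelled coding sequence on the DNA alphabet."""

    id: str
    sequence: str
    origin: str = HOST
    host_species: str = ""
    genome_type: Optional[str] = None
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.origin not in (VIRUS, HOST):
            raise ValueError(f"origin must be '{VIRUS}' or '{HOST}', got {self.origin!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        """Frame-0 codons (complete triplets only)."""
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


@dataclass(frozen=True)
class ValidationReport:
    id: str
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when reasons is empty")


def validate_cds(seq: CodingSequence, min_length_nt: int = 300) -> ValidationReport:
    """Screen one sequence against the CDS inclusion criteria.

    Pure function of the input; the reasons tuple follows the fixed order of
    :data:`FAILURE_REASONS`.
    """
    s = seq.sequence
    if not s:
        raise ValueError(f"{seq.id}: empty sequence")
    reasons: list[str] = []
    if len(s) <= min_length_nt:
        reasons.append("too_short")
    if not s.startswith("ATG"):
        reasons.append("no_start")
    codons = seq.codons()
    if not codons or codons[-1] not in STOP_CODONS:
        reasons.append("no_stop")
    if any(c in STOP_CODONS for c in codons[:-1]):
        reasons.append("internal_stop")
    if len(s) % 3 != 0:
        reasons.append("not_multiple_of_3")
    if set(s) - set(BASES):
        reasons.append("degenerate_base")
    return ValidationReport(id=seq.id, passed=not reasons, reasons=tuple(reasons))


def read_cds_fasta(
    path: str | Path,
    origin: str = HOST,
    labels: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[CodingSequence]:
    """Read a (multi-)FASTA file into :class:`CodingSequence` records.

    Sequences are uppercased and U is mapped to T.  ``labels`` maps record id
    to a dict with any of ``origin``, ``host_species``, ``genome_type``,
    ``family``; matching entries override the defaults.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        lab = dict(labels.get(rec.id, {})) if labels else {}
        records.append(
            CodingSequence(
                id=rec.id,
                sequence=seq,
                origin=lab.get("origin", origin),
                host_species=lab.get("host_species", ""),
                genome_type=lab.get("genome_type") or None,
                family=lab.get("family") or None,
            )
        )
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def read_labels(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a label TSV (columns: id plus any of origin/host_species/genome_type/family)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise ValueError(f"{path}: label table must have an 'id' column")
    known = [c for c in ("origin", "host_species", "genome_type", "family") if c in df.columns]
    return {
        row["id"]: {k: row[k] for k in known if row[k]} for _, row in df.iterrows()
    }


def filter_valid(
    seqs: Iterable[CodingSequence], min_length_nt: int = 300
) -> tuple[list[CodingSequence], list[ValidationReport]]:
    """Split sequences into the ones passing validation and the full report list."""
    seqs = list(seqs)
    reports = [validate_cds(s, min_length_nt) for s in seqs]
    passed = [s for s, r in zip(seqs, reports) if r.passed]
    return passed, reports


def validation_table(reports: Iterable[ValidationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in reports],
            "passed": [r.passed for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )


def write_cds_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), 70):
                fh.write(s.sequence[i : i + 70] + "\n")
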