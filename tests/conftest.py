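import numpy as np
import pytest

from cubkit.cub_metrics import CodonCountTable
from cubkit.genetic_code import SENSE_CODONS, STOP_CODONS
from cubkit.seqio import CodingSequence

NON_STOP_FILLER = "GCT"  # Ala codon used to pad sequences


def build_cds(codons, seq_id="test", start="ATG", stop="TAA", **kwargs):
    """Assemble a CDS string from body codons (no validation implied)."""
    return CodingSequence(id=seq_id, sequence=start + "".join(codons) + stop, **kwargs)


@pytest.fixture
def valid_cds():
    """303-nt CDS: ATG + 99 filler codons + TAA."""
    return build_cds([NON_STOP_FILLER] * 99)


@pytest.fixture
def random_count_table():
    """Factory for random codon count tables (all 61 sense codons keyed)."""

    def make(rng: np.random.Generator, low: int = 0, high: int = 30) -> CodonCountTable:
        counts = {c: int(rng.integers(low, high + 1)) for c in SENSE_CODONS}
        return CodonCountTable.from_counts(counts)

    return make


@pytest.fixture
def write_fasta(tmp_path):
    def write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return write


def assert_no_stops(seq: str) -> None:
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    assert not any(c in STOP_CODONS for c in codons[1:])
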