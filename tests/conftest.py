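import numpy as np
import pytest

from cubkit.codon_metrics import CodonCountTable
from cubkit.genetic_code import CODONS, GENETIC_CODE, STOP_CODONS
from cubkit.sequence_io import CodingSequence


def make_cds(body_codons: list[str], gene_id: str = "g1", stop: str = "TAA") -> CodingSequence:
    """Assemble a valid CDS from body codons (start/stop added)."""
    return CodingSequence(gene_id, "ATG" + "".join(body_codons) + stop)


def random_count_table(rng: np.random.Generator, max_count: int = 30) -> CodonCountTable:
    """A random small codon table over sense codons (stops left at 0)."""
    counts = rng.integers(0, max_count + 1, size=64)
    for stop in STOP_CODONS:
        counts[CODONS.index(stop)] = 0
    return CodonCountTable(counts.astype(np.int64))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def uniform_gene() -> CodingSequence:
    """A CDS using every sense codon of every family exactly once."""
    body = [c for aa, codons in sorted(GENETIC_CODE.items()) for c in codons]
    return make_cds(body, "uniform")


@pytest.fixture
def filter_fixture_records() -> list[tuple[str, str]]:
    """Eight records: one violation per filter rule plus two valid CDS."""
    valid_body = "AAA" * 98
    return [
        ("ok1", "ATG" + valid_body + "TAA"),
        ("short", "ATG" + "AAA" * 32 + "TAA"),              # 102 nt < 300
        ("frameshift", "ATG" + valid_body + "TAA" + "A"),   # 301 nt, not /3
        ("nostart", "TTG" + valid_body + "TAA"),
        ("nostop", "ATG" + valid_body + "AAA"),
        ("ambiguous", "ATG" + "AAA" * 97 + "AAN" + "TAA"),
        ("internalstop", "ATG" + "AAA" * 49 + "TAA" + "AAA" * 48 + "TAA"),
        ("ok2", "ATG" + "GGC" * 98 + "TGA"),
    ]
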