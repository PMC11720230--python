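"""CDS FASTA ingestion and quality filtering.

Coding sequences are screened with the conventional rules for codon-usage
work: a minimum length (default 300 nt), an intact reading frame, an ATG
start, a canonical stop (TAA/TAG/TGA), no ambiguous nucleotides, and no
internal stop codon.  Rejections are data, not errors: each rejected record
is attributed to the FIRST failing rule in a fixed order so reports are
deterministic.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import STOP_CODONS

logger = logging.getLogger(__name__)

#: fixed rule order; the first failing rule is the one reported
FILTER_RULES: tuple[str, ...] = (
    "duplicate_id",
    "too_short",
    "not_multiple_of_3",
    "no_start_codon",
    "no_canonical_stop",
    "ambiguous_base",
    "internal_stop",
)

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence (passed :func:`filter_cds`)."""

    gene_id: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass
class FilterReport:
    """Outcome of filtering one FASTA: who was kept, who failed, and why."""

    kept_count: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)
    rule_tallies: dict[str, int] = field(default_factory=dict)

    @property
    def input_count(self) -> int:
        return self.kept_count + len(self.rejected)

    def to_rows(self, kept_ids: list[str]) -> list[tuple[str, str, str]]:
        rows = [(gid, "kept", "") for gid in kept_ids]
        rows += [(gid, "rejected", rule) for gid, rule in self.rejected]
        return rows


def read_cds_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (plain or gzipped) FASTA into ``(id, sequence)`` pairs.

    Sequences are uppercased and U is normalized to T so mRNA-style files
    are accepted.  The record ID is the first whitespace-delimited token of
    the header, per FASTA convention.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[tuple[str, str]] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def first_failing_rule(sequence: str, min_len: int = 300) -> str | None:
    """Return the first violated filter rule, or None if the CDS is clean."""
    if len(sequence) < min_len:
        return "too_short"
    if len(sequence) % 3:
        return "not_multiple_of_3"
    if not sequence.startswith("ATG"):
        return "no_start_codon"
    if sequence[-3:] not in STOP_CODONS:
        return "no_canonical_stop"
    if not _ACGT.issuperset(sequence):
        return "ambiguous_base"
    for i in range(0, len(sequence) - 3, 3):
        if sequence[i : i + 3] in STOP_CODONS:
            return "internal_stop"
    return None


def filter_cds(
    records: list[tuple[str, str]], min_len: int = 300
) -> tuple[list[CodingSequence], FilterReport]:
    """Apply the CDS quality rules; return kept sequences and a report.

    Duplicate gene IDs (common in annotation dumps that repeat isoform IDs)
    keep the first occurrence; later copies are reported under the
    ``duplicate_id`` rule.
    """
    kept: list[CodingSequence] = []
    report = FilterReport(rule_tallies={r: 0 for r in FILTER_RULES})
    seen: set[str] = set()
    for gene_id, seq in records:
        if gene_id in seen:
            logger.warning("duplicate gene ID %r: keeping first occurrence", gene_id)
            rule = "duplicate_id"
        else:
            seen.add(gene_id)
            rule = first_failing_rule(seq, min_len=min_len)
        if rule is None:
            kept.append(CodingSequence(gene_id, seq))
            report.kept_count += 1
        else:
            report.rejected.append((gene_id, rule))
            report.rule_tallies[rule] += 1
    return kept, report


def translate(cds: CodingSequence) -> str:
    """Translate a filtered CDS (standard code); terminal stop excluded."""
    protein = str(Seq(cds.sequence).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon in {cds.gene_id}")
    return protein


def write_fasta(sequences: list[CodingSequence], path: str | Path, width: int = 70) -> None:
    """Write coding sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for cds in sequences:
            fh.write(f">{cds.gene_id}\n")
            for i in range(0, len(cds.sequence), width):
                fh.write(cds.sequence[i : i + width] + "\n")


def write_filter_report(
    report: FilterReport, kept_ids: list[str], path: str | Path
) -> None:
    """Write a TSV filter report: gene_id, status, failed_rule."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstatus\tfailed_rule\n")
        for row in report.to_rows(kept_ids):
            fh.write("\t".join(row) + "\n")
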