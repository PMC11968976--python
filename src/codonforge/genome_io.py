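"""Coding-sequence I/O, validation and translation.

A coding sequence (CDS) runs from a start codon through a stop codon in a
single reading frame. Corpora are filtered with four rules, applied in a
fixed order: length divisible by three, starts with a start codon, ends
with a stop codon, and contains exactly one in-frame stop (the terminal
one). Translation uses NCBI translation tables (via Biopython), with the
stop rendered as ``"_"`` and alternative start codons optionally re-coded
to methionine, following the NCBI CDS convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable as _NCBICodonTable

logger = logging.getLogger(__name__)

STOP_SYMBOL = "_"
_DNA_ALPHABET = frozenset("ACGT")

#: Validation rules in the order they are applied and reported.
VALIDATION_RULES = (
    "alphabet",
    "length divisible by three",
    "start codon",
    "stop codon",
    "single stop codon",
)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the line."""


@dataclass(frozen=True)
class TranslationTable:
    """An NCBI translation table with stops rendered as ``"_"``."""

    table_id: int
    codon_to_aa: Mapping[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"translation table must cover all 64 codons, got {len(self.codon_to_aa)}"
            )
        for codon in self.stop_codons:
            if self.codon_to_aa[codon] != STOP_SYMBOL:
                raise ValueError(f"stop codon {codon} does not map to '{STOP_SYMBOL}'")

    @classmethod
    def from_ncbi(cls, table_id: int = 1) -> "TranslationTable":
        """Build from Biopython's registry of NCBI translation tables."""
        try:
            ncbi = _NCBICodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise KeyError(f"unknown NCBI translation table id {table_id}") from exc
        codon_to_aa = dict(ncbi.forward_table)
        for codon in ncbi.stop_codons:
            codon_to_aa[codon] = STOP_SYMBOL
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            start_codons=frozenset(ncbi.start_codons),
            stop_codons=frozenset(ncbi.stop_codons),
        )

    def families(self) -> dict[str, list[str]]:
        """Synonymous-codon families: amino acid -> sorted codons."""
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.codon_to_aa):
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return fams


@dataclass(frozen=True)
class GeneRecord:
    """One validated CDS with its protein translation and organism label."""

    id: str
    dna: str
    protein: str
    organism: str

    def __post_init__(self) -> None:
        if len(self.dna) != 3 * len(self.protein):
            raise ValueError(f"{self.id}: DNA length {len(self.dna)} != 3 x protein length")
        if self.protein.count(STOP_SYMBOL) != 1 or not self.protein.endswith(STOP_SYMBOL):
            raise ValueError(f"{self.id}: protein must end with a single '{STOP_SYMBOL}'")

    @property
    def n_codons(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class ValidationResult:
    passed: bool
    failed_rule: str | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def _canonical_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(header, sequence)`` pairs.

    Sequences are uppercased and RNA ``U`` is transliterated to ``T``.
    Order is preserved; duplicate headers are kept with a logged warning.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    if not chunks:
                        raise FastaParseError(f"{path}: empty record '{header}' before line {lineno}")
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"{path}: sequence data before any header at line {lineno}")
                chunks.append(_canonical_dna(line))
    if header is not None:
        if not chunks:
            raise FastaParseError(f"{path}: empty record '{header}' at end of file")
        records.append((header, "".join(chunks)))
    seen: set[str] = set()
    for name, _ in records:
        if name in seen:
            logger.warning("duplicate FASTA header %r in %s", name, path)
        seen.add(name)
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    """Write ``(header, sequence)`` pairs as wrapped FASTA."""
    with Path(path).open("w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def validate_cds(dna: str, table: TranslationTable) -> ValidationResult:
    """Check the CDS filter rules in order; the first violation is reported.

    Rules (in reporting order): alphabet (A/C/G/T only, no ambiguity
    codes), length divisible by three, starts with a start codon, ends
    with a stop codon, exactly one in-frame stop located terminally.
    """
    dna = _canonical_dna(dna)
    if not dna or set(dna) - _DNA_ALPHABET:
        return ValidationResult(False, "alphabet")
    if len(dna) % 3 != 0:
        return ValidationResult(False, "length divisible by three")
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    if codons[0] not in table.start_codons:
        return ValidationResult(False, "start codon")
    if codons[-1] not in table.stop_codons:
        return ValidationResult(False, "stop codon")
    if any(c in table.stop_codons for c in codons[:-1]):
        return ValidationResult(False, "single stop codon")
    return ValidationResult(True)


def translate_cds(dna: str, table: TranslationTable, recode_start: bool = True) -> str:
    """Translate a codon-aligned DNA string, stop rendered as ``"_"``.

    With ``recode_start`` (default), a first codon listed among the
    table's start codons is rendered ``M`` even when its elongation
    meaning differs (e.g. GTG under table 11), per NCBI CDS convention.
    """
    dna = _canonical_dna(dna)
    if len(dna) % 3 != 0:
        raise ValueError(f"DNA length {len(dna)} not divisible by three")
    out: list[str] = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        try:
            aa = table.codon_to_aa[codon]
        except KeyError as exc:
            raise ValueError(f"invalid codon {codon!r} at nucleotide position {i}") from exc
        if i == 0 and recode_start and codon in table.start_codons:
            aa = "M"
        out.append(aa)
    return "".join(out)


@dataclass
class PreprocessResult:
    records: list[GeneRecord]
    rejections: list[tuple[str, str]] = field(default_factory=list)


def preprocess_corpus(
    inputs: Sequence[tuple[str, str, str]],
    tables: Mapping[str, TranslationTable],
    recode_start: bool = True,
) -> PreprocessResult:
    """Filter ``(id, dna, organism)`` triples into validated gene records.

    Every organism present in the input must have a translation table;
    that is checked before any filtering. Each rejected input yields one
    ``(id, failed_rule)`` row; kept + rejected always equals the input count.
    """
    missing = sorted({org for _, _, org in inputs} - set(tables))
    if missing:
        raise KeyError(f"no translation table for organism(s): {', '.join(missing)}")
    kept: list[GeneRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec_id, dna, organism in inputs:
        table = tables[organism]
        dna = _canonical_dna(dna)
        result = validate_cds(dna, table)
        if not result.passed:
            rejected.append((rec_id, result.failed_rule or "unknown"))
            continue
        protein = translate_cds(dna, table, recode_start=recode_start)
        kept.append(GeneRecord(id=rec_id, dna=dna, protein=protein, organism=organism))
    return PreprocessResult(records=kept, rejections=rejected)


def write_corpus_metadata(path: str | Path, result: PreprocessResult) -> None:
    """Tab-separated manifest: id, organism, length, status, failed_rule."""
    with Path(path).open("w") as handle:
        handle.write("id\torganism\tlength\tstatus\tfailed_rule\n")
        for rec in result.records:
            handle.write(f"{rec.id}\t{rec.organism}\t{len(rec.dna)}\tkept\t\n")
        for rec_id, rule in result.rejections:
            handle.write(f"{rec_id}\t\t\trejected\t{rule}\n")
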