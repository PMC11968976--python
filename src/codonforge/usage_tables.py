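"""Organism codon-usage tables and scalar codon-usage metrics.

The central object is :class:`UsageTable`: per-codon counts aggregated
over a corpus, within-family frequencies, and the relative adaptiveness

    w_ij = x_ij / x_imax

of each codon against the most-used synonym of the same amino acid.
From it follow the sequence-level statistics

* CSI — geometric mean of w over a gene's codons (CAI computed against a
  whole-genome usage table rather than a curated reference set),
* CFD — percentage of rare codons, those with w strictly below 0.30,
* GC  — fraction of G or C nucleotides,

and the fine-tuning gene-selection rule (top fraction of a corpus by CSI).

Conventions (package choices, configurable): codons of single-synonym
amino acids (ATG, TGG under the standard code) and stop codons are
excluded from the CSI geometric mean, as in the classical CAI
implementations; zero-count codons receive a pseudocount of 0.5 before
w is formed so the geometric mean is always defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import STOP_SYMBOL, GeneRecord, TranslationTable

RARE_W_THRESHOLD = 0.30
DEFAULT_PSEUDOCOUNT = 0.5


def iter_codons(dna: str) -> list[str]:
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} is not codon-aligned")
    return [dna[i : i + 3] for i in range(0, len(dna), 3)]


@dataclass(frozen=True)
class UsageTable:
    """Per-organism codon counts with derived frequencies and adaptiveness."""

    organism: str
    table: TranslationTable
    counts: Mapping[str, float]
    freq: Mapping[str, float] = field(init=False)
    family_max: Mapping[str, float] = field(init=False)
    w: Mapping[str, float] = field(init=False)
    rare: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        families = self.table.families()
        freq: dict[str, float] = {}
        family_max: dict[str, float] = {}
        w: dict[str, float] = {}
        for aa, codons in families.items():
            total = sum(self.counts[c] for c in codons)
            fmax = max(self.counts[c] for c in codons)
            if total <= 0:
                raise ValueError(f"family {aa} has zero total count")
            family_max[aa] = fmax
            for c in codons:
                freq[c] = self.counts[c] / total
                w[c] = self.counts[c] / fmax
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "family_max", family_max)
        object.__setattr__(self, "w", w)
        object.__setattr__(
            self, "rare", frozenset(c for c, wc in w.items() if wc < RARE_W_THRESHOLD)
        )

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, float],
        table: TranslationTable,
        organism: str = "unknown",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "UsageTable":
        """Build from raw counts, pseudocounting zero-count codons."""
        full = {c: float(counts.get(c, 0.0)) for c in table.codon_to_aa}
        if all(v == 0.0 for v in full.values()):
            raise ValueError("all codon counts are zero")
        full = {c: (v if v > 0 else pseudocount) for c, v in full.items()}
        return cls(organism=organism, table=table, counts=full)

    def aa_of(self, codon: str) -> str:
        return self.table.codon_to_aa[codon]

    def family(self, aa: str) -> list[str]:
        codons = [c for c, a in self.table.codon_to_aa.items() if a == aa]
        if not codons:
            raise KeyError(f"unknown amino acid {aa!r}")
        return sorted(codons)

    def family_frequencies(self, aa: str) -> dict[str, float]:
        return {c: self.freq[c] for c in self.family(aa)}

    def max_codon(self, aa: str) -> str:
        """Family-maximal codon; ties broken by lexicographic codon order."""
        fam = self.family(aa)
        best = max(self.counts[c] for c in fam)
        return next(c for c in fam if self.counts[c] == best)

    # -- serialization ------------------------------------------------

    def save_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            handle.write("codon\tcount\n")
            for codon in sorted(self.counts):
                handle.write(f"{codon}\t{self.counts[codon]:.6g}\n")

    @classmethod
    def load_tsv(
        cls,
        path: str | Path,
        table: TranslationTable,
        organism: str = "unknown",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "UsageTable":
        """Load a two-column ``codon<TAB>count`` (or frequency) file."""
        counts: dict[str, float] = {}
        with Path(path).open() as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.lower().startswith("codon"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
                counts[parts[0].upper().replace("U", "T")] = float(parts[1])
        return cls.from_counts(counts, table, organism=organism, pseudocount=pseudocount)


def relative_adaptiveness(
    counts: Mapping[str, float], table: TranslationTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> dict[str, float]:
    """Map each codon to w = count / max count within its synonymous family."""
    return dict(UsageTable.from_counts(counts, table, pseudocount=pseudocount).w)


def csi_eligible(codon: str, table: UsageTable) -> bool:
    """Whether a codon enters the CSI geometric mean under the default rule."""
    aa = table.aa_of(codon)
    return aa != STOP_SYMBOL and len(table.family(aa)) > 1


def compute_csi(dna: str, table: UsageTable, include_all: bool = False) -> float:
    """Codon similarity index: geometric mean of relative adaptiveness.

    By default, single-synonym codons (always w = 1) and stop codons are
    excluded; ``include_all=True`` averages over every codon instead.
    """
    codons = iter_codons(dna)
    if include_all:
        eligible = codons
    else:
        eligible = [c for c in codons if csi_eligible(c, table)]
    if not eligible:
        raise ValueError("no CSI-eligible codons in sequence")
    return math.exp(sum(math.log(table.w[c]) for c in eligible) / len(eligible))


def compute_cfd(dna: str, table: UsageTable) -> float:
    """Percentage of rare codons (w < 0.30) among all codons of the gene."""
    codons = iter_codons(dna)
    if not codons:
        return 0.0
    return 100.0 * sum(1 for c in codons if c in table.rare) / len(codons)


def compute_gc(dna: str) -> float:
    """GC fraction of the sequence."""
    if not dna:
        raise ValueError("empty sequence")
    dna = dna.upper()
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return (dna.count("G") + dna.count("C")) / len(dna)


def build_usage_table(
    corpus: Iterable[GeneRecord],
    organism: str,
    table: TranslationTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> UsageTable:
    """Aggregate codon counts of an organism's records into a usage table."""
    counts: dict[str, float] = {}
    n = 0
    for rec in corpus:
        if rec.organism != organism:
            continue
        n += 1
        for codon in iter_codons(rec.dna):
            counts[codon] = counts.get(codon, 0.0) + 1.0
    if n == 0:
        raise ValueError(f"no records for organism {organism!r}")
    return UsageTable.from_counts(counts, table, organism=organism, pseudocount=pseudocount)


def select_top_csi(
    corpus: Sequence[GeneRecord], table: UsageTable, fraction: float = 0.10
) -> list[GeneRecord]:
    """Top ``floor(fraction * N)`` records by CSI, ties broken by id.

    This is the fine-tuning gene-selection rule: keep the genes whose
    codon usage best matches the organism-wide table.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = int(math.floor(fraction * len(corpus)))
    scored = sorted(corpus, key=lambda rec: (-compute_csi(rec.dna, table), rec.id))
    return scored[:k]


def metrics_report(
    corpus: Iterable[GeneRecord], tables: Mapping[str, UsageTable]
) -> list[dict[str, object]]:
    """Per-gene CSI/CFD/GC rows keyed by id and organism."""
    rows = []
    for rec in corpus:
        table = tables[rec.organism]
        rows.append(
            {
                "id": rec.id,
                "organism": rec.organism,
                "CSI": compute_csi(rec.dna, table),
                "CFD": compute_cfd(rec.dna, table),
                "GC": compute_gc(rec.dna),
            }
        )
    return rows
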