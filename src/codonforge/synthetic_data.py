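"""Synthetic multi-organism CDS corpora with controllable codon bias.

Each synthetic organism carries a codon-usage table whose within-family
frequencies are drawn from a symmetric Dirichlet: small concentration
``alpha`` gives strongly skewed families (a few dominant codons, several
rare ones), large ``alpha`` approaches uniform usage. Proteins are
sampled with a leading methionine and terminal stop, then
back-translated codon-by-codon under one of the baseline policies
(URC / BFC / HFC), so every emitted record is a valid CDS and passes
preprocessing unchanged — the generator is a fixed point of the filter.

Mirrored organism pairs (one's family frequency ranking reversed in the
other) exercise organism conditioning: a model sharing all weights can
tell them apart only through the token-type id.

Defaults: Dirichlet alpha 0.3 (marked codon bias, comparable to highly
biased microbial genomes), usage counts materialized at 10,000 codons
per family, gene lengths log-normal over codon counts with median 100
clipped to [25, 500] so every gene supports an 18-codon window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import STOP_SYMBOL, GeneRecord, TranslationTable, write_fasta
from .usage_tables import UsageTable

DEFAULT_ALPHA = 0.3
DEFAULT_FAMILY_DEPTH = 10_000
DEFAULT_LENGTH_MEDIAN = 100
DEFAULT_LENGTH_SIGMA = 0.5
LENGTH_CLIP = (25, 500)
BackTranslatePolicy = str  # "URC" | "BFC" | "HFC"


@dataclass(frozen=True)
class SyntheticOrganism:
    key: str
    table: TranslationTable
    alpha: float
    usage: UsageTable
    seed: int


def make_usage_table(
    rng: np.random.Generator,
    alpha: float,
    table: TranslationTable,
    organism: str = "synthetic",
    family_depth: int = DEFAULT_FAMILY_DEPTH,
) -> UsageTable:
    """Draw per-family codon frequencies from Dirichlet(alpha) and count them.

    Counts are materialized by a multinomial draw of ``family_depth``
    codons per family, so the realized table has integer counts and
    satisfies every usage-table invariant (zero cells pseudocounted).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    counts: dict[str, float] = {}
    for aa, codons in sorted(table.families().items()):
        freqs = rng.dirichlet([alpha] * len(codons))
        fam_counts = rng.multinomial(family_depth, freqs)
        for codon, cnt in zip(codons, fam_counts):
            counts[codon] = float(cnt)
    return UsageTable.from_counts(counts, table, organism=organism)


def mirrored_usage_table(base: UsageTable, organism: str) -> UsageTable:
    """Reverse each family's frequency ranking (most common <-> rarest)."""
    counts: dict[str, float] = {}
    for aa, codons in sorted(base.table.families().items()):
        fam_counts = sorted(base.counts[c] for c in codons)
        order = sorted(codons, key=lambda c: (-base.counts[c], c))
        for codon, cnt in zip(order, fam_counts):
            counts[codon] = cnt
    return UsageTable.from_counts(counts, base.table, organism=organism)


def make_organism(
    key: str,
    seed: int,
    table: TranslationTable | None = None,
    alpha: float = DEFAULT_ALPHA,
    family_depth: int = DEFAULT_FAMILY_DEPTH,
) -> SyntheticOrganism:
    """A reproducible organism: same (key, seed) -> bit-identical table."""
    table = table or TranslationTable.from_ncbi(1)
    rng = np.random.default_rng([seed, len(key)] + [ord(ch) for ch in key])
    usage = make_usage_table(rng, alpha, table, organism=key, family_depth=family_depth)
    return SyntheticOrganism(key=key, table=table, alpha=alpha, usage=usage, seed=seed)


def mirrored_pair(
    key_a: str, key_b: str, seed: int, alpha: float = DEFAULT_ALPHA
) -> tuple[SyntheticOrganism, SyntheticOrganism]:
    """Two organisms whose family frequency rankings are reversed."""
    org_a = make_organism(key_a, seed, alpha=alpha)
    usage_b = mirrored_usage_table(org_a.usage, key_b)
    org_b = SyntheticOrganism(
        key=key_b, table=org_a.table, alpha=alpha, usage=usage_b, seed=seed
    )
    return org_a, org_b


def sample_protein(
    rng: np.random.Generator,
    length: int,
    composition: dict[str, float] | None = None,
) -> str:
    """Random protein of ``length`` codons: leading M, terminal stop.

    ``length`` counts codons including the stop; interior residues are
    drawn uniformly over the 20 amino acids unless weights are given.
    """
    if length < 2:
        raise ValueError("length must be at least 2 codons (start + stop)")
    aas = sorted("ACDEFGHIKLMNPQRSTVWY")
    if composition:
        keys = sorted(composition)
        weights = np.array([composition[k] for k in keys], dtype=float)
        weights /= weights.sum()
        interior = rng.choice(keys, size=length - 2, p=weights)
    else:
        interior = rng.choice(aas, size=length - 2)
    return "M" + "".join(interior) + STOP_SYMBOL


def back_translate(
    protein: str,
    usage: UsageTable,
    rng: np.random.Generator | None = None,
    policy: BackTranslatePolicy = "BFC",
) -> str:
    """Choose one codon per residue under a baseline policy.

    The first codon of an M-initial protein is always ATG and the stop
    is drawn among the table's stop codons per the policy, so the result
    is a valid CDS. Inverse of translation by construction.
    """
    policy = policy.upper()
    if policy not in ("URC", "BFC", "HFC"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy != "HFC" and rng is None:
        raise ValueError(f"policy {policy} requires an rng")
    codons: list[str] = []
    for i, aa in enumerate(protein):
        family = usage.family(aa)
        if i == 0 and aa == "M" and "ATG" in family:
            codons.append("ATG")
            continue
        if policy == "HFC":
            codons.append(usage.max_codon(aa))
        elif policy == "URC":
            codons.append(family[int(rng.integers(len(family)))])
        else:
            freqs = np.array([usage.freq[c] for c in family])
            codons.append(family[int(rng.choice(len(family), p=freqs / freqs.sum()))])
    return "".join(codons)


def sample_gene_lengths(
    rng: np.random.Generator,
    n: int,
    median: float = DEFAULT_LENGTH_MEDIAN,
    sigma: float = DEFAULT_LENGTH_SIGMA,
    clip: tuple[int, int] = LENGTH_CLIP,
) -> np.ndarray:
    """Log-normal codon counts, clipped so %MinMax windows always exist."""
    lengths = np.exp(rng.normal(np.log(median), sigma, size=n))
    return np.clip(np.round(lengths).astype(int), clip[0], clip[1])


def make_corpus(
    n_genes: int,
    organisms: list[SyntheticOrganism],
    seed: int,
    policy: BackTranslatePolicy = "BFC",
    length_median: float = DEFAULT_LENGTH_MEDIAN,
    length_sigma: float = DEFAULT_LENGTH_SIGMA,
) -> list[GeneRecord]:
    """Generate ``n_genes`` valid records split evenly across organisms."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not organisms:
        raise ValueError("at least one organism required")
    rng = np.random.default_rng(seed)
    records: list[GeneRecord] = []
    lengths = sample_gene_lengths(rng, n_genes, median=length_median, sigma=length_sigma)
    for i in range(n_genes):
        org = organisms[i % len(organisms)]
        protein = sample_protein(rng, int(lengths[i]))
        dna = back_translate(protein, org.usage, rng, policy=policy)
        records.append(
            GeneRecord(id=f"{org.key}_g{i:05d}", dna=dna, protein=protein, organism=org.key)
        )
    return records


def write_corpus(
    directory: str | Path,
    records: list[GeneRecord],
    seed: int,
) -> tuple[Path, Path]:
    """Write a corpus as FASTA plus a manifest TSV (id, organism, length, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "corpus.fasta"
    manifest = directory / "manifest.tsv"
    write_fasta(fasta, [(rec.id, rec.dna) for rec in records])
    with manifest.open("w") as handle:
        handle.write("id\torganism\tlength\tseed\n")
        for rec in records:
            handle.write(f"{rec.id}\t{rec.organism}\t{len(rec.dna)}\t{seed}\n")
    return fasta, manifest
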