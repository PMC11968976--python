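"""Codon prediction backends, constrained decoding, and mutation scoring.

Any backend maps an encoded sequence to one probability vector over the
90-token vocabulary per position. Three exact baselines bracket the
learned model:

* URC — uniform random choice over the synonymous family,
* BFC — background-frequency choice, proportional to the organism's
  codon-usage frequencies,
* HFC — highest-frequency choice, a point mass on the family-maximal
  codon.

Decoding is amino-acid-constrained: at each position the distribution
is restricted to the pair tokens whose amino-acid part matches the
target residue and renormalized, so the decoded DNA always translates
back to the input protein. Synonymous mutations are scored zero-shot as
ln p(mutant token) - ln p(wild-type token) from the distribution the
model assigns at that position when given the wild-type sequence.
"""

from __future__ import annotations

from typing import Literal, Protocol

import numpy as np

from .neural import ModelConfig, NeuralBackend, TrainSchedule, train_mlm  # noqa: F401
from .stream_tokenizer import EncodedSequence, OrganismRegistry, Vocabulary, encode_sequence
from .usage_tables import UsageTable, iter_codons

BaselineKind = Literal["URC", "BFC", "HFC"]
DecodeStrategy = Literal["greedy", "sample"]
InferenceMode = Literal["protein_only", "protein_dna"]


class Backend(Protocol):
    """Minimal contract every codon-prediction backend satisfies."""

    vocab: Vocabulary
    registry: OrganismRegistry

    def predict_distributions(self, encoded: EncodedSequence) -> np.ndarray: ...


def baseline_distribution(
    kind: BaselineKind, aa: str, table: UsageTable, vocab: Vocabulary
) -> np.ndarray:
    """Probability vector over the vocabulary for one amino acid.

    All mass lies on the synonymous pair tokens of ``aa``. HFC ties are
    broken toward the lexicographically first codon.
    """
    family_ids = vocab.family_pair_ids(aa)  # codon-sorted
    out = np.zeros(len(vocab))
    if kind == "URC":
        out[list(family_ids)] = 1.0 / len(family_ids)
    elif kind == "BFC":
        freqs = np.array([table.freq[vocab.codon_of_id(t)] for t in family_ids])
        out[list(family_ids)] = freqs / freqs.sum()
    elif kind == "HFC":
        ws = [table.w[vocab.codon_of_id(t)] for t in family_ids]
        out[family_ids[int(np.argmax(ws))]] = 1.0
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return out


class BaselineBackend:
    """Context-free codon predictor driven purely by usage tables."""

    def __init__(
        self,
        kind: BaselineKind,
        tables: dict[str, UsageTable],
        vocab: Vocabulary,
        registry: OrganismRegistry,
    ) -> None:
        if kind not in ("URC", "BFC", "HFC"):
            raise ValueError(f"unknown baseline kind {kind!r}")
        self.kind: BaselineKind = kind
        self.tables = tables
        self.vocab = vocab
        self.registry = registry

    def predict_distributions(self, encoded: EncodedSequence) -> np.ndarray:
        table = self.tables[self.registry.key_of(int(encoded.token_type_ids[0]))]
        vocab = self.vocab
        out = np.zeros((len(encoded), len(vocab)))
        cache: dict[str, np.ndarray] = {}
        for pos, tid in enumerate(encoded.token_ids.tolist()):
            if tid < vocab.n_special:
                out[pos, tid] = 1.0
                continue
            aa = vocab.aa_of_id(tid)
            if aa not in cache:
                cache[aa] = baseline_distribution(self.kind, aa, table, vocab)
            out[pos] = cache[aa]
        return out


def predict_distributions(backend: Backend, encoded: EncodedSequence) -> np.ndarray:
    """Per-position distributions from any backend (thin dispatcher)."""
    return backend.predict_distributions(encoded)


def constrained_decode(
    dist: np.ndarray,
    protein: str,
    vocab: Vocabulary,
    strategy: DecodeStrategy = "greedy",
    rng: np.random.Generator | None = None,
) -> str:
    """Decode DNA from per-residue distributions, constrained to the protein.

    ``dist`` has one row per protein position (special-token rows already
    stripped). At each position the mass on the residue's synonymous
    pair tokens is renormalized, then the codon is taken by argmax
    (ties -> lexicographically first codon) or sampled.
    """
    if dist.shape[0] < len(protein):
        raise ValueError(
            f"distribution covers {dist.shape[0]} positions but protein has {len(protein)}"
        )
    if strategy == "sample" and rng is None:
        raise ValueError("sampling decode requires an rng")
    codons: list[str] = []
    for i, aa in enumerate(protein):
        family_ids = list(vocab.family_pair_ids(aa))
        mass = dist[i, family_ids]
        total = mass.sum()
        if total <= 0:
            raise ValueError(f"zero probability mass on synonymous codons at position {i}")
        mass = mass / total
        if strategy == "greedy":
            choice = int(np.argmax(mass))
        else:
            choice = int(rng.choice(len(family_ids), p=mass))
        codons.append(vocab.codon_of_id(family_ids[choice]))
    return "".join(codons)


def optimize_sequence(
    backend: Backend,
    protein: str,
    organism: str,
    mode: InferenceMode = "protein_only",
    seed_dna: str | None = None,
    strategy: DecodeStrategy = "greedy",
    rng: np.random.Generator | None = None,
    max_len: int = 2048,
) -> str:
    """Back-translate a protein into host-adapted DNA.

    ``protein_only`` presents the model with ``[X_UNK]`` tokens
    throughout; ``protein_dna`` encodes a plausible seed DNA as pair
    tokens and re-predicts every position, letting the model revise the
    seed in context.
    """
    if mode == "protein_dna":
        if seed_dna is None:
            raise ValueError("protein_dna mode requires seed_dna")
        encoded = encode_sequence(
            backend.vocab, backend.registry, protein, seed_dna, organism=organism, max_len=max_len
        )
    elif mode == "protein_only":
        encoded = encode_sequence(
            backend.vocab, backend.registry, protein, None, organism=organism, max_len=max_len
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dist = backend.predict_distributions(encoded)
    n = encoded.n_sequence_tokens
    return constrained_decode(dist[1 : 1 + n], protein[:n], backend.vocab, strategy, rng)


def predicted_family_distributions(
    backend: Backend,
    proteins: list[str],
    organism: str,
    max_len: int = 2048,
) -> dict[str, np.ndarray]:
    """Average predicted within-family codon distributions at masked input.

    Encodes each protein with amino-acid-unknown tokens, reads the
    backend's distribution at every residue, renormalizes it over the
    residue's synonymous pair tokens (codon-sorted), and averages per
    amino acid. This is the quantity a well-trained model should match
    to the organism's usage table.
    """
    vocab = backend.vocab
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for protein in proteins:
        encoded = encode_sequence(
            vocab, backend.registry, protein, None, organism=organism, max_len=max_len
        )
        dist = backend.predict_distributions(encoded)
        n = encoded.n_sequence_tokens
        for i, aa in enumerate(protein[:n]):
            family_ids = list(vocab.family_pair_ids(aa))
            mass = dist[1 + i, family_ids]
            total = mass.sum()
            if total <= 0:
                continue
            mass = mass / total
            if aa not in sums:
                sums[aa] = mass.copy()
                counts[aa] = 1
            else:
                sums[aa] += mass
                counts[aa] += 1
    return {aa: sums[aa] / counts[aa] for aa in sums}


def family_kl(
    backend: Backend,
    table: UsageTable,
    proteins: list[str],
    organism: str,
    max_len: int = 2048,
) -> float:
    """Mean KL divergence of the true family frequencies from predictions.

    KL(true || predicted) per synonymous family, averaged over the
    families observed in ``proteins``; 0 means the backend reproduces
    the usage table exactly.
    """
    vocab = backend.vocab
    predicted = predicted_family_distributions(backend, proteins, organism, max_len=max_len)
    kls = []
    for aa, pred in predicted.items():
        family_ids = vocab.family_pair_ids(aa)
        true = np.array([table.freq[vocab.codon_of_id(t)] for t in family_ids])
        true = true / true.sum()
        pred = np.clip(pred, 1e-12, None)
        kls.append(float(np.sum(true * np.log(np.clip(true, 1e-12, None) / pred))))
    return float(np.mean(kls))


def score_synonymous_mutation(
    backend: Backend,
    wt_dna: str,
    organism: str,
    position: int,
    mutant_codon: str,
    mask_position: bool = False,
    max_len: int = 2048,
) -> float:
    """Log-likelihood ratio ln p(mutant codon) - ln p(wild-type codon).

    The wild-type DNA is presented in ``protein_dna`` encoding and the
    distribution at the queried codon (0-based index) is read off.
    With ``mask_position`` the queried token is first replaced by its
    amino-acid-unknown form so the model cannot see the wild-type codon.
    """
    vocab = backend.vocab
    codons = iter_codons(wt_dna.upper().replace("U", "T"))
    if not 0 <= position < len(codons):
        raise IndexError(f"codon index {position} out of range for {len(codons)} codons")
    mutant_codon = mutant_codon.upper().replace("U", "T")
    wt_codon = codons[position]
    aa_wt = vocab.table.codon_to_aa[wt_codon]
    aa_mut = vocab.table.codon_to_aa.get(mutant_codon)
    if aa_mut != aa_wt:
        raise ValueError(
            f"mutation {wt_codon}->{mutant_codon} at codon {position} is not synonymous"
        )
    protein = "".join(vocab.table.codon_to_aa[c] for c in codons)
    encoded = encode_sequence(
        vocab, backend.registry, protein, wt_dna, organism=organism, max_len=max_len
    )
    if mask_position:
        ids = encoded.token_ids.copy()
        ids[1 + position] = vocab.unk_aa_id(aa_wt)
        encoded = EncodedSequence(
            token_ids=ids,
            token_type_ids=encoded.token_type_ids,
            attention_mask=encoded.attention_mask,
            organism=encoded.organism,
        )
    dist = backend.predict_distributions(encoded)[1 + position]
    p_mut = dist[vocab.pair_id(aa_wt, mutant_codon)]
    p_wt = dist[vocab.pair_id(aa_wt, wt_codon)]
    if p_mut <= 0 or p_wt <= 0:
        raise ValueError("backend assigns zero probability to a synonymous codon")
    return float(np.log(p_mut) - np.log(p_wt))
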