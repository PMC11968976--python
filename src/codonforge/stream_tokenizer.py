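"""STREAM tokenization: merged amino-acid-codon tokens with per-residue masks.

Each sequence position carries one token that names both the amino acid
and, when known, the codon: ``[A_GCC]`` is alanine encoded by GCC, while
``[A_UNK]`` is alanine with the codon hidden. Because every amino acid
(plus the stop symbol ``_``) has its own masked token, masking removes
the codon but keeps the residue — the model always knows which protein
it is encoding. The vocabulary is exactly 90 tokens: 5 special tokens,
21 amino-acid-unknown tokens (20 amino acids + stop), and 64 pair tokens.

Sequences are wrapped as ``[CLS] ... [SEP] [PAD]*`` up to a maximum
length (default 2048), and every token carries the organism's token-type
id so one shared model can condition on the expression host.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome_io import STOP_SYMBOL, TranslationTable
from .usage_tables import iter_codons

SPECIAL_TOKENS = ("[UNK]", "[CLS]", "[SEP]", "[PAD]", "[MASK]")
DEFAULT_MAX_LEN = 2048
IGNORE_INDEX = -100


def pair_token(aa: str, codon: str) -> str:
    return f"[{aa}_{codon}]"


def unk_token(aa: str) -> str:
    return f"[{aa}_UNK]"


@dataclass(frozen=True)
class Vocabulary:
    """The 90-token STREAM alphabet with deterministic id assignment.

    Ids: specials first (in :data:`SPECIAL_TOKENS` order), then the 21
    amino-acid-unknown tokens sorted by residue symbol, then the 64 pair
    tokens sorted by (amino acid, codon).
    """

    table: TranslationTable
    tokens: tuple[str, ...] = field(init=False)
    token_to_id: dict[str, int] = field(init=False)
    _aa_by_id: dict[int, str] = field(init=False)
    _codon_by_id: dict[int, str] = field(init=False)
    _family_ids: dict[str, tuple[int, ...]] = field(init=False)

    def __post_init__(self) -> None:
        aas = sorted(set(self.table.codon_to_aa.values()))
        if len(aas) != 21:
            raise ValueError(f"expected 21 residue symbols (20 aa + stop), got {len(aas)}")
        pairs = sorted((aa, codon) for codon, aa in self.table.codon_to_aa.items())
        if len(pairs) != 64:
            raise ValueError("translation table must define all 64 codons")
        tokens = list(SPECIAL_TOKENS)
        tokens += [unk_token(aa) for aa in aas]
        tokens += [pair_token(aa, codon) for aa, codon in pairs]
        token_to_id = {tok: i for i, tok in enumerate(tokens)}
        aa_by_id: dict[int, str] = {}
        codon_by_id: dict[int, str] = {}
        family_ids: dict[str, list[int]] = {aa: [] for aa in aas}
        for aa in aas:
            aa_by_id[token_to_id[unk_token(aa)]] = aa
        for aa, codon in pairs:
            tid = token_to_id[pair_token(aa, codon)]
            aa_by_id[tid] = aa
            codon_by_id[tid] = codon
            family_ids[aa].append(tid)
        object.__setattr__(self, "tokens", tuple(tokens))
        object.__setattr__(self, "token_to_id", token_to_id)
        object.__setattr__(self, "_aa_by_id", aa_by_id)
        object.__setattr__(self, "_codon_by_id", codon_by_id)
        object.__setattr__(self, "_family_ids", {aa: tuple(v) for aa, v in family_ids.items()})

    def __len__(self) -> int:
        return len(self.tokens)

    # -- id helpers ---------------------------------------------------

    @property
    def unk_id(self) -> int:
        return self.token_to_id["[UNK]"]

    @property
    def cls_id(self) -> int:
        return self.token_to_id["[CLS]"]

    @property
    def sep_id(self) -> int:
        return self.token_to_id["[SEP]"]

    @property
    def pad_id(self) -> int:
        return self.token_to_id["[PAD]"]

    @property
    def mask_id(self) -> int:
        return self.token_to_id["[MASK]"]

    @property
    def n_special(self) -> int:
        return len(SPECIAL_TOKENS)

    @property
    def pair_ids(self) -> tuple[int, ...]:
        """Ids of the 64 amino-acid-codon pair tokens."""
        return tuple(range(self.n_special + 21, len(self.tokens)))

    def is_pair_id(self, token_id: int) -> bool:
        return token_id >= self.n_special + 21

    def is_unk_aa_id(self, token_id: int) -> bool:
        return self.n_special <= token_id < self.n_special + 21

    def aa_of_id(self, token_id: int) -> str:
        return self._aa_by_id[token_id]

    def codon_of_id(self, token_id: int) -> str:
        return self._codon_by_id[token_id]

    def pair_id(self, aa: str, codon: str) -> int:
        tok = pair_token(aa, codon)
        if tok not in self.token_to_id:
            raise KeyError(f"no pair token for amino acid {aa!r} with codon {codon!r}")
        return self.token_to_id[tok]

    def unk_aa_id(self, aa: str) -> int:
        return self.token_to_id[unk_token(aa)]

    def family_pair_ids(self, aa: str) -> tuple[int, ...]:
        """Ids of the synonymous pair tokens of one amino acid, codon-sorted."""
        if aa not in self._family_ids:
            raise KeyError(f"unknown amino acid {aa!r}")
        return self._family_ids[aa]

    # -- serialization ------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {"table_id": self.table.table_id, "tokens": list(self.tokens)}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        vocab = build_vocabulary(TranslationTable.from_ncbi(payload["table_id"]))
        if list(vocab.tokens) != payload["tokens"]:
            raise ValueError("stored vocabulary is inconsistent with its translation table")
        return vocab


def build_vocabulary(table: TranslationTable) -> Vocabulary:
    """Construct the 90-token vocabulary from a complete translation table."""
    return Vocabulary(table=table)


class OrganismRegistry:
    """Bijective map organism key <-> contiguous token-type id.

    Keys are registered in first-seen order; NCBI taxonomy ids (or any
    alternative spelling) can be attached as aliases of a canonical key.
    """

    def __init__(self) -> None:
        self._key_to_type: dict[str, int] = {}
        self._type_to_key: dict[int, str] = {}
        self._aliases: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self._key_to_type)

    def __contains__(self, key: str) -> bool:
        key = str(key)
        return key in self._key_to_type or key in self._aliases

    @property
    def organisms(self) -> list[str]:
        return [self._type_to_key[i] for i in range(len(self._type_to_key))]

    def add(self, key: str) -> int:
        key = str(key)
        if key in self._aliases:
            key = self._aliases[key]
        if key not in self._key_to_type:
            type_id = len(self._key_to_type)
            self._key_to_type[key] = type_id
            self._type_to_key[type_id] = key
        return self._key_to_type[key]

    def add_alias(self, alias: str, key: str) -> None:
        if key not in self._key_to_type:
            raise KeyError(f"unknown organism {key!r}")
        self._aliases[str(alias)] = key

    def type_id(self, key: str) -> int:
        key = str(key)
        if key in self._aliases:
            key = self._aliases[key]
        if key not in self._key_to_type:
            raise KeyError(f"organism {key!r} is not registered")
        return self._key_to_type[key]

    def key_of(self, type_id: int) -> str:
        return self._type_to_key[type_id]

    def save(self, path: str | Path) -> None:
        payload = {"organisms": self.organisms, "aliases": self._aliases}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "OrganismRegistry":
        payload = json.loads(Path(path).read_text())
        reg = cls()
        for key in payload["organisms"]:
            reg.add(key)
        for alias, key in payload.get("aliases", {}).items():
            reg.add_alias(alias, key)
        return reg


@dataclass(frozen=True)
class EncodedSequence:
    """A tokenized, organism-tagged, optionally padded sequence."""

    token_ids: np.ndarray
    token_type_ids: np.ndarray
    attention_mask: np.ndarray
    organism: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.token_ids)
        if len(self.token_type_ids) != n or len(self.attention_mask) != n:
            raise ValueError("encoded arrays must share one length")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels must match token_ids length")

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def n_sequence_tokens(self) -> int:
        """Number of non-special sequence tokens (excludes CLS/SEP/PAD)."""
        return int(self.attention_mask.sum()) - 2


def encode_sequence(
    vocab: Vocabulary,
    registry: OrganismRegistry,
    protein: str,
    dna: str | None = None,
    *,
    organism: str,
    max_len: int = DEFAULT_MAX_LEN,
    pad: bool = False,
) -> EncodedSequence:
    """Encode a protein (optionally with its DNA) for one organism.

    With DNA, positions become pair tokens ``[X_CODON]``; without, every
    position is the amino-acid-unknown token ``[X_UNK]`` (the inference
    input). ``[CLS]``/``[SEP]`` are added; truncation keeps the first
    ``max_len - 2`` sequence tokens (the 5' end); with ``pad`` the array
    is right-padded to ``max_len``.
    """
    if organism not in registry:
        raise KeyError(f"organism {organism!r} is not registered")
    type_id = registry.type_id(organism)
    if dna is None:
        body = [vocab.unk_aa_id(aa) for aa in protein]
    else:
        codons = iter_codons(dna.upper().replace("U", "T"))
        if len(codons) != len(protein):
            raise ValueError(
                f"DNA has {len(codons)} codons but protein has {len(protein)} residues"
            )
        body = []
        for i, (aa, codon) in enumerate(zip(protein, codons)):
            try:
                body.append(vocab.pair_id(aa, codon))
            except KeyError as exc:
                # alternative start codons re-coded to M have no [M_xxx]
                # pair token; fall back to the codon's elongation token
                if i == 0 and aa == "M" and codon in vocab.table.start_codons:
                    body.append(vocab.pair_id(vocab.table.codon_to_aa[codon], codon))
                    continue
                raise ValueError(
                    f"codon {codon} at position {i} does not encode {aa!r}"
                ) from exc
    body = body[: max_len - 2]
    ids = [vocab.cls_id, *body, vocab.sep_id]
    mask = [1] * len(ids)
    if pad and len(ids) < max_len:
        n_pad = max_len - len(ids)
        ids += [vocab.pad_id] * n_pad
        mask += [0] * n_pad
    return EncodedSequence(
        token_ids=np.asarray(ids, dtype=np.int64),
        token_type_ids=np.full(len(ids), type_id, dtype=np.int64),
        attention_mask=np.asarray(mask, dtype=np.int64),
        organism=registry.key_of(type_id),
    )


def decode_tokens(vocab: Vocabulary, token_ids: np.ndarray) -> tuple[str, str]:
    """Concatenate codon and amino-acid parts of a fully specified sequence.

    Special tokens are skipped; any amino-acid-unknown token means the
    model has not committed to a codon there, and is an error.
    """
    dna_parts: list[str] = []
    aa_parts: list[str] = []
    for tid in np.asarray(token_ids).tolist():
        if tid < vocab.n_special:
            continue
        if vocab.is_unk_aa_id(tid):
            raise ValueError(
                f"sequence not fully decoded: contains {vocab.tokens[tid]}"
            )
        dna_parts.append(vocab.codon_of_id(tid))
        aa_parts.append(vocab.aa_of_id(tid))
    return "".join(dna_parts), "".join(aa_parts)


def apply_mlm_corruption(
    vocab: Vocabulary,
    encoded: EncodedSequence,
    rng: np.random.Generator,
    select_rate: float = 0.15,
    mask_frac: float = 0.8,
    random_frac: float = 0.1,
) -> EncodedSequence:
    """Corrupt a pair-token sequence for masked-language-model training.

    A fraction ``select_rate`` of pair-token positions is selected
    independently; of these, ``mask_frac`` are replaced by their
    amino-acid-unknown token (``[A_GCC]`` -> ``[A_UNK]``), ``random_frac``
    by a pair token drawn uniformly from all 64, and the remainder left
    unchanged. Labels hold the original ids at selected positions and
    :data:`IGNORE_INDEX` elsewhere. Special tokens are never selected.
    """
    if not (0.0 <= select_rate <= 1.0):
        raise ValueError("select_rate must be in [0, 1]")
    if mask_frac < 0 or random_frac < 0 or mask_frac + random_frac > 1.0 + 1e-12:
        raise ValueError("mask_frac + random_frac must be <= 1")
    ids = np.asarray(encoded.token_ids).copy()
    is_pair = np.array([vocab.is_pair_id(int(t)) for t in ids])
    if not is_pair.any():
        raise ValueError("encoded sequence has no codon information to corrupt")
    labels = np.full(len(ids), IGNORE_INDEX, dtype=np.int64)
    selected = is_pair & (rng.random(len(ids)) < select_rate)
    labels[selected] = ids[selected]
    action = rng.random(len(ids))
    pair_ids = np.asarray(vocab.pair_ids)
    for pos in np.nonzero(selected)[0]:
        if action[pos] < mask_frac:
            ids[pos] = vocab.unk_aa_id(vocab.aa_of_id(int(ids[pos])))
        elif action[pos] < mask_frac + random_frac:
            ids[pos] = int(pair_ids[rng.integers(len(pair_ids))])
        # else: keep the original token; the label still supervises it
    return replace(encoded, token_ids=ids, labels=labels)
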