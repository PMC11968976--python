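import numpy as np
import pytest

from codonforge import make_corpus, make_organism
from codonforge.stream_tokenizer import (
    IGNORE_INDEX,
    SPECIAL_TOKENS,
    OrganismRegistry,
    Vocabulary,
    apply_mlm_corruption,
    build_vocabulary,
    decode_tokens,
    encode_sequence,
)

WORKED_PROTEIN = "MALW_"
WORKED_DNA = "ATGGCCCTGTGGTAA"
WORKED_TOKENS = ["[M_ATG]", "[A_GCC]", "[L_CTG]", "[W_TGG]", "[__TAA]"]


class TestVocabulary:
    def test_size_is_90(self, vocab):
        assert len(vocab) == 90

    def test_composition(self, vocab):
        assert vocab.tokens[:5] == SPECIAL_TOKENS
        unk_aa = [t for t in vocab.tokens if t.endswith("_UNK]")]
        pair = [t for t in vocab.tokens if not t.endswith("_UNK]") and t not in SPECIAL_TOKENS]
        assert len(unk_aa) == 21
        assert len(pair) == 64

    def test_pair_tokens_consistent_with_code(self, vocab, standard_table):
        for tid in vocab.pair_ids:
            assert vocab.aa_of_id(tid) == standard_table.codon_to_aa[vocab.codon_of_id(tid)]

    @pytest.mark.parametrize("aa,codon,token", [("A", "GCC", "[A_GCC]"), ("_", "TAA", "[__TAA]")])
    def test_printed_token_forms(self, vocab, aa, codon, token):
        assert vocab.tokens[vocab.pair_id(aa, codon)] == token

    def test_stop_unknown_token_double_underscore(self, vocab):
        assert vocab.tokens[vocab.unk_aa_id("_")] == "[__UNK]"

    def test_ids_stable_across_save_load(self, vocab, tmp_path):
        p = tmp_path / "vocab.json"
        vocab.save(p)
        loaded = Vocabulary.load(p)
        assert loaded.token_to_id == vocab.token_to_id

    def test_incomplete_table_rejected(self, standard_table):
        broken = dict(standard_table.codon_to_aa)
        broken.pop("ATG")
        import dataclasses

        with pytest.raises(ValueError):
            build_vocabulary(
                dataclasses.replace(standard_table, codon_to_aa=broken)
            )


class TestOrganismRegistry:
    def test_contiguous_bijective_ids(self, registry):
        assert registry.type_id("orgA") == 0
        assert registry.type_id("orgB") == 1
        assert registry.key_of(1) == "orgB"

    def test_taxonomy_alias(self):
        reg = OrganismRegistry()
        reg.add("E. coli")
        reg.add_alias("511145", "E. coli")
        assert reg.type_id("511145") == reg.type_id("E. coli")

    def test_save_load_roundtrip(self, registry, tmp_path):
        p = tmp_path / "registry.json"
        registry.save(p)
        loaded = OrganismRegistry.load(p)
        assert loaded.organisms == registry.organisms

    def test_unregistered_organism_errors(self, registry):
        with pytest.raises(KeyError):
            registry.type_id("martian")


class TestEncodeSequence:
    def test_worked_example_with_padding(self, vocab, registry):
        enc = encode_sequence(
            vocab, registry, WORKED_PROTEIN, WORKED_DNA,
            organism="orgA", max_len=10, pad=True,
        )
        tokens = [vocab.tokens[t] for t in enc.token_ids]
        assert tokens == ["[CLS]", *WORKED_TOKENS, "[SEP]", "[PAD]", "[PAD]", "[PAD]"]
        assert enc.attention_mask.tolist() == [1] * 7 + [0] * 3
        assert enc.n_sequence_tokens == 5

    def test_protein_only_uses_unk_tokens(self, vocab, registry):
        enc = encode_sequence(vocab, registry, "MK_", None, organism="orgA")
        tokens = [vocab.tokens[t] for t in enc.token_ids]
        assert tokens == ["[CLS]", "[M_UNK]", "[K_UNK]", "[__UNK]", "[SEP]"]

    def test_token_type_ids_constant_and_organism_specific(self, vocab, registry):
        enc_a = encode_sequence(vocab, registry, "MK_", None, organism="orgA")
        enc_b = encode_sequence(vocab, registry, "MK_", None, organism="orgB")
        assert set(enc_a.token_type_ids.tolist()) == {0}
        assert set(enc_b.token_type_ids.tolist()) == {1}

    def test_truncation_keeps_5prime_end(self, vocab, registry):
        protein = "M" + "A" * 3000 + "_"
        enc = encode_sequence(vocab, registry, protein, None, organism="orgA", max_len=2048)
        assert len(enc) == 2048
        assert enc.token_ids[0] == vocab.cls_id
        assert enc.token_ids[1] == vocab.unk_aa_id("M")
        assert enc.token_ids[-1] == vocab.sep_id

    def test_protein_dna_mismatch_errors(self, vocab, registry):
        with pytest.raises(ValueError):
            encode_sequence(vocab, registry, "MM_", WORKED_DNA[:9], organism="orgA")

    def test_unregistered_organism_errors(self, vocab, registry):
        with pytest.raises(KeyError):
            encode_sequence(vocab, registry, "MK_", None, organism="nobody")


class TestDecodeTokens:
    def test_worked_example_roundtrip(self, vocab, registry):
        enc = encode_sequence(vocab, registry, WORKED_PROTEIN, WORKED_DNA, organism="orgA")
        assert decode_tokens(vocab, enc.token_ids) == (WORKED_DNA, WORKED_PROTEIN)

    def test_cls_sep_only_is_empty(self, vocab):
        assert decode_tokens(vocab, np.array([vocab.cls_id, vocab.sep_id])) == ("", "")

    def test_unk_token_rejected(self, vocab):
        ids = np.array([vocab.cls_id, vocab.unk_aa_id("A"), vocab.sep_id])
        with pytest.raises(ValueError, match="not fully decoded"):
            decode_tokens(vocab, ids)

    def test_roundtrip_on_random_synthetic_records(self, vocab):
        org = make_organism("rt", 3)
        reg = OrganismRegistry()
        reg.add("rt")
        for rec in make_corpus(50, [org], seed=11):
            enc = encode_sequence(vocab, reg, rec.protein, rec.dna, organism="rt")
            assert decode_tokens(vocab, enc.token_ids) == (rec.dna, rec.protein)


class TestMlmCorruption:
    def _encode(self, vocab, registry, n=200):
        protein = "M" + "AKL" * ((n - 2) // 3) + "_"
        org = make_organism("mlm", 1)
        from codonforge import back_translate

        rng = np.random.default_rng(5)
        dna = back_translate(protein, org.usage, rng, policy="BFC")
        return encode_sequence(vocab, registry, protein, dna, organism="orgA", pad=True,
                               max_len=len(protein) + 10)

    def test_masked_token_keeps_amino_acid(self, vocab, registry, rng):
        enc = self._encode(vocab, registry)
        cor = apply_mlm_corruption(vocab, enc, rng)
        changed = np.nonzero(cor.labels != IGNORE_INDEX)[0]
        assert changed.size > 0
        for pos in changed:
            original = int(cor.labels[pos])
            new = int(cor.token_ids[pos])
            if vocab.is_unk_aa_id(new):
                assert vocab.aa_of_id(new) == vocab.aa_of_id(original)

    def test_specials_never_selected(self, vocab, registry, rng):
        enc = self._encode(vocab, registry)
        cor = apply_mlm_corruption(vocab, enc, rng, select_rate=1.0)
        for pos in (0, int(enc.attention_mask.sum()) - 1):
            assert cor.labels[pos] == IGNORE_INDEX
            assert cor.token_ids[pos] == enc.token_ids[pos]
        pad_region = np.nonzero(enc.attention_mask == 0)[0]
        assert (cor.labels[pad_region] == IGNORE_INDEX).all()

    def test_zero_rate_identity(self, vocab, registry, rng):
        enc = self._encode(vocab, registry)
        cor = apply_mlm_corruption(vocab, enc, rng, select_rate=0.0)
        assert (cor.token_ids == enc.token_ids).all()
        assert (cor.labels == IGNORE_INDEX).all()

    def test_reproducible_from_seed(self, vocab, registry):
        enc = self._encode(vocab, registry)
        a = apply_mlm_corruption(vocab, enc, np.random.default_rng(7))
        b = apply_mlm_corruption(vocab, enc, np.random.default_rng(7))
        assert (a.token_ids == b.token_ids).all()
        assert (a.labels == b.labels).all()

    def test_protein_only_input_rejected(self, vocab, registry, rng):
        enc = encode_sequence(vocab, registry, "MK_", None, organism="orgA")
        with pytest.raises(ValueError):
            apply_mlm_corruption(vocab, enc, rng)

    def test_empirical_rates_at_scale(self, vocab, registry):
        """Selection ~15% and mask-within-selection ~80% over >=100k tokens."""
        org = make_organism("rates", 2)
        records = make_corpus(900, [org], seed=21)
        reg = OrganismRegistry()
        reg.add("rates")
        rng = np.random.default_rng(13)
        n_pair = n_sel = n_masked = 0
        for rec in records:
            enc = encode_sequence(vocab, reg, rec.protein, rec.dna, organism="rates")
            cor = apply_mlm_corruption(vocab, enc, rng)
            sel = cor.labels != IGNORE_INDEX
            n_pair += len(rec.protein)
            n_sel += int(sel.sum())
            n_masked += sum(
                1 for pos in np.nonzero(sel)[0] if vocab.is_unk_aa_id(int(cor.token_ids[pos]))
            )
        assert n_pair >= 100_000
        assert abs(100.0 * n_sel / n_pair - 15.0) < 0.3
        assert abs(100.0 * n_masked / n_sel - 80.0) < 1.0
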