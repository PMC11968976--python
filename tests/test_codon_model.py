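import math

import numpy as np
import pytest

from codonforge import (
    BaselineBackend,
    back_translate,
    make_corpus,
    make_organism,
    sample_protein,
)
from codonforge.codon_model import (
    baseline_distribution,
    constrained_decode,
    optimize_sequence,
    score_synonymous_mutation,
)
from codonforge.stream_tokenizer import OrganismRegistry, encode_sequence
from codonforge.usage_tables import compute_csi


@pytest.fixture(scope="module")
def toy_setup(request):
    """Toy-usage baseline backends sharing one vocabulary/registry."""
    import codonforge as cf

    table = cf.TranslationTable.from_ncbi(1)
    vocab = cf.build_vocabulary(table)
    counts = {c: 5.0 for c in table.codon_to_aa}
    counts.update({"AAA": 8.0, "AAG": 2.0, "GCC": 4.0, "GCA": 2.0, "GCG": 3.0, "GCT": 1.0})
    usage = cf.UsageTable.from_counts(counts, table, organism="toy")
    reg = OrganismRegistry()
    reg.add("toy")
    backends = {
        kind: BaselineBackend(kind, {"toy": usage}, vocab, reg)
        for kind in ("URC", "BFC", "HFC")
    }
    return vocab, reg, usage, backends


class TestBaselineDistribution:
    def test_urc_uniform_over_family(self, toy_setup):
        vocab, _, usage, _ = toy_setup
        dist = baseline_distribution("URC", "L", usage, vocab)
        fam = vocab.family_pair_ids("L")
        assert np.allclose(dist[list(fam)], 1 / 6)
        assert math.isclose(dist.sum(), 1.0)

    def test_urc_single_codon_family(self, toy_setup):
        vocab, _, usage, _ = toy_setup
        dist = baseline_distribution("URC", "W", usage, vocab)
        assert dist[vocab.pair_id("W", "TGG")] == 1.0

    def test_bfc_family_frequencies(self, toy_setup):
        vocab, _, usage, _ = toy_setup
        dist = baseline_distribution("BFC", "K", usage, vocab)
        assert math.isclose(dist[vocab.pair_id("K", "AAA")], 0.8)
        assert math.isclose(dist[vocab.pair_id("K", "AAG")], 0.2)

    def test_hfc_point_mass_on_argmax(self, toy_setup):
        vocab, _, usage, _ = toy_setup
        dist = baseline_distribution("HFC", "K", usage, vocab)
        assert dist[vocab.pair_id("K", "AAA")] == 1.0

    def test_unknown_amino_acid(self, toy_setup):
        vocab, _, usage, _ = toy_setup
        with pytest.raises(KeyError):
            baseline_distribution("URC", "Z", usage, vocab)


class TestPredictDistributions:
    def test_rows_normalized(self, toy_setup):
        vocab, reg, usage, backends = toy_setup
        enc = encode_sequence(vocab, reg, "MKAL_", None, organism="toy")
        for be in backends.values():
            dist = be.predict_distributions(enc)
            assert dist.shape == (len(enc), len(vocab))
            assert np.allclose(dist.sum(axis=1), 1.0, atol=1e-6)
            assert (dist >= 0).all()

    def test_unk_position_gets_family_distribution(self, toy_setup):
        vocab, reg, usage, backends = toy_setup
        enc = encode_sequence(vocab, reg, "ML_", None, organism="toy")
        dist = backends["URC"].predict_distributions(enc)
        fam = vocab.family_pair_ids("L")
        assert np.allclose(dist[2, list(fam)], 1 / 6)


class TestConstrainedDecode:
    def test_hfc_decode_hand_value(self, toy_setup):
        vocab, reg, usage, backends = toy_setup
        dna = optimize_sequence(backends["HFC"], "MK_", "toy")
        assert dna == "ATGAAATAA"

    def test_single_codon_positions_forced(self, toy_setup):
        vocab, reg, usage, backends = toy_setup
        for kind in ("URC", "BFC", "HFC"):
            dna = optimize_sequence(backends[kind], "MWM_", "toy",
                                    rng=np.random.default_rng(0), strategy="sample")
            assert dna.startswith("ATG" + "TGG" + "ATG")

    def test_sampled_decode_reproducible(self, toy_setup):
        _, _, _, backends = toy_setup
        a = optimize_sequence(backends["BFC"], "MKKKKAALL_", "toy",
                              strategy="sample", rng=np.random.default_rng(77))
        b = optimize_sequence(backends["BFC"], "MKKKKAALL_", "toy",
                              strategy="sample", rng=np.random.default_rng(77))
        assert a == b

    def test_zero_mass_errors_with_position(self, toy_setup):
        voc, _, _, _ = toy_setup
        dist = np.zeros((2, len(voc)))
        dist[0, voc.pair_id("M", "ATG")] = 1.0
        with pytest.raises(ValueError, match="position 1"):
            constrained_decode(dist, "MK", voc)

    def test_translation_always_preserved(self, toy_setup):
        vocab, reg, usage, backends = toy_setup
        rng = np.random.default_rng(8)
        for _ in range(50):
            protein = sample_protein(rng, int(rng.integers(2, 60)))
            for kind, be in backends.items():
                dna = optimize_sequence(be, protein, "toy", strategy="sample", rng=rng)
                translated = "".join(
                    vocab.table.codon_to_aa[dna[i : i + 3]] for i in range(0, len(dna), 3)
                )
                assert translated == protein


class TestOptimizeSequence:
    def test_hfc_ignores_seed_dna(self, toy_setup):
        _, _, usage, backends = toy_setup
        protein = "MKKAAL_"
        seed = back_translate(protein, usage, np.random.default_rng(5), policy="URC")
        out_po = optimize_sequence(backends["HFC"], protein, "toy", mode="protein_only")
        out_pd = optimize_sequence(
            backends["HFC"], protein, "toy", mode="protein_dna", seed_dna=seed
        )
        assert out_po == out_pd

    def test_hfc_fixed_point(self, toy_setup):
        _, _, _, backends = toy_setup
        protein = "MKKAAL_"
        hfc_out = optimize_sequence(backends["HFC"], protein, "toy")
        again = optimize_sequence(
            backends["HFC"], protein, "toy", mode="protein_dna", seed_dna=hfc_out
        )
        assert again == hfc_out

    def test_hfc_output_has_csi_one(self, toy_setup):
        _, _, usage, backends = toy_setup
        dna = optimize_sequence(backends["HFC"], "MKKKAALLNDE_", "toy")
        assert math.isclose(compute_csi(dna, usage), 1.0)

    def test_bfc_frequencies_converge_to_table(self, toy_setup):
        """Over many decoded codons the BFC output matches the usage table."""
        vocab, _, usage, backends = toy_setup
        rng = np.random.default_rng(31)
        counts: dict[str, int] = {}
        total_by_aa: dict[str, int] = {}
        n_codons = 0
        while n_codons < 50_000:
            protein = sample_protein(rng, 250, composition={"K": 1.0, "A": 1.0})
            dna = optimize_sequence(backends["BFC"], protein, "toy",
                                    strategy="sample", rng=rng)
            for i in range(0, len(dna), 3):
                c = dna[i : i + 3]
                counts[c] = counts.get(c, 0) + 1
                aa = vocab.table.codon_to_aa[c]
                total_by_aa[aa] = total_by_aa.get(aa, 0) + 1
            n_codons += len(protein)
        l1 = []
        for aa in "KA":
            fam = usage.family(aa)
            emp = np.array([counts.get(c, 0) for c in fam], dtype=float)
            emp /= emp.sum()
            true = np.array([usage.freq[c] for c in fam])
            l1.append(np.abs(emp - true).sum())
        assert max(l1) < 0.02

    def test_bfc_beats_urc_in_csi(self):
        """BFC tracks the biased table; URC does not (sign test over proteins)."""
        org = make_organism("bias", 17, alpha=0.2)
        import codonforge as cf

        vocab = cf.build_vocabulary(org.table)
        reg = OrganismRegistry()
        reg.add("bias")
        bfc = BaselineBackend("BFC", {"bias": org.usage}, vocab, reg)
        urc = BaselineBackend("URC", {"bias": org.usage}, vocab, reg)
        rng = np.random.default_rng(1)
        wins = 0
        n = 200
        for _ in range(n):
            protein = sample_protein(rng, 40)
            c_bfc = compute_csi(optimize_sequence(bfc, protein, "bias",
                                                  strategy="sample", rng=rng), org.usage)
            c_urc = compute_csi(optimize_sequence(urc, protein, "bias",
                                                  strategy="sample", rng=rng), org.usage)
            wins += c_bfc > c_urc
        # one-sided sign test at p < 0.01: need >= 128/200 under H0 p=0.5
        from scipy.stats import binomtest

        assert binomtest(wins, n, alternative="greater").pvalue < 0.01


class TestMutationScoring:
    def test_bfc_closed_form(self, toy_setup):
        _, _, usage, backends = toy_setup
        wt = "ATGGCCAAATAA"  # M A(GCC) K(AAA) _
        got = score_synonymous_mutation(backends["BFC"], wt, "toy", 1, "GCA")
        expected = math.log(usage.freq["GCA"] / usage.freq["GCC"])
        assert math.isclose(got, expected, abs_tol=1e-12)

    def test_identity_mutation_scores_zero(self, toy_setup):
        _, _, _, backends = toy_setup
        assert score_synonymous_mutation(backends["BFC"], "ATGAAATAA", "toy", 1, "AAA") == 0.0

    def test_non_synonymous_rejected(self, toy_setup):
        _, _, _, backends = toy_setup
        with pytest.raises(ValueError, match="not synonymous"):
            score_synonymous_mutation(backends["BFC"], "ATGAAATAA", "toy", 1, "GCA")

    def test_scores_monotone_in_frequency_ratio(self, toy_setup):
        """Across all synonymous mutants, BFC scores rank exactly by ln f ratio."""
        from scipy.stats import spearmanr

        vocab, _, usage, backends = toy_setup
        wt = "ATGGCCAAACTGGATTAA"
        scores, ratios = [], []
        for pos in range(1, 5):
            wt_codon = wt[3 * pos : 3 * pos + 3]
            aa = vocab.table.codon_to_aa[wt_codon]
            for mut in usage.family(aa):
                if mut == wt_codon:
                    continue
                scores.append(
                    score_synonymous_mutation(backends["BFC"], wt, "toy", pos, mut)
                )
                ratios.append(math.log(usage.freq[mut] / usage.freq[wt_codon]))
        rho = spearmanr(scores, ratios).statistic
        assert math.isclose(rho, 1.0)

    def test_out_of_range_position(self, toy_setup):
        _, _, _, backends = toy_setup
        with pytest.raises(IndexError):
            score_synonymous_mutation(backends["BFC"], "ATGAAATAA", "toy", 5, "AAG")
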