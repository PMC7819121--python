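import numpy as np
import pytest
from Bio.Align import substitution_matrices

from cottonprx import evolution as ev
from cottonprx import synthetic_data as sd
from oracles import SENSE_CODONS, ng86_oracle, nw_score_oracle


class TestCodonAlign:
    def test_identical_sequences_fully_paired(self):
        cds = "ATGAAACCCGGGTTTTAA"
        pairs = ev.codon_align(cds, cds)
        assert pairs == [(c, c) for c in ["ATG", "AAA", "CCC", "GGG", "TTT"]]

    def test_whole_codon_insertion_gapped_out(self):
        a = "ATGAAACCCGGGTTT"
        b = "ATGAAATGGCCCGGGTTT"  # extra TGG codon
        pairs = ev.codon_align(a, b)
        assert len(pairs) == 5
        assert all(ca == cb for ca, cb in pairs)

    def test_internal_stop_is_error(self):
        with pytest.raises(ValueError, match="internal stop"):
            ev.codon_align("ATGTAAAAA", "ATGAAAAAA")

    def test_length_not_multiple_of_three_is_error(self):
        with pytest.raises(ValueError, match="divisible"):
            ev.codon_align("ATGAA", "ATGAAA")

    def test_alignment_score_matches_dp_oracle(self):
        rng = np.random.default_rng(3)
        matrix = substitution_matrices.load("BLOSUM62")
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = aligner.extend_gap_score = -8.0
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), size=int(rng.integers(3, 10))))
            b = "".join(rng.choice(list(aas), size=int(rng.integers(3, 10))))
            assert aligner.score(a, b) == pytest.approx(
                nw_score_oracle(a, b, matrix, -8.0)
            )


class TestNg86:
    def test_identical_gives_zero(self):
        pairs = [("ATG", "ATG"), ("AAA", "AAA")]
        assert ev.ng86(pairs) == (0.0, 0.0)

    def test_synonymous_third_position_only(self):
        pairs = [("GGT", "GGT")] * 100 + [("GGT", "GGC")]
        ka, ks = ev.ng86(pairs)
        assert ka == 0.0
        assert ks > 0.0

    def test_site_counts_sum_to_three_per_codon(self):
        for codon in SENSE_CODONS:
            s, n = ev.codon_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            pairs = [
                (SENSE_CODONS[rng.integers(len(SENSE_CODONS))],
                 SENSE_CODONS[rng.integers(len(SENSE_CODONS))])
                for _ in range(5)
            ]
            try:
                fwd = ev.ng86(pairs)
                rev = ev.ng86([(b, a) for a, b in pairs])
            except ev.SaturationError:
                continue
            assert fwd[0] == pytest.approx(rev[0], abs=1e-12)
            assert fwd[1] == pytest.approx(rev[1], abs=1e-12)

    def test_matches_pathway_enumeration_oracle_single_codons(self):
        checked = 0
        for ca in SENSE_CODONS:
            for cb in SENSE_CODONS:
                ndiff = sum(x != y for x, y in zip(ca, cb))
                if not 1 <= ndiff <= 2:
                    continue
                # pad with identical codons to keep p < 3/4
                pairs = [(ca, cb)] + [("GGT", "GGT")] * 10
                try:
                    ours = ev.ng86(pairs)
                except ev.SaturationError:
                    continue
                oracle = ng86_oracle(pairs)
                assert ours[0] == pytest.approx(oracle[0], abs=1e-12)
                assert ours[1] == pytest.approx(oracle[1], abs=1e-12)
                checked += 1
        assert checked > 2000

    def test_matches_oracle_on_random_three_codon_pairs(self):
        rng = np.random.default_rng(13)
        done = 0
        while done < 200:
            base = [SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
                    for _ in range(3)]
            other = list(base)
            for _ in range(int(rng.integers(1, 3))):
                idx = int(rng.integers(3))
                pos = int(rng.integers(3))
                alt = other[idx][:pos] + str(
                    rng.choice(list("ACGT"))
                ) + other[idx][pos + 1 :]
                if alt not in ev.STOP_CODONS:
                    other[idx] = alt
            pairs = list(zip(base, other)) + [("GGT", "GGT")] * 6
            try:
                ours = ev.ng86(pairs)
            except ev.SaturationError:
                continue
            oracle = ng86_oracle(pairs)
            assert ours[0] == pytest.approx(oracle[0], abs=1e-12)
            assert ours[1] == pytest.approx(oracle[1], abs=1e-12)
            done += 1

    def test_saturation_error_names_class(self):
        pairs = [("GGT", "GGC"), ("CCT", "CCA"), ("TTT", "TTC")]
        with pytest.raises(ev.SaturationError, match="synonymous"):
            ev.ng86(pairs)


class TestDivergenceTime:
    def test_zero_ks(self):
        assert ev.divergence_time(0.0) == 0.0

    def test_analytic_point(self):
        # Ks 0.03 at the dicot rate: 0.03 / (3e-8) years = 1 MYA
        assert ev.divergence_time(0.03) == pytest.approx(1.0)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ks = float(rng.uniform(0, 2))
            lam = float(rng.uniform(1e-9, 1e-7))
            assert ev.divergence_time(2 * ks, lam) == pytest.approx(
                2 * ev.divergence_time(ks, lam)
            )
            assert ev.divergence_time(ks, 2 * lam) == pytest.approx(
                ev.divergence_time(ks, lam) / 2
            )

    def test_negative_ks_is_error(self):
        with pytest.raises(ValueError):
            ev.divergence_time(-0.1)


class TestRecovery:
    def test_synonymous_only_pairs_have_zero_ka(self):
        config = sd.SimulationConfig(seed=21, duplicate_n_nonsyn=0)
        pairs, _ = sd.gen_duplicate_pairs(config, n_pairs=10)
        for id_a, id_b, cds_a, cds_b in pairs:
            dup = ev.analyze_pair(id_a, id_b, cds_a, cds_b)
            assert dup.ka == 0.0
            assert dup.ks > 0.0

    def test_ks_recovery_within_15_percent(self):
        # 200 seeded low-divergence pairs; the planted expectation is the
        # Jukes-Cantor-corrected proportion of planted synonymous changes
        # over the synonymous sites of each pair
        config = sd.SimulationConfig(seed=22)
        pairs, truth = sd.gen_duplicate_pairs(config, n_pairs=200)
        rel_errors = []
        for (id_a, id_b, cds_a, cds_b), row in zip(pairs, truth.itertuples()):
            aligned = ev.codon_align(cds_a, cds_b)
            ka, ks = ev.ng86(aligned)
            s_sites = sum(
                (ev.codon_sites(ca)[0] + ev.codon_sites(cb)[0]) / 2
                for ca, cb in aligned
            )
            expected = ev.jukes_cantor(row.n_syn / s_sites, "synonymous")
            rel_errors.append(abs(ks - expected) / expected)
        assert float(np.mean(rel_errors)) < 0.15

    def test_zero_substitutions_give_identical_pair(self):
        config = sd.SimulationConfig(
            seed=23, duplicate_n_syn=0, duplicate_n_nonsyn=0
        )
        ((id_a, id_b, cds_a, cds_b),), _ = sd.gen_duplicate_pairs(config)
        assert cds_a == cds_b
        dup = ev.analyze_pair(id_a, id_b, cds_a, cds_b)
        assert (dup.ka, dup.ks, dup.t_mya) == (0.0, 0.0, 0.0)
        assert dup.ka_ks is None
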