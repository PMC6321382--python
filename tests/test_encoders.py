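import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pupsite.alphabet import AA_INDEX, AA_PAIRS, AMINO_ACIDS
from pupsite.encoders import (
    ANBPBModel,
    ResidueProfile,
    combine_features,
    encode_aac,
    encode_aapc,
    encode_anbpb,
    encode_pc_pseaac,
    encode_top_n_gram,
    fit_anbpb,
    load_default_property_tables,
    profile_from_window,
    read_profile,
    top_n_gram_matrix,
    write_profile,
)
from pupsite.peptide_io import FeatureMatrix, PeptideWindow

from conftest import make_fm

# a 21-mer window strategy: K center, arbitrary flanks
flank = st.text(alphabet=AMINO_ACIDS, min_size=10, max_size=10)
windows_21 = st.builds(lambda a, b: a + "K" + b, flank, flank)


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac("A" * 21)
        assert v[AA_INDEX["A"]] == 1.0 and v.sum() == 1.0

    def test_hand_count_all_residues_plus_extra_a(self):
        # each of the 20 amino acids once, plus one extra A, K centered
        w = "ACDEFGHILA" + "K" + "MNPQRSTVWY"
        v = encode_aac(w)
        assert v[AA_INDEX["A"]] == pytest.approx(2 / 21)
        others = np.delete(v, AA_INDEX["A"])
        np.testing.assert_allclose(others, 1 / 21)

    def test_pads_excluded_from_denominator(self):
        w = "XXXXXXXXXA" + "K" + "AAAAAAAAAX"  # 10 A, 1 K, 10 X
        v = encode_aac(w)
        assert v[AA_INDEX["A"]] == pytest.approx(10 / 11)
        assert v[AA_INDEX["K"]] == pytest.approx(1 / 11)

    def test_all_x_errors(self):
        with pytest.raises(ValueError, match="all-'X'"):
            encode_aac("X" * 21)

    @given(windows_21)
    def test_sums_to_one_and_pure(self, w):
        v = encode_aac(w)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_array_equal(v, encode_aac(w))


class TestAAPC:
    def test_homopolymer(self):
        v = encode_aapc("A" * 21)
        assert v[AA_PAIRS.index("AA")] == 1.0 and v.sum() == 1.0

    def test_alternating(self):
        w = "AC" * 10 + "A"  # 21-mer, 10 AC pairs and 10 CA pairs
        v = encode_aapc(w)
        assert v[AA_PAIRS.index("AC")] == 0.5
        assert v[AA_PAIRS.index("CA")] == 0.5

    def test_x_excluded_pairs(self):
        v = encode_aapc("XXXXXXXXXMKAXXXXXXXXX")
        assert v[AA_PAIRS.index("MK")] == 0.5
        assert v[AA_PAIRS.index("KA")] == 0.5
        assert v.sum() == 1.0

    def test_no_valid_pair_errors(self):
        with pytest.raises(ValueError, match="pair"):
            encode_aapc("XAXKXAX")

    @given(windows_21)
    def test_brute_force_oracle(self, w):
        """Counts match direct enumeration of X-free adjacent pairs."""
        expected = {p: 0 for p in AA_PAIRS}
        total = 0
        for a, b in zip(w, w[1:]):
            if "X" not in (a, b):
                expected[a + b] += 1
                total += 1
        v = encode_aapc(w)
        for p, c in expected.items():
            assert v[AA_PAIRS.index(p)] == pytest.approx(c / total)


class TestANBPB:
    def test_fit_counts_conserved_and_additive(self):
        pos = ["AKC", "AKD"]
        neg = ["CKA"]
        m = fit_anbpb(pos, neg)
        np.testing.assert_array_equal(m.pos_counts.sum(axis=0), [2, 2, 2])
        np.testing.assert_array_equal(m.neg_counts.sum(axis=0), [1, 1, 1])
        m2 = fit_anbpb(pos + pos, neg)
        np.testing.assert_array_equal(m2.pos_counts, 2 * m.pos_counts)

    def test_single_window_one_hot_columns(self):
        m = fit_anbpb(["AKC"], ["DKE"])
        assert m.pos_counts[AA_INDEX["A"], 0] == 1
        assert m.pos_counts[:, 0].sum() == 1

    def test_phi_zero_is_half_at_count_equal_mp(self):
        # m = 21 makes m*p = 1 exactly; a residue with count 1 encodes to 0.5
        pos = ["AKA"] + ["CKC"] * 20  # A appears once at position 0
        neg = ["DKD"] * 21
        model = fit_anbpb(pos, neg)
        v = encode_anbpb(model, "AKD")
        assert v[0] == pytest.approx(0.5)

    def test_unseen_residue_tail_probability(self):
        """Count 0 with m=183: z = -(183/21)/sqrt(183 * (1/21) * (20/21)),
        checked against an erfc-based normal CDF oracle."""
        counts = np.zeros((21, 3))
        counts[AA_INDEX["C"], :] = 183  # all mass on C; A never seen
        model = ANBPBModel(counts, counts.copy(), m_pos=183, m_neg=183)
        z = -(183 / 21) / math.sqrt(183 * (1 / 21) * (20 / 21))
        expected = 0.5 * math.erfc(-z / math.sqrt(2))
        v = encode_anbpb(model, "AKA")
        assert v[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.2e-3, abs=2e-4)

    def test_dimension_42_for_21mers(self, strong_dataset):
        model = fit_anbpb(strong_dataset.positives, strong_dataset.negatives)
        v = encode_anbpb(model, strong_dataset.windows[0])
        assert v.shape == (42,)

    def test_components_strictly_inside_unit_interval(self, strong_dataset):
        model = fit_anbpb(strong_dataset.positives, strong_dataset.negatives)
        for w in strong_dataset.windows[:10]:
            v = encode_anbpb(model, w)
            assert (v > 0).all() and (v < 1).all()

    def test_monotone_in_counts(self):
        """Raising the count of the observed residue never lowers its score."""
        prev = -1.0
        for c in range(0, 11):
            counts = np.zeros((21, 1))
            counts[AA_INDEX["K"], 0] = c
            counts[AA_INDEX["C"], 0] = 10 - c
            model = ANBPBModel(counts, counts.copy(), m_pos=10, m_neg=10)
            v = encode_anbpb(model, "K")
            assert v[0] >= prev
            prev = v[0]

    def test_length_mismatch_errors(self):
        model = fit_anbpb(["AKC"], ["DKE"])
        with pytest.raises(ValueError, match="length"):
            encode_anbpb(model, "AAKCC")


class TestTopNGram:
    def test_one_hot_homopolymer(self):
        v = encode_top_n_gram(profile_from_window("A" * 21), 1)
        assert v[AMINO_ACIDS.index("A")] == 1.0

    def test_two_gram_words(self):
        row = np.zeros(20)
        row[AA_INDEX["A"]], row[AA_INDEX["C"]] = 0.6, 0.4
        profile = ResidueProfile(np.tile(row, (3, 1)))
        v = encode_top_n_gram(profile, 2)
        names = ["".join(t) for t in itertools.product(AMINO_ACIDS, repeat=2)]
        assert v[names.index("AC")] == 1.0

    def test_alphabetical_tie_break(self):
        row = np.zeros(20)
        row[AA_INDEX["C"]] = row[AA_INDEX["W"]] = 0.5
        v = encode_top_n_gram(ResidueProfile(row[None, :]), 1)
        assert v[AMINO_ACIDS.index("C")] == 1.0  # C before W

    def test_top1_of_one_hot_equals_positional_aac(self):
        w = "ACDEFGHILM" + "K" + "NPQRSTVWYA"
        v = encode_top_n_gram(profile_from_window(w), 1)
        np.testing.assert_allclose(v, encode_aac(w))

    def test_invalid_n(self):
        with pytest.raises(ValueError, match="n in"):
            encode_top_n_gram(profile_from_window("AKA"), 3)

    @given(windows_21)
    def test_sums_to_one(self, w):
        assert encode_top_n_gram(profile_from_window(w), 1).sum() == pytest.approx(1.0)

    def test_profile_file_round_trip(self, tmp_path):
        p = profile_from_window("XAKAX")
        f = tmp_path / "prof.tsv"
        write_profile(p, f)
        np.testing.assert_allclose(read_profile(f).freqs, p.freqs)


class TestProfileFromWindow:
    def test_one_hot_rows(self):
        p = profile_from_window("A" * 21)
        assert p.freqs[:, AA_INDEX["A"]].sum() == 21

    def test_x_position_uniform(self):
        p = profile_from_window("XAKAX")
        np.testing.assert_allclose(p.freqs[0], 0.05)


class TestPCPseAAC:
    def test_lambda_zero_equals_aac(self):
        w = "ACDEFGHILA" + "K" + "MNPQRSTVWY"
        np.testing.assert_allclose(
            encode_pc_pseaac(w, lam=0), encode_aac(w), atol=1e-12
        )

    def test_homopolymer_zero_correlation(self):
        v = encode_pc_pseaac("A" * 21, lam=4)
        np.testing.assert_allclose(v[:20], encode_aac("A" * 21))
        np.testing.assert_array_equal(v[20:], 0.0)

    def test_lambda_too_large_errors(self):
        with pytest.raises(ValueError, match="lambda"):
            encode_pc_pseaac("AKA", lam=3)

    @pytest.mark.parametrize("lam", [1, 2, 3, 4, 5])
    def test_oracle_shared_denominator(self, lam):
        """Components match a direct transcription of the pseudo-composition
        formula (frequencies and weighted tier factors over a shared
        denominator) on a fixed window."""
        rng = np.random.default_rng(7)
        w = "".join(rng.choice(list(AMINO_ACIDS), 10)) + "K" + "".join(
            rng.choice(list(AMINO_ACIDS), 10)
        )
        tables = load_default_property_tables()
        props = tables.standardized()
        idx = [AA_INDEX[r] for r in w]
        L = len(w)
        thetas = []
        for k in range(1, lam + 1):
            vals = [
                np.mean((props[:, idx[i + k]] - props[:, idx[i]]) ** 2)
                for i in range(L - k)
            ]
            thetas.append(sum(vals) / (L - k))
        freqs = np.zeros(20)
        for i in idx:
            freqs[i] += 1 / L
        wgt = 0.05
        denom = 1 + wgt * sum(thetas)
        expected = np.concatenate([freqs / denom, wgt * np.array(thetas) / denom])
        got = encode_pc_pseaac(w, lam=lam, weight=wgt)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)

    @given(windows_21, st.integers(min_value=0, max_value=5))
    def test_sums_to_one(self, w, lam):
        v = encode_pc_pseaac(w, lam=lam, weight=0.05)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert v.shape == (20 + lam,)


class TestCombineFeatures:
    def test_combined_width_407(self, strong_dataset):
        from pupsite.encoders import (
            aapc_matrix,
            anbpb_matrix,
            pc_pseaac_matrix,
            top_n_gram_matrix,
        )
        from pupsite.feature_selection import (
            rank_amino_acid_pairs,
            select_aapc_features,
        )
        from pupsite.encoders import aac_matrix

        ws = strong_dataset.windows[:30]
        ranking = rank_amino_acid_pairs(aac_matrix(strong_dataset.windows))
        model = fit_anbpb(strong_dataset.positives, strong_dataset.negatives)
        combined = combine_features(
            [
                ("aapc", select_aapc_features(aapc_matrix(ws), ranking, 320)),
                ("top1", top_n_gram_matrix(ws, 1)),
                ("anbpb", anbpb_matrix(model, ws)),
                ("pse", pc_pseaac_matrix(ws, lam=5)),
            ]
        )
        assert combined.n_features == 320 + 20 + 42 + 25 == 407

    def test_sample_order_mismatch_errors(self):
        a = make_fm(np.zeros((2, 1)), prefix="a")
        b = make_fm(np.zeros((2, 1)), prefix="b")
        with pytest.raises(ValueError, match="sample order"):
            combine_features([("x", a), ("y", b)])

    def test_duplicate_names_disambiguated_by_prefix(self):
        a = make_fm(np.zeros((2, 1)), names=["f"])
        b = make_fm(np.ones((2, 1)), names=["f"])
        c = combine_features([("x", a), ("y", b)])
        assert c.feature_names == ["x:f", "y:f"]
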