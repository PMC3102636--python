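"""Substitution-model construction, normalization and rate variation."""

import numpy as np
import pytest
from scipy import stats

from evosim.models import (
    AMINO_ACIDS,
    DNA,
    Alphabet,
    ModelError,
    SiteRateModel,
    STANDARD_GENETIC_CODE,
    SubstitutionModel,
    build_general_model,
    build_gtr,
    build_gy94,
    build_k80,
    build_unrest,
    codon_freqs_f3x4,
    discrete_gamma_rates,
    draw_site_rates,
    load_empirical_aa,
    sense_codons,
    transition_probabilities,
    write_empirical_aa,
)


def expected_rate(m: SubstitutionModel) -> float:
    off = m.Q.copy()
    np.fill_diagonal(off, 0.0)
    return float((m.pi[:, None] * off).sum())


def assert_valid(m: SubstitutionModel):
    assert np.abs(m.Q.sum(axis=1)).max() < 1e-10
    assert np.abs(m.pi @ m.Q).max() < 1e-8
    assert abs(m.pi.sum() - 1.0) < 1e-10
    assert abs(expected_rate(m) - 1.0) < 1e-10


class TestGeneralModel:
    def test_two_state_detailed_balance(self):
        # balance: pi_A * 1 = pi_B * 3  ->  pi = (0.75, 0.25)
        ab = Alphabet(("A", "B"))
        m = build_general_model(ab, [[0, 1], [3, 0]])
        assert np.allclose(m.pi, [0.75, 0.25], atol=1e-12)
        assert_valid(m)

    def test_symmetric_rates_give_uniform_pi(self, rng):
        R = rng.uniform(0.2, 2.0, size=(5, 5))
        R = (R + R.T) / 2
        m = build_general_model(Alphabet(tuple("abcde")), R)
        assert np.allclose(m.pi, 0.2, atol=1e-10)
        assert_valid(m)

    def test_triplet_token_alphabet(self):
        # three functionally equivalent stop codons under their own process
        stops = Alphabet(("TAA", "TAG", "TGA"))
        m = build_general_model(stops, [[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        assert m.alphabet.symbols == ("TAA", "TAG", "TGA")
        assert_valid(m)

    def test_negative_rate_rejected(self):
        with pytest.raises(ModelError, match="nonnegative"):
            build_general_model(DNA, -np.ones((4, 4)))

    def test_reducible_chain_names_unreachable_states(self):
        R = np.zeros((4, 4))
        R[0, 1] = R[1, 0] = 1.0
        R[2, 3] = R[3, 2] = 1.0
        with pytest.raises(ModelError, match="G|T"):
            build_general_model(DNA, R)

    def test_nonstationary_pi_rejected(self):
        with pytest.raises(ModelError, match="stationary"):
            build_general_model(
                Alphabet(("A", "B")), [[0, 1], [3, 0]], pi=np.array([0.5, 0.5])
            )

    def test_unnormalized_flag_keeps_raw_rates(self):
        ab = Alphabet(("A", "B"))
        m = build_general_model(ab, [[0, 2], [2, 0]], normalize=False)
        assert m.Q[0, 1] == 2.0 and m.scale == 1.0


class TestNamedNucleotideModels:
    def test_k80_kappa_one_is_jukes_cantor(self):
        m = build_k80(1.0)
        off = m.Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0, atol=1e-12)

    def test_k80_kappa_two_rates(self):
        # beta (kappa + 2) = 1 with uniform pi -> transversion 1/4, transition 1/2
        m = build_k80(2.0)
        a, g = DNA.index["A"], DNA.index["G"]
        c = DNA.index["C"]
        assert m.Q[a, g] == pytest.approx(0.5, abs=1e-12)
        assert m.Q[a, c] == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.3, 1.0, 2.0, 7.5])
    def test_k80_normalization(self, kappa):
        assert_valid(build_k80(kappa))

    def test_k80_invalid_kappa(self):
        with pytest.raises(ModelError):
            build_k80(0.0)

    def test_gtr_nests_k80(self):
        kappa = 2.5
        # order (AC, AG, AT, CG, CT, GT): transitions are AG and CT
        m_gtr = build_gtr([1, kappa, 1, 1, kappa, 1], [0.25] * 4)
        m_k80 = build_k80(kappa)
        assert np.allclose(m_gtr.Q, m_k80.Q, atol=1e-12)

    def test_gtr_skewed_frequencies_stationary(self):
        m = build_gtr([1.2, 2.0, 0.7, 1.1, 3.0, 0.9], [0.1, 0.2, 0.3, 0.4])
        assert np.allclose(m.pi, [0.1, 0.2, 0.3, 0.4])
        assert_valid(m)

    def test_gtr_frequency_sum_checked(self):
        with pytest.raises(ModelError, match="sum"):
            build_gtr([1] * 6, [0.3, 0.3, 0.3, 0.3])

    def test_unrest_symmetric_gives_uniform(self):
        m = build_unrest([1.0] * 12)
        assert np.allclose(m.pi, 0.25, atol=1e-10)

    def test_unrest_recovers_gtr_frequencies(self):
        gtr = build_gtr([1.2, 2.0, 0.7, 1.1, 3.0, 0.9], [0.1, 0.2, 0.3, 0.4])
        rates = [gtr.Q[i, j] for i in range(4) for j in range(4) if i != j]
        m = build_unrest(rates)
        assert np.allclose(m.pi, gtr.pi, atol=1e-8)
        assert_valid(m)


class TestEmpiricalAminoAcid:
    @pytest.mark.parametrize("name", ["WAG", "JTT", "LG"])
    def test_packaged_matrices(self, name):
        m = load_empirical_aa(name)
        assert len(m.alphabet) == 20
        assert_valid(m)

    def test_equal_exchangeabilities_file(self, tmp_path):
        path = tmp_path / "flat.dat"
        lines = [" ".join(["1.0"] * i) for i in range(1, 20)]
        lines += ["", " ".join(["0.05"] * 20)]
        path.write_text("\n".join(lines) + "\n")
        m = load_empirical_aa(str(path))
        off = m.Q[~np.eye(20, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_write_reload_roundtrip(self, tmp_path):
        m = load_empirical_aa("WAG")
        out = tmp_path / "back.dat"
        write_empirical_aa(m, str(out))
        m2 = load_empirical_aa(str(out))
        assert np.allclose(m2.Q, m.Q, rtol=1e-8)
        assert np.allclose(m2.pi, m.pi, atol=1e-9)

    def test_malformed_triangle_reports_line(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("1.0\n1.0 oops\n")
        with pytest.raises(ModelError, match="line 2"):
            load_empirical_aa(str(path))

    def test_off_frequencies_renormalized_with_warning(self, tmp_path):
        path = tmp_path / "warn.dat"
        lines = [" ".join(["1.0"] * i) for i in range(1, 20)]
        lines += ["", " ".join(["0.06"] * 20)]  # sums to 1.2
        path.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="renormal"):
            m = load_empirical_aa(str(path))
        assert abs(m.pi.sum() - 1.0) < 1e-12


class TestGY94:
    def test_state_space_excludes_stops(self):
        codons = sense_codons()
        assert len(codons) == 61
        assert not any(STANDARD_GENETIC_CODE[c] == "*" for c in codons)

    def test_omega_zero_kills_all_nonsynonymous_rates(self):
        m = build_gy94(2.0, 0.0)
        code = STANDARD_GENETIC_CODE
        syms = m.alphabet.symbols
        for i, ci in enumerate(syms):
            for j, cj in enumerate(syms):
                if i != j and code[ci] != code[cj]:
                    assert m.Q[i, j] == 0.0

    def test_transition_vs_transversion_classification(self):
        kappa, omega = 2.0, 0.5
        m = build_gy94(kappa, omega)
        idx = m.alphabet.index
        # AAA->AAG synonymous transition (kappa); AAA->AAT nonsynonymous
        # transversion (omega); with equal frequencies the ratio is kappa/omega
        ratio = m.Q[idx["AAA"], idx["AAG"]] / m.Q[idx["AAA"], idx["AAT"]]
        assert ratio == pytest.approx(kappa / omega, rel=1e-12)

    def test_multi_position_changes_forbidden(self):
        m = build_gy94(2.0, 0.5)
        idx = m.alphabet.index
        assert m.Q[idx["AAA"], idx["AGG"]] == 0.0

    def test_neutral_equal_frequency_rates_collapse(self):
        m = build_gy94(1.0, 1.0)
        off = m.Q[~np.eye(61, dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0], rtol=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ModelError):
            build_gy94(0.0, 1.0)
        with pytest.raises(ModelError):
            build_gy94(2.0, -0.1)
        with pytest.raises(ModelError, match="stop"):
            build_gy94(2.0, 1.0, codon_freqs=np.full(64, 1 / 64))

    def test_f3x4_frequencies(self):
        pi = codon_freqs_f3x4(np.full((3, 4), 0.25))
        assert pi.shape == (61,)
        assert np.allclose(pi, 1 / 61)
        assert_valid(build_gy94(2.0, 0.3, codon_freqs=pi))


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, k80_2):
        assert np.allclose(transition_probabilities(k80_2, 0.0), np.eye(4), atol=1e-14)

    def test_long_time_reaches_equilibrium(self):
        m = build_gtr([1.2, 2.0, 0.7, 1.1, 3.0, 0.9], [0.1, 0.2, 0.3, 0.4])
        P = transition_probabilities(m, 50.0)
        assert np.allclose(P, np.tile(m.pi, (4, 1)), atol=1e-6)

    def test_jukes_cantor_closed_form(self, jc):
        t = 0.1
        P = transition_probabilities(jc, t)
        diag = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        assert np.allclose(np.diag(P), diag, atol=1e-12)

    def test_negative_time_rejected(self, jc):
        with pytest.raises(ModelError):
            transition_probabilities(jc, -0.1)

    def test_matches_truncated_power_series(self, rng):
        # independent oracle: sum_{k<=40} (Qt)^k / k!
        for n in (2, 4, 7, 10):
            ab = Alphabet(tuple(f"s{i}" for i in range(n)))
            m = build_general_model(ab, rng.uniform(0.1, 1.5, size=(n, n)))
            t = rng.uniform(0.05, 2.0)
            A = m.Q * t
            term = np.eye(n)
            series = np.eye(n)
            for k in range(1, 41):
                term = term @ A / k
                series += term
            assert np.allclose(transition_probabilities(m, t), series, atol=1e-8)


class TestSiteRates:
    def test_constant(self, rng):
        assert np.all(draw_site_rates(SiteRateModel("constant"), 10, rng) == 1.0)

    def test_all_invariant(self, rng):
        m = SiteRateModel("invariant_plus_gamma", alpha=1.0, p_inv=1.0)
        assert np.all(draw_site_rates(m, 100, rng) == 0.0)

    @pytest.mark.parametrize("alpha,k", [(0.2, 4), (1.0, 4), (2.5, 8)])
    def test_discrete_gamma_category_mean_is_one(self, alpha, k):
        rates = discrete_gamma_rates(alpha, k)
        assert np.all(rates >= 0)
        assert abs(rates.mean() - 1.0) < 1e-9

    def test_discrete_gamma_known_values(self):
        # Yang (1994)-style equal-probability category means for alpha=0.5
        rates = discrete_gamma_rates(0.5, 4)
        assert np.allclose(rates, [0.0334, 0.2519, 0.8203, 2.8944], atol=2e-4)

    def test_invariant_plus_gamma_marginal_mean(self, rng):
        m = SiteRateModel("invariant_plus_gamma", alpha=1.0, p_inv=0.3)
        draws = draw_site_rates(m, 60000, rng)
        frac_zero = np.mean(draws == 0.0)
        assert frac_zero == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 60000))
        assert draws.mean() == pytest.approx(1.0, abs=0.05)

    def test_continuous_gamma_mean(self, rng):
        m = SiteRateModel("continuous_gamma", alpha=2.0)
        draws = draw_site_rates(m, 60000, rng)
        assert draws.mean() == pytest.approx(1.0, abs=3 / np.sqrt(2.0 * 60000))

    def test_custom_rule_and_negative_error(self, rng):
        m = SiteRateModel("custom", custom_rule=lambda i, g: float(i % 3))
        assert list(draw_site_rates(m, 4, rng)) == [0.0, 1.0, 2.0, 0.0]
        bad = SiteRateModel("custom", custom_rule=lambda i, g: -1.0)
        with pytest.raises(ModelError, match="site 0"):
            draw_site_rates(bad, 2, rng)

    def test_gamma_alpha_validation(self):
        with pytest.raises(ModelError):
            SiteRateModel("discrete_gamma", alpha=0.0)

    def test_determinism_given_seed(self):
        m = SiteRateModel("continuous_gamma", alpha=0.7)
        a = draw_site_rates(m, 20, np.random.default_rng(5))
        b = draw_site_rates(m, 20, np.random.default_rng(5))
        assert np.array_equal(a, b)
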