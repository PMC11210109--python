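"""Modality / sub-modality / probability transitions and the full pair."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from consig import (
    DOWN,
    NULL,
    UP,
    ConnectivityModel,
    LayerSet,
    ModalityDistribution,
    ProbabilityTransitionConfig,
    SubmodalityTransitionConfig,
    TransitionMatrix,
    compose_lfc,
    sample_primary_layers,
    simulate_secondary,
    symmetric_transition_matrix,
    transition_modalities,
    transition_probabilities,
    transition_submodalities,
)
from consig.signature_model import build_submodality_bank

DET = SubmodalityTransitionConfig(strategy="deterministic")
DET_P = ProbabilityTransitionConfig(strategy="deterministic")
INDEP = SubmodalityTransitionConfig(strategy="independent")
INDEP_P = ProbabilityTransitionConfig(strategy="independent")


class TestSymmetricMatrix:
    def test_perfect_connectivity(self):
        m = symmetric_transition_matrix(ConnectivityModel(c=1.0, gamma=0.0)).matrix
        np.testing.assert_allclose(m, np.eye(3), atol=1e-15)

    def test_null_connectivity(self):
        m = symmetric_transition_matrix(ConnectivityModel(c=0.0, gamma=0.0)).matrix
        np.testing.assert_allclose(m[0], [0.5, 0.0, 0.5], atol=1e-15)
        np.testing.assert_allclose(m[1], [0.0, 1.0, 0.0], atol=1e-15)

    def test_hand_derived_row(self):
        m = symmetric_transition_matrix(ConnectivityModel(c=0.5, gamma=0.02)).matrix
        np.testing.assert_allclose(m[0], [0.7425, 0.01, 0.2475], atol=1e-12)
        np.testing.assert_allclose(m[1, 1], 0.98, atol=1e-12)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        c=st.floats(min_value=-1, max_value=1, allow_nan=False),
        gamma=st.floats(min_value=0, max_value=0.5, allow_nan=False),
    )
    def test_row_stochastic_identity(self, c, gamma):
        """The printed formulas are row-stochastic for every valid (c, gamma)."""
        m = symmetric_transition_matrix(ConnectivityModel(c=c, gamma=gamma)).matrix
        assert (m >= -1e-15).all()
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            ConnectivityModel(c=1.2, gamma=0.0)
        with pytest.raises(ValueError):
            ConnectivityModel(c=0.0, gamma=0.6)


class TestModalityTransition:
    def test_identity_matrix(self):
        primary = np.array([1, 2, 3, 1, 2, 3])
        out = transition_modalities(primary, TransitionMatrix(np.eye(3)), seed=0)
        np.testing.assert_array_equal(out, primary)

    def test_absorbing_null(self):
        matrix = TransitionMatrix(np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0.0]]))
        out = transition_modalities(np.array([1, 2, 3]), matrix, seed=0)
        assert (out == NULL).all()

    def test_empirical_frequencies(self):
        g = 20_000
        matrix = symmetric_transition_matrix(ConnectivityModel(c=0.0, gamma=0.0))
        out = transition_modalities(np.full(g, UP), matrix, seed=1)
        for beta, p in [(UP, 0.5), (NULL, 0.0), (DOWN, 0.5)]:
            se = np.sqrt(max(p * (1 - p), 0.25) / g)
            assert abs((out == beta).mean() - p) <= 3 * se

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            TransitionMatrix(np.full((3, 3), 0.5))

    def test_chi_square_per_row(self, bank, omega):
        g = 50_000
        layers = sample_primary_layers(omega, bank, g, seed=2)
        matrix = symmetric_transition_matrix(ConnectivityModel(c=0.4, gamma=0.1))
        out = transition_modalities(layers.modality, matrix, seed=3)
        for alpha in (UP, NULL, DOWN):
            sel = layers.modality == alpha
            observed = [(out[sel] == b).sum() for b in (1, 2, 3)]
            expected = matrix.row(alpha) * sel.sum()
            keep = expected > 0
            assert stats.chisquare(
                np.array(observed)[keep], expected[keep]
            ).pvalue > 0.001


class TestSubmodalityTransition:
    def test_deterministic_identity(self, bank, omega):
        layers = sample_primary_layers(omega, bank, 2000, seed=4)
        sec_mod = layers.modality.copy()
        out = transition_submodalities(layers, sec_mod, bank, DET, seed=5)
        linked = (layers.modality != NULL) & (sec_mod != NULL)
        np.testing.assert_array_equal(out[linked], layers.submodality[linked])

    def test_stochastic_binomial_degenerate(self):
        """tau = N gives Binomial(N, 1): always N."""
        n = 10
        entries = [
            {"family": "gamma", "params": (2.0 + i, 1.0), "proportion": 1.0 / n}
            for i in range(n)
        ]
        bank10 = build_submodality_bank(
            {"modalities": {"up": entries, "down": entries,
                            "null": [{"family": "gaussian", "params": (0.0, 0.1),
                                      "proportion": 1.0}]}}
        )
        g = 200
        layers = LayerSet(
            modality=np.full(g, UP),
            submodality=np.full(g, n),
            probability=np.full(g, 0.5),
        )
        cfg = SubmodalityTransitionConfig(strategy="stochastic")
        out = transition_submodalities(layers, np.full(g, UP), bank10, cfg, seed=6)
        assert (out == n).all()

    def test_stochastic_binomial_mean(self):
        """Conditional mean of the binomial link is tau (= n * tau/n)."""
        n = 10
        entries = [
            {"family": "gamma", "params": (2.0 + i, 1.0), "proportion": 1.0 / n}
            for i in range(n)
        ]
        bank10 = build_submodality_bank(
            {"modalities": {"up": entries, "down": entries,
                            "null": [{"family": "gaussian", "params": (0.0, 0.1),
                                      "proportion": 1.0}]}}
        )
        g = 100_000
        layers = LayerSet(
            modality=np.full(g, UP),
            submodality=np.full(g, 5),
            probability=np.full(g, 0.5),
        )
        cfg = SubmodalityTransitionConfig(strategy="stochastic")
        out = transition_submodalities(layers, np.full(g, UP), bank10, cfg, seed=7)
        assert 4.95 <= out.mean() <= 5.05

    def test_unequal_counts_rejected(self, bank):
        solo = [{"family": "gamma", "params": (4.0, 0.5), "proportion": 1.0}]
        bank_mixed = build_submodality_bank(
            {
                "modalities": {
                    "up": [
                        {"family": "gamma", "params": (20.0, 0.04), "proportion": 0.5},
                        {"family": "gamma", "params": (20.0, 0.08), "proportion": 0.5},
                    ],
                    "null": [{"family": "gaussian", "params": (0.0, 0.1),
                              "proportion": 1.0}],
                    "down": solo,
                },
            }
        )
        layers = LayerSet(
            modality=np.array([UP]), submodality=np.array([1]),
            probability=np.array([0.5]),
        )
        with pytest.raises(ValueError):
            transition_submodalities(layers, np.array([DOWN]), bank_mixed, DET, seed=0)

    def test_null_genes_use_independent_draw(self, bank):
        """alpha = 2 or beta = 2 always draws from the secondary proportions."""
        g = 20_000
        layers = LayerSet(
            modality=np.full(g, NULL), submodality=np.ones(g, dtype=int),
            probability=np.full(g, 0.5),
        )
        out = transition_submodalities(layers, np.full(g, UP), bank, DET, seed=8)
        props = np.array(bank.secondary[UP].proportions)
        freqs = np.array([(out == s + 1).mean() for s in range(len(props))])
        np.testing.assert_allclose(freqs, props, atol=3 * np.sqrt(0.25 / g) + 0.01)

    def test_copula_strategy_correlates_ranks(self, bank, omega):
        layers = sample_primary_layers(
            ModalityDistribution(omega=(0.5, 0.0, 0.5)), bank, 30_000, seed=9
        )
        cfg = SubmodalityTransitionConfig(
            strategy="copula", copula_family="frank", target_correlation=0.9
        )
        out = transition_submodalities(layers, layers.modality, bank, cfg, seed=10)
        # doubly-deregulated genes (all here) should correlate strongly
        r = np.corrcoef(layers.submodality, out)[0, 1]
        assert r == pytest.approx(0.9, abs=0.03)


class TestProbabilityTransition:
    def test_deterministic_copy(self):
        psi = np.linspace(0, 1, 11)
        out = transition_probabilities(psi, DET_P, seed=0)
        np.testing.assert_array_equal(out, psi)

    def test_independent_uniform_uncorrelated(self):
        rng = np.random.default_rng(0)
        psi = rng.uniform(size=50_000)
        out = transition_probabilities(psi, INDEP_P, seed=1)
        assert stats.kstest(out, "uniform").pvalue > 0.001
        assert abs(np.corrcoef(psi, out)[0, 1]) < 0.02

    def test_copula_gauss_hits_target(self):
        rng = np.random.default_rng(2)
        psi = rng.uniform(size=50_000)
        cfg = ProbabilityTransitionConfig(
            strategy="copula", copula_family="gauss", target_correlation=0.8
        )
        out = transition_probabilities(psi, cfg, seed=3)
        assert np.corrcoef(psi, out)[0, 1] == pytest.approx(0.8, abs=0.02)

    def test_copula_requires_fields(self):
        with pytest.raises(ValueError):
            ProbabilityTransitionConfig(strategy="copula")
        with pytest.raises(ValueError):
            ProbabilityTransitionConfig(strategy="independent", copula_family="gauss")


class TestSimulateSecondary:
    def test_identity_at_perfect_connectivity(self, bank, omega):
        layers = sample_primary_layers(omega, bank, 3000, seed=11)
        primary = compose_lfc(layers, bank)
        _, secondary = simulate_secondary(
            layers, ConnectivityModel(c=1.0, gamma=0.0), DET, DET_P, bank, seed=12
        )
        np.testing.assert_allclose(secondary.lfc, primary.lfc, atol=1e-12)

    def test_negation_at_anti_connectivity(self, bank, omega):
        """c = -1, gamma = 0 swaps up/down; the sign-symmetric bank negates."""
        layers = sample_primary_layers(omega, bank, 3000, seed=13)
        primary = compose_lfc(layers, bank)
        _, secondary = simulate_secondary(
            layers, ConnectivityModel(c=-1.0, gamma=0.0), DET, DET_P, bank, seed=14
        )
        dereg = layers.modality != NULL
        np.testing.assert_allclose(
            secondary.lfc[dereg], -primary.lfc[dereg], atol=1e-12
        )

    def test_null_connectivity_no_chimeric_correlation(self, bank, omega):
        cors = []
        for k in range(5):
            layers = sample_primary_layers(omega, bank, 10_000, seed=20 + k)
            primary = compose_lfc(layers, bank)
            _, secondary = simulate_secondary(
                layers, ConnectivityModel(c=0.0, gamma=0.02), INDEP, INDEP_P,
                bank, seed=30 + k,
            )
            cors.append(np.corrcoef(primary.lfc, secondary.lfc)[0, 1])
        assert -0.05 <= np.mean(cors) <= 0.05

    def test_custom_matrix_accepted(self, bank, omega):
        layers = sample_primary_layers(omega, bank, 500, seed=15)
        matrix = TransitionMatrix(np.array([[0.9, 0.05, 0.05],
                                            [0.1, 0.8, 0.1],
                                            [0.05, 0.05, 0.9]]))
        _, secondary = simulate_secondary(layers, matrix, DET, DET_P, bank, seed=16)
        assert secondary.n_genes == 500

    def test_noise_shrinks_correlation(self, bank, omega):
        """Fixed c, higher gamma pulls the pair correlation towards zero."""

        def mean_corr(gamma, seeds=range(5)):
            out = []
            for k in seeds:
                layers = sample_primary_layers(omega, bank, 10_000, seed=40 + k)
                primary = compose_lfc(layers, bank)
                _, secondary = simulate_secondary(
                    layers, ConnectivityModel(c=0.75, gamma=gamma), DET, DET_P,
                    bank, seed=50 + k,
                )
                out.append(np.corrcoef(primary.lfc, secondary.lfc)[0, 1])
            return np.mean(out)

        assert mean_corr(0.3) < mean_corr(0.02)
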