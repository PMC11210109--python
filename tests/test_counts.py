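"""Read-count generation and the simplified NB-Wald DE re-inference."""

import numpy as np
import pytest
from scipy import stats

from consig import (
    BaseExpression,
    CountMatrix,
    CountModel,
    compose_lfc,
    control_expression,
    median_of_ratios_size_factors,
    nb_wald_de,
    perturb_control,
    sample_base_expression,
    sample_primary_layers,
    simulate_count_matrix,
    simulate_counts,
    simulate_replicate_layers,
)
from consig.counts import expected_counts, reinfer_signature, xi_per_gene


class TestControlExpression:
    @pytest.mark.parametrize(
        "xi,expected", [(0.0, 100.0), (1.0, 200.0 / 3.0), (-1.0, 400.0 / 3.0)]
    )
    def test_hand_values(self, xi, expected):
        base = BaseExpression(mu_tilde=np.array([100.0]))
        assert control_expression(base, np.array([xi]))[0] == pytest.approx(expected)

    def test_mean_preservation_identity(self):
        """(mu_Ct + mu_Ct * 2^xi) / 2 equals mu_tilde to machine precision."""
        rng = np.random.default_rng(0)
        mu = rng.lognormal(3, 1, 1000)
        xi = rng.normal(0, 2, 1000)
        base = BaseExpression(mu_tilde=mu)
        mu_ct = control_expression(base, xi)
        np.testing.assert_allclose((mu_ct + mu_ct * np.exp2(xi)) / 2, mu, rtol=1e-14)

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError):
            BaseExpression(mu_tilde=np.array([-1.0]))


class TestPerturbControl:
    def test_zero_sd_identity(self):
        mu = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(perturb_control(mu, seed=0, sd=0.0), mu)

    def test_log2_noise_sd(self):
        mu = np.full(50_000, 100.0)
        out = perturb_control(mu, seed=1, sd=0.5)
        assert 0.49 <= np.log2(out / mu).std() <= 0.51
        assert (out >= 0).all()

    def test_determinism(self):
        mu = np.arange(1.0, 100.0)
        a = perturb_control(mu, seed=2)
        b = perturb_control(mu, seed=2)
        np.testing.assert_array_equal(a, b)


class TestSimulateCounts:
    def test_single_gene_gets_whole_library(self):
        base = BaseExpression(mu_tilde=np.array([37.0]))
        model = CountModel(total_reads=1000)
        delta = expected_counts(np.array([37.0]), np.array([2.0]), base, model)
        assert delta[0] == pytest.approx(1000.0)

    def test_expected_library_size_exact_and_realized_close(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(3, 1.2, 2000)
        base = BaseExpression(mu_tilde=mu)
        model = CountModel(total_reads=10_000_000)
        fc = np.exp2(rng.normal(0, 1, 2000))
        delta = expected_counts(mu, fc, base, model)
        assert delta.sum() == pytest.approx(model.total_reads, rel=1e-12)
        counts = simulate_counts(mu, fc, base, model, seed=4)
        assert abs(counts.sum() - model.total_reads) / model.total_reads < 0.01

    def test_poisson_limit_at_large_size_factor(self):
        """Variance/mean ratio approaches 1 as f grows (NB -> Poisson)."""
        g = 20_000
        mu = np.full(g, 100.0)
        base = BaseExpression(mu_tilde=mu)
        model = CountModel(total_reads=g * 1000, size_factor=1e6)
        counts = simulate_counts(mu, np.ones(g), base, model, seed=5)
        ratio = counts.var() / counts.mean()
        assert ratio == pytest.approx(1.0, abs=0.05)
        # and the default f = 1/3 is visibly overdispersed: ratio ~ 1 + 1/f = 4
        model_od = CountModel(total_reads=g * 1000, size_factor=1.0 / 3.0)
        counts_od = simulate_counts(mu, np.ones(g), base, model_od, seed=6)
        assert counts_od.var() / counts_od.mean() == pytest.approx(4.0, rel=0.1)

    def test_all_zero_expression_rejected(self):
        base = BaseExpression(mu_tilde=np.zeros(5))
        with pytest.raises(ValueError):
            expected_counts(np.zeros(5), np.ones(5), base, CountModel())


class TestSizeFactors:
    def test_identical_columns(self):
        mat = np.tile(np.arange(1, 50)[:, None], (1, 4))
        np.testing.assert_allclose(median_of_ratios_size_factors(mat), 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        mat = rng.poisson(100, size=(200, 3)) + 1
        doubled = np.column_stack([mat, 2 * mat[:, 0]])
        sf = median_of_ratios_size_factors(doubled)
        assert sf[3] / sf[0] == pytest.approx(2.0, rel=1e-9)

    def test_against_brute_force(self):
        rng = np.random.default_rng(8)
        mat = rng.negative_binomial(5, 0.1, size=(300, 4))
        keep = (mat > 0).all(axis=1)
        geo = np.exp(np.mean(np.log(mat[keep].astype(float)), axis=1))
        expected = [
            float(np.median(mat[keep, j] / geo)) for j in range(4)
        ]
        np.testing.assert_allclose(
            median_of_ratios_size_factors(mat), expected, rtol=1e-12
        )

    def test_no_common_gene_rejected(self):
        mat = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError):
            median_of_ratios_size_factors(mat)


def _two_group_matrix(treated, control, gene_ids=None):
    t = np.asarray(treated)
    c = np.asarray(control)
    counts = np.column_stack([t, c]).astype(np.int64)
    n_t, n_c = t.shape[1], c.shape[1]
    return CountMatrix(
        counts=counts,
        condition=["treated"] * n_t + ["control"] * n_c,
        replicate=list(range(1, n_t + 1)) + list(range(1, n_c + 1)),
        gene_ids=gene_ids
        if gene_ids is not None
        else np.array([f"g{i}" for i in range(counts.shape[0])]),
    )


class TestNbWaldDe:
    def test_null_gene(self):
        base = np.array([[100, 110, 90], [50, 55, 45]])
        cm = _two_group_matrix(base, base)
        res = nb_wald_de(cm)
        np.testing.assert_allclose(res.lfc_hat, 0.0, atol=1e-12)
        assert (res.pvalue > 0.9).all()

    def test_too_few_replicates_rejected(self):
        cm = CountMatrix(
            counts=np.array([[5, 6, 7]]),
            condition=["treated", "control", "control"],
            replicate=[1, 1, 2],
            gene_ids=np.array(["g0"]),
        )
        with pytest.raises(ValueError):
            nb_wald_de(cm)

    def test_bh_against_brute_force(self):
        """BH step-up on the produced p-values, re-derived independently."""
        rng = np.random.default_rng(9)
        t = rng.poisson(200, size=(100, 3))
        c = rng.poisson(100, size=(100, 3))
        res = nb_wald_de(_two_group_matrix(t, c))
        p = res.pvalue
        n = p.size
        order = np.argsort(p, kind="stable")
        stepped = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(res.padj, expected, rtol=1e-10)

    def test_lfc_coverage(self):
        """95% t-CI for a true linear FC of 4 covers 2 log2 units >= 90%.

        The focal gene sits in a background of 99 null genes so that the
        median-of-ratios normalization is estimated from stable genes.
        """
        rng = np.random.default_rng(10)
        f = 1.0 / 3.0
        p = f / (1.0 + f)
        covered = 0
        n_seeds = 200
        tcrit = stats.t.ppf(0.975, 4)
        for _ in range(n_seeds):
            null_t = rng.negative_binomial(f * 500.0, p, size=(99, 3))
            null_c = rng.negative_binomial(f * 500.0, p, size=(99, 3))
            t = np.vstack([rng.negative_binomial(f * 4000.0, p, size=(1, 3)), null_t])
            c = np.vstack([rng.negative_binomial(f * 1000.0, p, size=(1, 3)), null_c])
            res = nb_wald_de(_two_group_matrix(t, c))
            lo = res.lfc_hat[0] - tcrit * res.se[0]
            hi = res.lfc_hat[0] + tcrit * res.se[0]
            covered += lo <= 2.0 <= hi
        assert covered / n_seeds >= 0.90


class TestReplicates:
    def test_perfect_replication(self, bank, omega):
        layers = sample_primary_layers(omega, bank, 1000, seed=11)
        reps = simulate_replicate_layers(
            layers, 3, bank, seed=12, rep_connectivity=1.0, rep_noise=0.0
        )
        for r in reps:
            np.testing.assert_array_equal(r.modality, layers.modality)
            np.testing.assert_array_equal(r.submodality, layers.submodality)
            np.testing.assert_array_equal(r.probability, layers.probability)

    def test_default_replicates_strongly_correlated(self, bank, omega):
        """Each replicate tracks its parent closely (c = 0.9, gamma = 0.02).

        Parent-replicate correlation sits near 0.9; two replicates are
        conditionally independent given the parent, so their pairwise
        correlation is near 0.9^2 ~ 0.8.
        """
        layers = sample_primary_layers(omega, bank, 10_000, seed=13)
        parent = compose_lfc(layers, bank).lfc
        reps = simulate_replicate_layers(layers, 3, bank, seed=14)
        lfcs = [compose_lfc(r, bank, 2).lfc for r in reps]
        for r in lfcs:
            assert np.corrcoef(parent, r)[0, 1] > 0.8
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.corrcoef(lfcs[i], lfcs[j])[0, 1] > 0.65

    def test_determinism(self, bank, omega):
        layers = sample_primary_layers(omega, bank, 500, seed=15)
        a = simulate_replicate_layers(layers, 2, bank, seed=16)
        b = simulate_replicate_layers(layers, 2, bank, seed=16)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.probability, y.probability)
            np.testing.assert_array_equal(x.modality, y.modality)


class TestEndToEnd:
    def test_recovery_and_peak_flattening(self, bank, omega):
        g = 2000
        layers = sample_primary_layers(omega, bank, g, seed=17)
        truth = compose_lfc(layers, bank)
        base = sample_base_expression(g, seed=18)
        model = CountModel(total_reads=2_000_000)
        sig = reinfer_signature(layers, bank, base, model, seed=19)
        sel = (np.abs(truth.lfc) >= 1) & (base.mu_tilde >= 50)
        # sanity recovery bound; the stricter bound lives in the acceptance suite
        assert np.corrcoef(truth.lfc[sel], sig.lfc[sel])[0, 1] > 0.8
        # re-inference flattens the near-zero peak of the raw simulated LFC
        assert (np.abs(sig.lfc) < 0.05).mean() < (np.abs(truth.lfc) < 0.05).mean()

    def test_against_pydeseq2(self, bank, omega):
        """The simplified NB-Wald LFCs track DESeq2's on the same counts."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        import warnings

        import pandas as pd
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        g = 300
        layers = sample_primary_layers(omega, bank, g, seed=20)
        base = sample_base_expression(g, seed=21)
        cm = simulate_count_matrix(layers, bank, base, CountModel(total_reads=300_000), seed=22)
        mine = nb_wald_de(cm)
        counts_df = pd.DataFrame(cm.counts.T, columns=cm.gene_ids)
        meta = pd.DataFrame({"condition": cm.condition}, index=counts_df.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=counts_df, metadata=meta, design="~condition", quiet=True
            )
            dds.deseq2()
            ds = DeseqStats(
                dds, contrast=["condition", "treated", "control"], quiet=True
            )
            ds.summary()
        ref = ds.results_df["log2FoldChange"].to_numpy()
        ok = np.isfinite(ref)
        assert np.corrcoef(mine.lfc_hat[ok], ref[ok])[0, 1] > 0.99

    def test_count_matrix_structure(self, bank, omega):
        layers = sample_primary_layers(omega, bank, 200, seed=23)
        base = sample_base_expression(200, seed=24)
        cm = simulate_count_matrix(layers, bank, base, CountModel(total_reads=100_000), seed=25)
        assert cm.counts.shape == (200, 6)
        assert cm.condition.count("treated") == 3
        assert cm.condition.count("control") == 3
        assert np.issubdtype(cm.counts.dtype, np.integer)
        # xi lookup matches the bank's mean LFCs
        xi = xi_per_gene(layers, bank)
        assert xi.shape == (200,)
        assert (xi[layers.modality == 2] == 0).all()
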