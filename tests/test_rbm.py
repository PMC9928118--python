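"""Compositional RBM: energy oracles, sampler correctness, training,
partition-function estimation and interpretation tools."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp, softmax
from scipy.stats import chisquare, spearmanr
from sklearn.metrics import roc_auc_score

from conftest import build_tiny_rbm, enumerate_states, exact_log_partition
from pepfunnel.alignment import Alignment, sequence_weights
from pepfunnel.alphabet import ALPHABET, Q, encode_many
from pepfunnel.potentials import DReLU
from pepfunnel.rbm import SequenceRBM, frobenius_couplings
from pepfunnel.synthetic import make_mfa


class TestEnergy:
    def test_zero_model_energy_is_hidden_constant(self):
        model = build_tiny_rbm()
        model.weights_ = np.zeros_like(model.weights_)
        model.fields_ = np.where(model.fields_ < -1e8, model.fields_, 0.0)
        const = model.potential_.gamma(np.zeros(model.n_hidden)).sum()
        assert model.unnormalized_logp(["AAA", "ACD", "DDD"]) == pytest.approx(const)

    def test_normalization_by_enumeration(self):
        model = build_tiny_rbm(seed=1)
        log_z, states = exact_log_partition(model, 4)
        assert np.exp(model.unnormalized_logp(states) - log_z).sum() == pytest.approx(1.0)

    def test_field_gauge_shift(self):
        model = build_tiny_rbm(seed=2)
        states = enumerate_states(3, 4)
        before = model.unnormalized_logp(states)
        model.fields_[1] = model.fields_[1] + 0.7
        after = model.unnormalized_logp(states)
        assert np.allclose(after - before, 0.7)

    def test_quadratic_potential_equals_low_rank_potts(self):
        model = build_tiny_rbm(seed=3, quadratic=1.3)
        states = enumerate_states(3, 4)
        lp = model.unnormalized_logp(states)
        W = model.weights_
        M = model.n_hidden
        potts = []
        for st in itertools.product(range(4), repeat=3):
            g = sum(model.fields_[i, st[i]] for i in range(3))
            quad = sum(
                sum(W[mu, i, st[i]] for i in range(3)) ** 2 / (2 * 1.3) for mu in range(M)
            )
            potts.append(g + quad + M * 0.5 * np.log(2 * np.pi / 1.3))
        assert np.abs(lp - np.array(potts)).max() < 1e-10


class TestGibbs:
    def test_zero_weight_model_samples_softmax_fields(self):
        model = build_tiny_rbm(seed=4)
        model.weights_ = np.zeros_like(model.weights_)
        rng = np.random.default_rng(0)
        v = np.zeros((20_000, 3), dtype=np.int8)
        v = model.gibbs_step(v, rng)
        probs = softmax(model.fields_, axis=1)
        for i in range(3):
            freq = np.bincount(v[:, i], minlength=Q) / v.shape[0]
            se = np.sqrt(probs[i] * (1 - probs[i]) / v.shape[0])
            assert np.all(np.abs(freq - probs[i]) <= 4 * se + 1e-4)

    def test_stationary_distribution_matches_enumeration(self):
        model = build_tiny_rbm(n_columns=2, n_states=2, n_hidden=1, seed=5)
        log_z, states = exact_log_partition(model, 2)
        p = np.exp(model.unnormalized_logp(states) - log_z)
        rng = np.random.default_rng(0)
        n_chains = 4000
        v = rng.integers(0, 2, size=(n_chains, 2)).astype(np.int8)
        for _ in range(400):
            v = model.gibbs_step(v, rng)
        counts = np.bincount(v[:, 0] * 2 + v[:, 1], minlength=4)
        assert chisquare(counts, p * n_chains).pvalue > 0.01

    def test_identical_seed_identical_trajectory(self):
        model = build_tiny_rbm(seed=6)
        v0 = np.zeros((50, 3), dtype=np.int8)
        a = model.gibbs_step(v0.copy(), np.random.default_rng(9))
        b = model.gibbs_step(v0.copy(), np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestLogPartition:
    def test_zero_weight_model_is_exact(self):
        model = build_tiny_rbm(seed=7)
        model.weights_ = np.zeros_like(model.weights_)
        log_z, se = model.estimate_log_partition(n_betas=50, n_repeats=3, random_state=0)
        exact, _ = exact_log_partition(model, 4)
        assert log_z == pytest.approx(exact, abs=1e-9)

    def test_ais_within_three_se_of_enumeration(self):
        model = build_tiny_rbm(seed=8)
        exact, _ = exact_log_partition(model, 4)
        log_z, se = model.estimate_log_partition(
            n_betas=1000, n_repeats=10, n_chains_per_repeat=5, random_state=1
        )
        assert abs(log_z - exact) <= max(3 * se, 0.02)

    def test_variance_shrinks_with_more_temperatures(self):
        model = build_tiny_rbm(seed=9, n_hidden=3)
        model.weights_ *= 2.0  # make the path non-trivial
        spreads = []
        for n_betas in (20, 2000):
            reps = [
                model.estimate_log_partition(n_betas=n_betas, n_repeats=2, random_state=s)[0]
                for s in range(6)
            ]
            spreads.append(np.std(reps))
        assert spreads[1] < spreads[0]

    def test_score_samples_requires_log_partition(self):
        model = build_tiny_rbm(seed=10)
        model.log_partition_ = None
        with pytest.raises(ValueError, match="estimate_log_partition"):
            model.score_samples(["AAA"])

    def test_normalized_scores_sum_to_one(self):
        model = build_tiny_rbm(seed=11)
        exact, states = exact_log_partition(model, 4)
        model.log_partition_ = exact
        assert np.exp(model.score_samples(states)).sum() == pytest.approx(1.0)


class TestTraining:
    def test_single_sequence_fields_only_reproduces_delta(self):
        aln = Alignment(ids=["a"], sequences=["PRIEIT"])
        model = SequenceRBM(
            n_hidden=1, weight_l12=0.0, weight_init_scale=0.0, n_updates=300,
            mc_steps=2, n_chains=20, batch_size=8, random_state=0,
        ).fit(aln)
        probs = softmax(model.fields_, axis=1)
        wt = encode_many(["PRIEIT"])[0]
        assert np.all(probs[np.arange(6), wt] > 0.95)

    def test_two_block_data_separated_by_hidden_unit(self):
        aln, labels = make_mfa(
            n_records=300, n_columns=12, n_genes=2, conservation=0.7, seed=0
        )
        model = SequenceRBM(
            n_hidden=4, weight_l12=0.01, n_updates=500, mc_steps=5, n_chains=50,
            random_state=0,
        ).fit(aln, sample_weight=sequence_weights(aln))
        I = model.hidden_input(aln)
        y = (labels["gene"] == "gene0").to_numpy()
        best_auc = max(
            max(roc_auc_score(y, I[:, mu]), roc_auc_score(y, -I[:, mu]))
            for mu in range(model.n_hidden)
        )
        assert best_auc > 0.9

    def test_sparsity_penalty_shrinks_weights(self):
        aln, _ = make_mfa(n_records=200, n_columns=10, n_genes=2, seed=1)
        w = sequence_weights(aln)
        common = dict(n_hidden=3, n_updates=400, mc_steps=3, n_chains=30, random_state=0)
        loose = SequenceRBM(weight_l12=0.0, **common).fit(aln, sample_weight=w)
        tight = SequenceRBM(weight_l12=0.5, **common).fit(aln, sample_weight=w)
        assert np.abs(tight.weights_).mean() < np.abs(loose.weights_).mean()

    def test_training_log_recorded(self):
        aln, _ = make_mfa(n_records=100, n_columns=8, n_genes=1, seed=2)
        model = SequenceRBM(
            n_hidden=2, n_updates=120, mc_steps=2, n_chains=20, random_state=0
        ).fit(aln)
        assert {"update", "lr", "step_norm"} <= set(model.training_log_.columns)
        assert model.training_log_["update"].iloc[-1] == 119


class TestInterpretation:
    def test_landscape_wild_type_entries_zero(self, tiny_rbm):
        grid = tiny_rbm.mutational_landscape("ACD")
        wt = encode_many(["ACD"])[0]
        assert np.allclose(grid[np.arange(3), wt], 0.0)

    def test_landscape_independent_model_closed_form(self):
        model = build_tiny_rbm(seed=12)
        model.weights_ = np.zeros_like(model.weights_)
        grid = model.mutational_landscape("ACD")
        wt = encode_many(["ACD"])[0]
        expected = model.fields_ - model.fields_[np.arange(3), wt][:, None]
        assert np.allclose(grid[:, :4], expected[:, :4])

    def test_landscape_agrees_with_sequencewise_differences(self, tiny_rbm):
        wt = "ACD"
        grid = tiny_rbm.mutational_landscape(wt)
        base = tiny_rbm.unnormalized_logp([wt])[0]
        direct = np.zeros((3, 4))
        for i in range(3):
            for a in range(4):
                mutant = wt[:i] + ALPHABET[a] + wt[i + 1 :]
                direct[i, a] = tiny_rbm.unnormalized_logp([mutant])[0] - base
        assert np.allclose(grid[:, :4], direct, atol=1e-10)
        rho = spearmanr(grid[:, :4].ravel(), direct.ravel()).statistic
        assert rho == pytest.approx(1.0)

    def test_couplings_zero_for_independent_model(self):
        model = build_tiny_rbm(seed=13)
        model.weights_ = np.zeros_like(model.weights_)
        J = model.effective_couplings(["AAA", "ACD"])
        assert np.allclose(J, 0.0)

    def test_couplings_quadratic_closed_form(self):
        model = build_tiny_rbm(seed=14, quadratic=1.3)
        J = model.effective_couplings(["AAA", "ACD", "DDC"])
        W = model.weights_
        expected = np.einsum("mia,mjb->ijab", W, W) / 1.3
        idx = np.arange(3)
        expected[idx, idx] = 0.0
        assert np.allclose(J, expected, atol=1e-12)

    def test_planted_coupled_pair_top_ranked(self):
        aln, _ = make_mfa(
            n_records=800, n_columns=12, n_genes=1, conservation=0.4,
            motif_conservation=0.4, coupling_pairs=[(2, 8)], coupling_strength=0.8,
            floor_total=0.0, seed=0,
        )
        model = SequenceRBM(
            n_hidden=6, weight_l12=0.01, n_updates=2500, mc_steps=5, n_chains=50,
            random_state=0,
        ).fit(aln, sample_weight=sequence_weights(aln))
        F = frobenius_couplings(model.effective_couplings(aln))
        i, j = np.unravel_index(np.argmax(F), F.shape)
        assert {int(i), int(j)} == {2, 8}

    def test_participation_single_site(self):
        model = build_tiny_rbm(seed=15, n_hidden=1)
        model.weights_ = np.zeros_like(model.weights_)
        model.weights_[0, 1, :3] = [1.0, -2.0, 0.5]
        assert model.participation_fractions()[0] == pytest.approx(1 / 3)

    def test_participation_uniform_sites(self):
        model = build_tiny_rbm(seed=16, n_hidden=1)
        model.weights_ = np.ones_like(model.weights_)
        assert model.participation_fractions()[0] == pytest.approx(1.0)

    def test_participation_zero_unit(self):
        model = build_tiny_rbm(seed=17, n_hidden=2)
        model.weights_[0] = 0.0
        assert model.participation_fractions()[0] == 0.0


class TestSamplingAndRecovery:
    def test_low_temperature_raises_mean_score(self):
        generator = build_tiny_rbm(seed=18)
        cold = generator.sample(400, beta=2.0, burn_in=100, thin=2, random_state=0)
        warm = generator.sample(400, beta=1.0, burn_in=100, thin=2, random_state=1)
        assert generator.unnormalized_logp(cold).mean() > generator.unnormalized_logp(warm).mean()

    def test_parameter_recovery_from_generated_samples(self):
        """A model retrained on samples of a known generator should come
        close to the generator's held-out likelihood."""
        generator = build_tiny_rbm(seed=19)
        train = generator.sample(800, burn_in=200, thin=2, random_state=0)
        heldout = generator.sample(300, burn_in=200, thin=2, random_state=1)
        student = SequenceRBM(
            n_hidden=2, weight_l12=0.01, n_updates=1200, mc_steps=5, n_chains=50,
            batch_size=100, random_state=0,
        ).fit(train)
        exact_student, states = exact_log_partition(student, 21)
        student.log_partition_ = exact_student
        exact_gen, _ = exact_log_partition(generator, 4)
        generator.log_partition_ = exact_gen
        oracle = generator.score_samples(heldout, per_site=True).mean()
        learned = student.score_samples(heldout, per_site=True).mean()
        assert learned >= oracle - 0.15

    def test_save_load_roundtrip(self, tmp_path, tiny_rbm):
        tiny_rbm.log_partition_ = 1.234
        tiny_rbm.save(tmp_path / "model.npz")
        again = SequenceRBM.load(tmp_path / "model.npz")
        states = enumerate_states(3, 4)
        assert np.allclose(again.unnormalized_logp(states), tiny_rbm.unnormalized_logp(states))
        assert again.log_partition_ == pytest.approx(1.234)
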