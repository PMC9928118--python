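"""Compositional Restricted Boltzmann Machine over gapped peptide sequences.

The model assigns to a sequence S = (s_1 .. s_N), s_i in the 21-letter gapped
alphabet, the probability

    P(S) = (1/Z) exp[ sum_i g_i(s_i) + sum_mu Gamma_mu( I_mu(S) ) ],
    I_mu(S) = sum_i w_{i mu}(s_i),

where g are site-specific fields, w a sparse M x N x 21 weight tensor whose
slices act as recombinable sequence motifs, and Gamma_mu strictly convex
dReLU potentials (see :mod:`pepfunnel.potentials`). Training maximizes the
reweighted data log-likelihood, with an L1^2 sparsity penalty
(lambda_12 / 2) * sum_mu (sum_{i,a} |w_{i mu}(a)|)^2 on the weights and an L2
penalty of strength 1e-2 * lambda_12 on the fields, by persistent
contrastive divergence with ADAM. The partition function is estimated by
annealed importance sampling from the fields-only base model along a path
that scales only the weight tensor.

Interpretation utilities: single-mutant landscapes (Z cancels), effective
epistatic couplings J_ij(a,b) = sum_mu w_{i mu}(a) w_{j mu}(b)
<Gamma''_mu(I_mu)>_data, and per-unit participation fractions measuring how
many sites carry each motif.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .alignment import Alignment
from .alphabet import Q, decode, encode_many, one_hot
from .potentials import DReLU

__all__ = ["SequenceRBM", "zero_sum_gauge", "frobenius_couplings"]

LOG10E = np.log10(np.e)


def _as_codes(X) -> np.ndarray:
    if isinstance(X, Alignment):
        return X.codes()
    if isinstance(X, np.ndarray) and X.ndim == 2 and X.dtype != object:
        return X.astype(np.int8)
    if isinstance(X, str):
        return encode_many([X])
    return encode_many(X)


def zero_sum_gauge(J: np.ndarray) -> np.ndarray:
    """Apply the zero-sum gauge to an (N, N, q, q) coupling tensor."""
    J = J - J.mean(axis=2, keepdims=True)
    J = J - J.mean(axis=3, keepdims=True)
    return J


def frobenius_couplings(J: np.ndarray) -> np.ndarray:
    """Per-pair Frobenius norms of a zero-sum-gauged coupling tensor,
    diagonal excluded."""
    Jg = zero_sum_gauge(J)
    norms = np.sqrt((Jg**2).sum(axis=(2, 3)))
    np.fill_diagonal(norms, 0.0)
    return norms


class SequenceRBM(BaseEstimator):
    """dReLU restricted Boltzmann machine trained by PCD.

    Parameters mirror the training configuration: ``n_hidden`` (M),
    ``weight_l12`` (lambda_12, the L1^2 sparsity strength; the field L2
    strength is ``1e-2 * weight_l12``), minibatch size, number of persistent
    chains, Gibbs sweeps per gradient (``mc_steps``), number of gradient
    updates, and the ADAM schedule (learning rate decaying exponentially from
    ``learning_rate`` to ``lr_final`` over the second half of training).
    """

    def __init__(
        self,
        n_hidden: int = 30,
        weight_l12: float = 0.25,
        n_updates: int = 20000,
        batch_size: int = 100,
        n_chains: int = 100,
        mc_steps: int = 20,
        learning_rate: float = 1e-3,
        lr_final: float = 1e-5,
        adam_beta1: float = 0.0,
        adam_beta2: float = 0.99,
        adam_eps: float = 1e-3,
        gamma_min: float = 0.05,
        weight_init_scale: float = 0.3,
        random_state: int | None = None,
    ):
        self.n_hidden = n_hidden
        self.weight_l12 = weight_l12
        self.n_updates = n_updates
        self.batch_size = batch_size
        self.n_chains = n_chains
        self.mc_steps = mc_steps
        self.learning_rate = learning_rate
        self.lr_final = lr_final
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.adam_eps = adam_eps
        self.gamma_min = gamma_min
        self.weight_init_scale = weight_init_scale
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    # energy and conditionals
    # ------------------------------------------------------------------ #

    def _require_fit(self):
        check_is_fitted(self, "fields_")

    def hidden_input(self, X, beta: float = 1.0) -> np.ndarray:
        """Motif-matching scores I_mu(S) for a batch: (n, M)."""
        self._require_fit()
        return self._hidden_input_fast(_as_codes(X), beta=beta)

    def _hidden_input_fast(self, codes: np.ndarray, beta: float = 1.0) -> np.ndarray:
        W = self.weights_
        N = codes.shape[1]
        # (n, N) gather per hidden unit via advanced indexing: (M, n)
        out = W[:, np.arange(N)[None, :], codes].sum(axis=2)  # (M, n)
        return beta * out.T

    def unnormalized_logp(self, X, beta: float = 1.0) -> np.ndarray:
        """sum_i g_i(s_i) + sum_mu Gamma_mu(I_mu(S)), batched.

        With ``beta`` != 1, fields and weights are scaled (low-temperature
        tilting); the dReLU shape parameters are untouched.
        """
        self._require_fit()
        codes = _as_codes(X)
        if codes.shape[1] != self.n_columns_:
            raise ValueError("sequence length does not match the model")
        N = codes.shape[1]
        field_term = beta * self.fields_[np.arange(N), codes].sum(axis=1)
        I = self._hidden_input_fast(codes, beta=beta)
        return field_term + self.potential_.gamma(I).sum(axis=1)

    def score_samples(self, X, per_site: bool = False) -> np.ndarray:
        """Normalized log-probability; requires an estimated log-partition."""
        if getattr(self, "log_partition_", None) is None:
            raise ValueError(
                "log partition not available: call estimate_log_partition() first"
            )
        scores = self.unnormalized_logp(X) - self.log_partition_
        return scores / self.n_columns_ if per_site else scores

    def score(self, X, y=None, sample_weight=None) -> float:
        return float(np.average(self.score_samples(X), weights=sample_weight))

    def _sample_visible_given_hidden(
        self, h: np.ndarray, rng: np.random.Generator, beta: float = 1.0
    ) -> np.ndarray:
        # logits: (n, N, Q) = beta * (g + h . w)
        logits = beta * (self.fields_[None, :, :] + np.einsum("nm,mia->nia", h, self.weights_))
        logits -= logits.max(axis=2, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=2, keepdims=True)
        cumulative = probs.cumsum(axis=2)
        u = rng.random(cumulative.shape[:2])
        return (u[:, :, None] > cumulative).sum(axis=2).astype(np.int8)

    def gibbs_step(
        self, codes: np.ndarray, rng: np.random.Generator, beta: float = 1.0
    ) -> np.ndarray:
        """One alternate-Gibbs sweep (hidden then visible) on a batch."""
        self._require_fit()
        I = self._hidden_input_fast(codes, beta=beta)
        h = self.potential_.sample(I, rng)
        return self._sample_visible_given_hidden(h, rng, beta=beta)

    # ------------------------------------------------------------------ #
    # training
    # ------------------------------------------------------------------ #

    def _init_parameters(self, codes: np.ndarray, sample_weight: np.ndarray, rng):
        N = codes.shape[1]
        M = self.n_hidden
        counts = np.zeros((N, Q))
        for i in range(N):
            np.add.at(counts[i], codes[:, i], sample_weight)
        freqs = (counts + 1e-4) / (counts + 1e-4).sum(axis=1, keepdims=True)
        self.fields_ = np.log(freqs)
        self.fields_ -= self.fields_.mean(axis=1, keepdims=True)
        self.weights_ = rng.normal(0.0, self.weight_init_scale / np.sqrt(N), size=(M, N, Q))
        self.potential_ = DReLU.initial(M)
        self.n_columns_ = N

    def _moment_dict(self):
        return {
            "fields": np.zeros_like(self.fields_),
            "weights": np.zeros_like(self.weights_),
            "theta_p": np.zeros(self.n_hidden),
            "theta_m": np.zeros(self.n_hidden),
            "gamma_p": np.zeros(self.n_hidden),
            "gamma_m": np.zeros(self.n_hidden),
        }

    def _statistics(self, codes: np.ndarray, weights: np.ndarray):
        """Weighted data-side (or chain-side) sufficient statistics."""
        n, N = codes.shape
        w_norm = weights / weights.sum()
        onehot = one_hot(codes)  # (n, N, Q)
        visible = np.einsum("n,nia->ia", w_norm, onehot)
        I = self._hidden_input_fast(codes)  # (n, M)
        gprime = self.potential_.mean(I)  # (n, M)
        coupling = np.einsum("n,nm,nia->mia", w_norm, gprime, onehot)
        d_tp, d_tm, d_gp, d_gm = self.potential_.parameter_gradients(I)
        hidden = {
            "theta_p": w_norm @ d_tp,
            "theta_m": w_norm @ d_tm,
            "gamma_p": w_norm @ d_gp,
            "gamma_m": w_norm @ d_gm,
        }
        return visible, coupling, hidden

    def fit(self, X, y=None, sample_weight=None):
        """Train by persistent contrastive divergence on a (weighted)
        alignment; X may be an Alignment, a list of sequences or a code
        matrix."""
        codes = _as_codes(X)
        n, N = codes.shape
        if n == 0:
            raise ValueError("empty training data")
        if sample_weight is None:
            sample_weight = np.ones(n)
        sample_weight = np.asarray(sample_weight, dtype=float)
        rng = np.random.default_rng(self.random_state)
        self._init_parameters(codes, sample_weight, rng)

        chains = codes[rng.integers(0, n, size=self.n_chains)].copy()
        m1 = self._moment_dict()
        m2 = self._moment_dict()
        b1, b2 = self.adam_beta1, self.adam_beta2
        log_rows = []
        p_select = sample_weight / sample_weight.sum()
        half = self.n_updates // 2
        for t in range(self.n_updates):
            batch_idx = rng.choice(n, size=min(self.batch_size, n), p=p_select)
            batch = codes[batch_idx]
            batch_w = np.ones(batch.shape[0])
            pos_visible, pos_coupling, pos_hidden = self._statistics(batch, batch_w)
            for _ in range(self.mc_steps):
                chains = self.gibbs_step(chains, rng)
            neg_visible, neg_coupling, neg_hidden = self._statistics(
                chains, np.ones(self.n_chains)
            )

            l12 = self.weight_l12
            abs_sums = np.abs(self.weights_).sum(axis=(1, 2))  # per hidden unit
            grad = {
                "fields": pos_visible - neg_visible - 1e-2 * l12 * self.fields_,
                "weights": pos_coupling
                - neg_coupling
                - l12 * abs_sums[:, None, None] * np.sign(self.weights_),
                "theta_p": pos_hidden["theta_p"] - neg_hidden["theta_p"],
                "theta_m": pos_hidden["theta_m"] - neg_hidden["theta_m"],
                "gamma_p": pos_hidden["gamma_p"] - neg_hidden["gamma_p"],
                "gamma_m": pos_hidden["gamma_m"] - neg_hidden["gamma_m"],
            }
            for key, g_val in grad.items():
                if not np.all(np.isfinite(g_val)):
                    raise FloatingPointError(
                        f"non-finite gradient for {key} at update {t}; training diverged"
                    )

            if t < half:
                lr = self.learning_rate
            else:
                frac = (t - half) / max(1, self.n_updates - half)
                lr = self.learning_rate * (self.lr_final / self.learning_rate) ** frac
            step_norm = 0.0
            for key in grad:
                m1[key] = b1 * m1[key] + (1 - b1) * grad[key]
                m2[key] = b2 * m2[key] + (1 - b2) * grad[key] ** 2
                m1_hat = m1[key] / (1 - b1 ** (t + 1)) if b1 > 0 else m1[key]
                m2_hat = m2[key] / (1 - b2 ** (t + 1))
                step = lr * m1_hat / (np.sqrt(m2_hat) + self.adam_eps)
                step_norm += float((step**2).sum())
                if key == "fields":
                    self.fields_ += step
                elif key == "weights":
                    self.weights_ += step
                elif key == "theta_p":
                    self.potential_.theta_plus += step
                elif key == "theta_m":
                    self.potential_.theta_minus += step
                elif key == "gamma_p":
                    self.potential_.gamma_plus = np.maximum(
                        self.potential_.gamma_plus + step, self.gamma_min
                    )
                elif key == "gamma_m":
                    self.potential_.gamma_minus = np.maximum(
                        self.potential_.gamma_minus + step, self.gamma_min
                    )
            if t % max(1, self.n_updates // 50) == 0 or t == self.n_updates - 1:
                log_rows.append(
                    {
                        "update": t,
                        "lr": lr,
                        "step_norm": np.sqrt(step_norm),
                        "mean_abs_weight": float(np.abs(self.weights_).mean()),
                    }
                )
        self.training_log_ = pd.DataFrame(log_rows)
        self.chains_ = chains
        self.log_partition_ = None
        self.log_partition_se_ = None
        return self

    # ------------------------------------------------------------------ #
    # partition function, sampling, likelihood
    # ------------------------------------------------------------------ #

    def base_log_partition(self) -> float:
        """Closed-form log Z of the fields-only base model (weights zeroed):
        sum_i log sum_a exp(g_i(a)) plus the analytic hidden-unit integrals
        Gamma_mu(0)."""
        self._require_fit()
        fields_part = logsumexp(self.fields_, axis=1).sum()
        hidden_part = self.potential_.gamma(np.zeros(self.n_hidden)).sum()
        return float(fields_part + hidden_part)

    def estimate_log_partition(
        self,
        n_betas: int = 10_000,
        n_repeats: int = 10,
        n_chains_per_repeat: int = 1,
        random_state=None,
    ) -> tuple[float, float]:
        """Annealed importance sampling estimate of log Z.

        The path scales only the weight tensor: p_beta(S) propto
        exp(sum g + sum_mu Gamma_mu(beta * I_mu)), beta on a linear grid from
        0 to 1. Chains start as exact samples of the fields-only base model.
        Returns (logZ, standard error over repeats) and stores them on the
        estimator.
        """
        self._require_fit()
        rng = np.random.default_rng(random_state)
        n_total = n_repeats * n_chains_per_repeat
        # exact base samples: independent softmax(g) columns
        probs = softmax(self.fields_, axis=1)
        cumulative = probs.cumsum(axis=1)
        u = rng.random((n_total, self.n_columns_))
        v = (u[:, :, None] > cumulative[None, :, :]).sum(axis=2).astype(np.int8)

        betas = np.linspace(0.0, 1.0, n_betas)
        log_w = np.zeros(n_total)
        I = self._hidden_input_fast(v)
        for b_prev, b_next in zip(betas[:-1], betas[1:]):
            log_w += (
                self.potential_.gamma(b_next * I).sum(axis=1)
                - self.potential_.gamma(b_prev * I).sum(axis=1)
            )
            v = self._gibbs_step_scaled_weights(v, b_next, rng)
            I = self._hidden_input_fast(v)
        log_w += self.base_log_partition()
        per_repeat = log_w.reshape(n_repeats, n_chains_per_repeat)
        estimates = logsumexp(per_repeat, axis=1) - np.log(n_chains_per_repeat)
        log_z = float(logsumexp(log_w) - np.log(n_total))
        se = float(np.std(estimates, ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else np.inf
        self.log_partition_ = log_z
        self.log_partition_se_ = se
        return log_z, se

    def _gibbs_step_scaled_weights(self, codes, beta_w, rng):
        """Gibbs transition for the AIS intermediate model (weights scaled by
        beta_w, fields kept at full strength)."""
        I = self._hidden_input_fast(codes) * beta_w
        h = self.potential_.sample(I, rng)
        logits = self.fields_[None, :, :] + beta_w * np.einsum(
            "nm,mia->nia", h, self.weights_
        )
        logits -= logits.max(axis=2, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=2, keepdims=True)
        u = rng.random(probs.shape[:2])
        return (u[:, :, None] > probs.cumsum(axis=2)).sum(axis=2).astype(np.int8)

    def sample(
        self,
        n: int,
        beta: float = 1.0,
        burn_in: int = 500,
        thin: int = 10,
        n_parallel: int | None = None,
        random_state=None,
    ) -> list[str]:
        """Gibbs-sample sequences from the (beta-tilted) model.

        ``beta > 1`` is low-temperature sampling: fields and weights are
        scaled by beta, concentrating the distribution on high-probability
        sequences.
        """
        self._require_fit()
        if beta <= 0:
            raise ValueError("beta must be positive")
        rng = np.random.default_rng(random_state)
        if n_parallel is None:
            n_parallel = min(n, 100)
        probs = softmax(beta * self.fields_, axis=1)
        u = rng.random((n_parallel, self.n_columns_))
        v = (u[:, :, None] > probs.cumsum(axis=1)[None, :, :]).sum(axis=2).astype(np.int8)
        for _ in range(burn_in):
            v = self.gibbs_step(v, rng, beta=beta)
        collected = []
        while len(collected) < n:
            for _ in range(thin):
                v = self.gibbs_step(v, rng, beta=beta)
            collected.extend(decode(row) for row in v)
        return collected[:n]

    def entropy_log10(self, n_samples: int = 2000, random_state=None, **sample_kwargs) -> float:
        """Model entropy H = log Z - <unnormalized log p>, in log10 units.

        Monte Carlo over model samples; requires an estimated log partition.
        """
        if getattr(self, "log_partition_", None) is None:
            raise ValueError("call estimate_log_partition() first")
        seqs = self.sample(n_samples, random_state=random_state, **sample_kwargs)
        h_nats = self.log_partition_ - float(np.mean(self.unnormalized_logp(seqs)))
        return max(0.0, h_nats) * LOG10E

    def save(self, path) -> None:
        """Serialize parameters (and the log-partition estimate if present)
        to a single .npz archive."""
        self._require_fit()
        np.savez(
            path,
            fields=self.fields_,
            weights=self.weights_,
            gamma_plus=self.potential_.gamma_plus,
            gamma_minus=self.potential_.gamma_minus,
            theta_plus=self.potential_.theta_plus,
            theta_minus=self.potential_.theta_minus,
            log_partition=np.array(
                [np.nan if self.log_partition_ is None else self.log_partition_]
            ),
        )

    @classmethod
    def load(cls, path) -> "SequenceRBM":
        data = np.load(path)
        model = cls(n_hidden=data["weights"].shape[0])
        model.fields_ = data["fields"]
        model.weights_ = data["weights"]
        model.potential_ = DReLU(
            gamma_plus=data["gamma_plus"],
            gamma_minus=data["gamma_minus"],
            theta_plus=data["theta_plus"],
            theta_minus=data["theta_minus"],
        )
        model.n_columns_ = model.fields_.shape[0]
        logz = float(data["log_partition"][0])
        model.log_partition_ = None if np.isnan(logz) else logz
        model.log_partition_se_ = None
        return model

    # ------------------------------------------------------------------ #
    # interpretation
    # ------------------------------------------------------------------ #

    def mutational_landscape(self, wild_type: str) -> np.ndarray:
        """(N, 21) matrix of Delta log P for all single mutants of the
        wild type (zeros at wild-type entries; Z cancels)."""
        self._require_fit()
        codes = _as_codes(wild_type)[0]
        N = self.n_columns_
        I0 = self._hidden_input_fast(codes[None, :])[0]  # (M,)
        gamma0 = self.potential_.gamma(I0).sum()
        # delta inputs for mutating site i to a: (N, Q, M)
        wt_w = self.weights_[:, np.arange(N), codes].T  # (N, M)
        delta_I = self.weights_.transpose(1, 2, 0) - wt_w[:, None, :]
        gamma_mut = self.potential_.gamma(I0[None, None, :] + delta_I).sum(axis=2)
        field_delta = self.fields_ - self.fields_[np.arange(N), codes][:, None]
        return field_delta + gamma_mut - gamma0

    def effective_couplings(self, X) -> np.ndarray:
        """Data-averaged effective epistatic couplings
        J_ij(a,b) = sum_mu w_imu(a) w_jmu(b) <Gamma''_mu(I_mu)>_data."""
        self._require_fit()
        codes = _as_codes(X)
        I = self._hidden_input_fast(codes)
        curvature = self.potential_.variance(I).mean(axis=0)  # (M,)
        J = np.einsum("m,mia,mjb->ijab", curvature, self.weights_, self.weights_)
        idx = np.arange(self.n_columns_)
        J[idx, idx] = 0.0
        return J

    def participation_fractions(self) -> np.ndarray:
        """Per-hidden-unit participation fraction
        p_mu = (sum_{i,a} w^2)^2 / (N * sum_i (sum_a w^2)^2); all-zero units
        get 0. The mean over units is the motif-sparsity summary."""
        self._require_fit()
        per_site = (self.weights_**2).sum(axis=2)  # (M, N)
        total = per_site.sum(axis=1)
        denom = self.n_columns_ * (per_site**2).sum(axis=1)
        out = np.zeros(self.n_hidden)
        nz = denom > 0
        out[nz] = total[nz] ** 2 / denom[nz]
        return out
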