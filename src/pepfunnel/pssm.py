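"""Independent (per-column) baseline sequence model.

A position-specific scoring matrix factorizes the sequence distribution over
columns: P(S) = prod_i P_i(s_i). It is the natural null model against which
the RBM's coupling terms are judged, and its entropy gives a closed-form
estimate of the effective sequence-space size, reported as a base-10
exponent (space size = 10^H).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .alignment import Alignment, profile_matrix, sequence_weights
from .alphabet import ALPHABET, Q, decode, encode_many

__all__ = ["PSSM", "fit_pssm", "select_pssm_pseudocount"]

LOG10E = np.log10(np.e)


def _as_codes(X) -> np.ndarray:
    if isinstance(X, Alignment):
        return X.codes()
    if isinstance(X, np.ndarray) and X.dtype != object and X.ndim == 2:
        return X.astype(np.int8)
    if isinstance(X, str):
        return encode_many([X])
    return encode_many(X)


class PSSM(BaseEstimator):
    """Per-column categorical model with pseudocount smoothing.

    Parameters
    ----------
    pseudocount : float
        Added to every weighted (column, symbol) count before normalization.

    Attributes
    ----------
    log_probs_ : ndarray of shape (N, 21)
        Column log-probabilities; each row's probabilities sum to one.
    """

    def __init__(self, pseudocount: float = 1e-2):
        self.pseudocount = pseudocount

    def fit(self, X, y=None, sample_weight=None):
        codes = _as_codes(X)
        if isinstance(X, Alignment):
            aln = X
        else:
            aln = None
        if sample_weight is None:
            sample_weight = np.ones(codes.shape[0])
        sample_weight = np.asarray(sample_weight, dtype=float)
        counts = np.zeros((codes.shape[1], Q))
        for i in range(codes.shape[1]):
            np.add.at(counts[i], codes[:, i], sample_weight)
        counts += self.pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            self.log_probs_ = np.log(probs)
        self.n_columns_ = codes.shape[1]
        return self

    @classmethod
    def from_log_probs(cls, log_probs: np.ndarray) -> "PSSM":
        model = cls()
        model.log_probs_ = np.asarray(log_probs, dtype=float)
        model.n_columns_ = model.log_probs_.shape[0]
        return model

    @classmethod
    def uniform(cls, n_columns: int, include_gap: bool = False) -> "PSSM":
        """Uniform model over the 20 residues (or all 21 symbols)."""
        probs = np.full((n_columns, Q), 0.0)
        n_symbols = Q if include_gap else Q - 1
        probs[:, :n_symbols] = 1.0 / n_symbols
        with np.errstate(divide="ignore"):
            return cls.from_log_probs(np.log(probs))

    def _tilted_probs(self, beta: float) -> np.ndarray:
        if beta <= 0:
            raise ValueError("beta must be positive")
        logp = beta * self.log_probs_
        logp -= logp.max(axis=1, keepdims=True)
        probs = np.exp(logp)
        return probs / probs.sum(axis=1, keepdims=True)

    def score_samples(self, X, per_site: bool = False) -> np.ndarray:
        """Log-probability of each sequence (optionally divided by length)."""
        check_is_fitted(self, "log_probs_")
        codes = _as_codes(X)
        if codes.shape[1] != self.n_columns_:
            raise ValueError("sequence length does not match the model")
        scores = self.log_probs_[np.arange(self.n_columns_), codes].sum(axis=1)
        return scores / self.n_columns_ if per_site else scores

    def score(self, X, y=None, sample_weight=None) -> float:
        return float(np.average(self.score_samples(X), weights=sample_weight))

    def sample(self, n: int, beta: float = 1.0, random_state=None) -> list[str]:
        """Draw i.i.d. sequences, columns tilted to P_i^beta (renormalized)."""
        check_is_fitted(self, "log_probs_")
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(random_state)
        probs = self._tilted_probs(beta)
        cumulative = probs.cumsum(axis=1)
        u = rng.random((n, self.n_columns_))
        codes = (u[:, :, None] > cumulative[None, :, :]).sum(axis=2)
        return [decode(row) for row in codes]

    def entropy_log10(self, beta: float = 1.0) -> float:
        """Total column entropy of the (beta-tilted) model, in log10 units.

        The effective number of sequences under the model is 10**entropy.
        """
        check_is_fitted(self, "log_probs_")
        probs = self._tilted_probs(beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(probs > 0, probs * np.log(probs), 0.0)
        return float(-terms.sum() * LOG10E)

    def save(self, path) -> None:
        path = Path(path)
        header = {"alphabet": ALPHABET, "n_columns": self.n_columns_}
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            np.savetxt(fh, self.log_probs_)

    @classmethod
    def load(cls, path) -> "PSSM":
        return cls.from_log_probs(np.loadtxt(path, comments="#"))


def fit_pssm(aln: Alignment, weights=None, pseudocount: float = 1e-2) -> PSSM:
    if weights is None:
        weights = sequence_weights(aln)
    return PSSM(pseudocount=pseudocount).fit(aln, sample_weight=weights)


def select_pssm_pseudocount(
    train: Alignment,
    validation: Alignment,
    train_weights=None,
    grid=None,
) -> tuple[PSSM, float]:
    """Grid-search the pseudocount by held-out log-likelihood.

    The default grid is {1e-3 ... 1} times the effective (weighted) sequence
    count of the training alignment.
    """
    if train_weights is None:
        train_weights = sequence_weights(train)
    effective = float(np.sum(train_weights))
    if grid is None:
        grid = np.logspace(-3, 0, 7) * effective
    best_model, best_pc, best_score = None, None, -np.inf
    for pc in grid:
        model = PSSM(pseudocount=float(pc)).fit(train, sample_weight=train_weights)
        score = model.score(validation)
        if score > best_score:
            best_model, best_pc, best_score = model, float(pc), score
    return best_model, best_pc
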