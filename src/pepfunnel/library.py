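"""Candidate peptide panel assembly and designable-space sizing.

The panel mixes RBM samples (regular and low-temperature), PSSM samples,
uniform-random negatives, natural cluster representatives of the training
alignment, and user-supplied positive controls. RBM sample pools are reduced
to diverse representatives by single-linkage clustering, keeping the
highest-likelihood member per cluster; every entry is scored by the same RBM
and annotated with its nearest natural sequence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .alignment import Alignment, cluster_representatives
from .alphabet import ALPHABET, encode_many
from .pssm import PSSM
from .rbm import SequenceRBM

__all__ = ["build_library", "estimate_space_size", "POSITIVE_CONTROLS"]

#: High-affinity synthetic binders of the calcineurin PxIxIT site used as
#: on-chip positive controls.
POSITIVE_CONTROLS = {
    "PVIVIT": "MAGPHPVIVITGPHEE",
    "PKIVIT": "MAGPHPKIVITGPHEE",
}

_DEFAULT_COUNTS = {
    "crbm": 180,
    "crbm_lowT": 361,
    "pssm": 72,
    "random": 36,
    "natural": 70,
}


def _closest_natural(sequences: list[str], mfa: Alignment) -> tuple[list[str], np.ndarray]:
    codes = encode_many(sequences)
    nat = mfa.codes()
    ids, dists = [], np.empty(len(sequences), dtype=int)
    for k, row in enumerate(codes):
        d = (nat != row).sum(axis=1)
        best = int(np.argmin(d))
        ids.append(mfa.ids[best])
        dists[k] = int(d[best])
    return ids, dists


def _reduce_pool(
    pool: list[str], model: SequenceRBM, n_keep: int, cluster_cut: float
) -> list[str]:
    pool = list(dict.fromkeys(pool))  # dedupe, order-preserving
    aln = Alignment(ids=[f"s{k}" for k in range(len(pool))], sequences=pool)
    scores = model.unnormalized_logp(aln)
    reps = cluster_representatives(aln, cluster_cut, scores)
    if len(reps) < n_keep:
        warnings.warn(
            f"requested {n_keep} sequences but only {len(reps)} distinct clusters"
        )
    rep_scores = {rid: scores[aln.ids.index(rid)] for rid in reps}
    ordered = sorted(reps, key=lambda rid: -rep_scores[rid])[:n_keep]
    index = {rid: k for k, rid in enumerate(aln.ids)}
    return [pool[index[rid]] for rid in ordered]


def build_library(
    model: SequenceRBM,
    pssm: PSSM,
    mfa: Alignment,
    counts: dict | None = None,
    beta_low_t: float = 2.0,
    cluster_cut: float = 2,
    n_pool: int = 10_000,
    positive_controls: dict | None = None,
    extra_natural: dict | None = None,
    seed: int = 0,
    burn_in: int = 200,
    thin: int = 5,
) -> pd.DataFrame:
    """Assemble the scored candidate panel.

    Returns a frame with columns sequence, source, loglik_per_site (by the
    shared RBM, unnormalized), closest_natural and hamming_to_natural.
    """
    counts = {**_DEFAULT_COUNTS, **(counts or {})}
    if positive_controls is None:
        positive_controls = POSITIVE_CONTROLS
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str]] = []

    pool_regular = model.sample(
        n_pool, beta=1.0, burn_in=burn_in, thin=thin, random_state=rng.integers(2**31)
    )
    pool_low_t = model.sample(
        n_pool, beta=beta_low_t, burn_in=burn_in, thin=thin,
        random_state=rng.integers(2**31),
    )
    for seq in _reduce_pool(pool_regular, model, counts["crbm"], cluster_cut):
        entries.append((seq, "crbm"))
    for seq in _reduce_pool(pool_low_t, model, counts["crbm_lowT"], cluster_cut):
        entries.append((seq, "crbm_lowT"))
    for seq in pssm.sample(counts["pssm"], random_state=rng.integers(2**31)):
        entries.append((seq, "pssm"))

    residues = ALPHABET[:-1]  # gap-free negatives
    for _ in range(counts["random"]):
        seq = "".join(rng.choice(list(residues), size=mfa.n_columns))
        entries.append((seq, "random"))

    nat_scores = model.unnormalized_logp(mfa)
    reps = cluster_representatives(mfa, cluster_cut, nat_scores)
    rep_scores = sorted(reps, key=lambda rid: -nat_scores[mfa.ids.index(rid)])
    for rid in rep_scores[: counts["natural"]]:
        entries.append((mfa.sequences[mfa.ids.index(rid)], "natural"))
    for name, seq in (extra_natural or {}).items():
        entries.append((seq, "natural"))
    for name, seq in positive_controls.items():
        entries.append((seq, "positive_control"))

    # uniqueness across the whole panel, first source wins
    seen, rows = set(), []
    for seq, source in entries:
        if seq in seen:
            continue
        seen.add(seq)
        rows.append({"sequence": seq, "source": source})
    frame = pd.DataFrame(rows)
    frame["loglik_per_site"] = (
        model.unnormalized_logp(frame["sequence"].tolist()) / mfa.n_columns
    )
    closest, dist = _closest_natural(frame["sequence"].tolist(), mfa)
    frame["closest_natural"] = closest
    frame["hamming_to_natural"] = dist
    return frame


def estimate_space_size(
    model,
    beta: float = 1.0,
    n_samples: int = 2000,
    random_state=None,
) -> float:
    """Effective sequence-space size of a model, as a base-10 exponent.

    Exact column-entropy sum for a PSSM; for an RBM, the Monte Carlo entropy
    H = log Z - <unnormalized log p> over model samples (the tilted model for
    beta != 1 is handled by rescaling fields and weights).
    """
    if isinstance(model, PSSM):
        return model.entropy_log10(beta=beta)
    if isinstance(model, SequenceRBM):
        if beta == 1.0:
            tilted = model
        else:
            tilted = SequenceRBM(n_hidden=model.n_hidden)
            tilted.fields_ = model.fields_ * beta
            tilted.weights_ = model.weights_ * beta
            tilted.potential_ = model.potential_
            tilted.n_columns_ = model.n_columns_
        tilted.estimate_log_partition(
            n_betas=2000, n_repeats=5, random_state=random_state
        )
        return tilted.entropy_log10(
            n_samples=n_samples, random_state=random_state, burn_in=200, thin=5
        )
    raise TypeError(f"unsupported model type: {type(model)!r}")
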