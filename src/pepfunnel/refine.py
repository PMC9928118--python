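"""Likelihood-based outlier removal from a raw fragment alignment.

A small throwaway RBM (10 dReLU units, sparse penalty lambda_12 = 1e-2) is
trained on the raw alignment; records whose Z-normalized (unnormalized) log
probability falls below a cutoff do not share the alignment's conservation
and covariation patterns and are discarded. The unnormalized score suffices:
the partition function is constant across records and cancels in the
Z-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, profile_matrix, sequence_weights
from .rbm import SequenceRBM

__all__ = ["RefinementReport", "refine_alignment"]


@dataclass
class RefinementReport:
    ids: list[str]
    z_scores: np.ndarray
    kept: np.ndarray
    cutoff: float
    group_edges: np.ndarray
    group_index: np.ndarray
    group_profiles: list[np.ndarray]
    #: raw-likelihood location/scale behind the Z normalization; reusing them
    #: (with the same filter model) anchors the cutoff to a fixed likelihood
    #: threshold across repeated refinement passes
    raw_mean: float = 0.0
    raw_sd: float = 1.0
    model: SequenceRBM | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "z_loglik": self.z_scores,
                "group": self.group_index,
                "kept": self.kept,
            }
        )


def refine_alignment(
    aln: Alignment,
    cutoff_z: float = -0.3,
    n_groups: int = 6,
    n_hidden: int = 10,
    weight_l12: float = 1e-2,
    n_updates: int = 2000,
    seed: int = 0,
    model: SequenceRBM | None = None,
    z_stats: tuple[float, float] | None = None,
    **rbm_params,
) -> tuple[Alignment, RefinementReport]:
    """Train the filter RBM, Z-normalize per-record log-likelihoods, bin the
    records into equal-width likelihood groups with per-group profiles, and
    drop records with Z below ``cutoff_z``.

    ``z_stats`` (mean, sd of raw log-likelihood) re-anchors the Z scale, e.g.
    to a previous pass's report, so the cutoff keeps denoting the same
    likelihood threshold; by default the input's own statistics are used
    (mean 0, SD 1 over the input). Aborts if the cutoff would remove more
    than 90% of the records.
    """
    weights = sequence_weights(aln)
    if model is None:
        model = SequenceRBM(
            n_hidden=n_hidden,
            weight_l12=weight_l12,
            n_updates=n_updates,
            random_state=seed,
            **rbm_params,
        ).fit(aln, sample_weight=weights)
    raw = model.unnormalized_logp(aln)
    raw_mean, raw_sd = z_stats if z_stats is not None else (raw.mean(), raw.std())
    z = (raw - raw_mean) / raw_sd
    kept = z >= cutoff_z
    if kept.sum() < 0.1 * aln.n_records:
        raise RuntimeError(
            f"cutoff {cutoff_z} would remove {(~kept).mean():.0%} of records; aborting"
        )
    edges = np.linspace(z.min(), z.max(), n_groups + 1)
    group_index = np.clip(np.digitize(z, edges[1:-1]), 0, n_groups - 1)
    profiles = []
    for g in range(n_groups):
        members = np.flatnonzero(group_index == g)
        if members.size == 0:
            profiles.append(np.full((aln.n_columns, 21), np.nan))
            continue
        sub = aln.subset([aln.ids[k] for k in members])
        profiles.append(profile_matrix(sub, pseudocount=0.0))
    report = RefinementReport(
        ids=list(aln.ids),
        z_scores=z,
        kept=kept,
        cutoff=cutoff_z,
        group_edges=edges,
        group_index=group_index,
        group_profiles=profiles,
        raw_mean=float(raw_mean),
        raw_sd=float(raw_sd),
        model=model,
    )
    filtered = aln.subset([rid for rid, keep in zip(aln.ids, kept) if keep])
    return filtered, report
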