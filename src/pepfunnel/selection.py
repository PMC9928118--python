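"""Grid search over RBM size and sparsity with a cluster-aware split.

The selection rule trades accuracy for interpretability: among grid points
whose mean participation fraction stays below a cap (default 0.5), pick the
one with the best held-out per-site log-likelihood; if no point satisfies
the cap, fall back to the overall best likelihood. The chosen configuration
is then retrained on the full alignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignment import Alignment, sequence_weights, train_validation_split
from .rbm import SequenceRBM

__all__ = ["select_rbm"]


def select_rbm(
    aln: Alignment,
    grid_hidden=(10, 20, 30),
    grid_l12=(0.0, 0.25, 0.5),
    sparsity_cap: float = 0.5,
    cut_distance: float = 2,
    val_fraction: float = 0.2,
    seed: int = 0,
    ais_betas: int = 2000,
    ais_repeats: int = 5,
    refit_full: bool = True,
    **rbm_params,
) -> tuple[SequenceRBM, pd.DataFrame]:
    """Train every (M, lambda_12) grid point, record held-out per-site
    log-likelihood and motif sparsity, and return the selected model
    (retrained on the full alignment) plus the selection table."""
    train_ids, val_ids = train_validation_split(
        aln, cut_distance=cut_distance, val_fraction=val_fraction, seed=seed
    )
    train, val = aln.subset(train_ids), aln.subset(val_ids)
    train_w = sequence_weights(train)
    rows = []
    models = {}
    for m in grid_hidden:
        for l12 in grid_l12:
            model = SequenceRBM(
                n_hidden=m, weight_l12=l12, random_state=seed, **rbm_params
            )
            try:
                model.fit(train, sample_weight=train_w)
                model.estimate_log_partition(
                    n_betas=ais_betas, n_repeats=ais_repeats, random_state=seed
                )
            except FloatingPointError:
                rows.append(
                    {"n_hidden": m, "weight_l12": l12, "heldout_per_site": np.nan,
                     "sparsity": np.nan, "diverged": True}
                )
                continue
            heldout = float(np.mean(model.score_samples(val, per_site=True)))
            sparsity = float(model.participation_fractions().mean())
            rows.append(
                {"n_hidden": m, "weight_l12": l12, "heldout_per_site": heldout,
                 "sparsity": sparsity, "diverged": False}
            )
            models[(m, l12)] = model
    table = pd.DataFrame(rows)
    usable = table[~table["diverged"]]
    if usable.empty:
        raise RuntimeError("all grid points diverged")
    capped = usable[usable["sparsity"] <= sparsity_cap]
    pool = capped if not capped.empty else usable
    best = pool.loc[pool["heldout_per_site"].idxmax()]
    key = (int(best["n_hidden"]), float(best["weight_l12"]))
    if not refit_full:
        return models[key], table
    full_w = sequence_weights(aln)
    final = SequenceRBM(
        n_hidden=key[0], weight_l12=key[1], random_state=seed, **rbm_params
    ).fit(aln, sample_weight=full_w)
    return final, table
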