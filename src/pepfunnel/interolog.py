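"""Interolog-consistency filtering of candidate homolog triplets.

When two protein families interact, their phylogenies mirror each other:
sequences from organisms where the interaction is conserved diverge at
correlated rates. For each substrate we hold a small set of *seed* triplets
(enzyme catalytic domain CnA, regulatory domain CnB, substrate SP) from
organisms with an experimentally validated interaction, plus many *candidate*
triplets from homology search. A candidate is kept when the divergence of its
three components from the seeds is mutually consistent, quantified by Pearson
correlations between per-component similarity profiles.

Scores: S[l, l', k] is the pairwise identity between triplet l and seed l'
for component k; R[l, k, k'] the Pearson correlation over seeds of the two
similarity profiles; R_l their off-diagonal mean. Candidates with R_l below
the worst seed's own (leave-one-out) R_l are discarded, so all seeds pass by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment

__all__ = [
    "Triplet",
    "TripletSet",
    "ConsistencyScores",
    "pairwise_identity",
    "similarity_tensor",
    "triplet_consistency",
    "select_species_copies",
    "filter_triplets",
    "extract_fragments",
    "DegenerateCorrelationError",
]

COMPONENTS = ("CnA", "CnB", "SP")


class DegenerateCorrelationError(ValueError):
    """Similarity profile with zero variance over seeds: Pearson undefined."""


@dataclass
class Triplet:
    triplet_id: str
    organism: str
    cna: str
    cnb: str
    sp: str
    # id of the CnA / CnB copy, distinguishing paralogs within an organism
    cna_id: str = ""
    cnb_id: str = ""

    def component(self, k: str) -> str:
        return {"CnA": self.cna, "CnB": self.cnb, "SP": self.sp}[k]


@dataclass
class TripletSet:
    substrate_id: str
    seeds: list[Triplet]
    candidates: list[Triplet]
    slim_start: int | None = None  # 1-based column of the SLiM in the SP alignment

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("seed triplets must be non-empty")
        for t in self.seeds + self.candidates:
            if not (t.cna and t.cnb and t.sp):
                raise ValueError(f"triplet {t.triplet_id} is missing a component")


@dataclass
class ConsistencyScores:
    triplet_ids: list[str]
    #: (n_triplets, 3) columns (CnA-CnB, CnA-SP, CnB-SP)
    r_pairs: np.ndarray
    r_mean: np.ndarray
    kept: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.r_pairs, columns=["R_CnA_CnB", "R_CnA_SP", "R_CnB_SP"]
        )
        frame.insert(0, "triplet_id", self.triplet_ids)
        frame["R_l"] = self.r_mean
        if self.kept is not None:
            frame["kept"] = self.kept
        return frame


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of aligned positions with identical symbols.

    Columns gapped in both sequences are excluded; gap-vs-residue counts as a
    mismatch. Raises on empty overlap.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be globally aligned (equal length)")
    pairs = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    if not pairs:
        raise ValueError("undefined similarity: no aligned positions after gap exclusion")
    return sum(x == y for x, y in pairs) / len(pairs)


def similarity_tensor(ts: TripletSet) -> np.ndarray:
    """S[l, l', k]: identity of triplet l to seed l' for component k.

    l runs over seeds followed by candidates; l' over seeds; k over
    (CnA, CnB, SP).
    """
    everything = ts.seeds + ts.candidates
    out = np.empty((len(everything), len(ts.seeds), len(COMPONENTS)))
    for l, trip in enumerate(everything):
        for lp, seed in enumerate(ts.seeds):
            for k, comp in enumerate(COMPONENTS):
                out[l, lp, k] = pairwise_identity(trip.component(comp), seed.component(comp))
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateCorrelationError(
            "zero variance over seeds; similarity profile is constant"
        )
    return float(np.corrcoef(x, y)[0, 1])


def triplet_consistency(ts: TripletSet, similarities: np.ndarray | None = None) -> ConsistencyScores:
    """Per-triplet consistency R_l = mean of the three off-diagonal Pearson
    correlations between component similarity profiles.

    Seed triplets are scored leave-one-out (their profile over the *other*
    seeds), so the later thresholding rule is well defined; candidates are
    scored over all seeds. Requires at least 3 usable seed points.
    """
    if similarities is None:
        similarities = similarity_tensor(ts)
    n_seeds = len(ts.seeds)
    if n_seeds < 3:
        raise ValueError("need at least 3 seed triplets for Pearson correlation")
    everything = ts.seeds + ts.candidates
    pair_index = [(0, 1), (0, 2), (1, 2)]
    r_pairs = np.empty((len(everything), 3))
    for l, trip in enumerate(everything):
        if l < n_seeds:
            cols = [lp for lp in range(n_seeds) if lp != l]
            if len(cols) < 3:
                raise ValueError("need at least 4 seeds for leave-one-out seed scoring")
        else:
            cols = list(range(n_seeds))
        prof = similarities[l, cols, :]
        for p, (k, kp) in enumerate(pair_index):
            r_pairs[l, p] = _pearson(prof[:, k], prof[:, kp])
    return ConsistencyScores(
        triplet_ids=[t.triplet_id for t in everything],
        r_pairs=r_pairs,
        r_mean=r_pairs.mean(axis=1),
    )


def select_species_copies(ts: TripletSet, scores: ConsistencyScores) -> TripletSet:
    """Keep, per organism, the single CnA and CnB copy maximizing the mean R_l
    over that organism's candidate triplets; ties go to the lexicographically
    smallest copy id."""
    r_by_id = dict(zip(scores.triplet_ids, scores.r_mean))
    by_org: dict[str, list[Triplet]] = {}
    for t in ts.candidates:
        by_org.setdefault(t.organism, []).append(t)
    kept: list[Triplet] = []
    for org in sorted(by_org):
        trips = by_org[org]
        best_copy = {}
        for comp_attr in ("cna_id", "cnb_id"):
            means = {}
            for copy_id in sorted({getattr(t, comp_attr) for t in trips}):
                vals = [r_by_id[t.triplet_id] for t in trips if getattr(t, comp_attr) == copy_id]
                means[copy_id] = np.mean(vals)
            best = max(sorted(means), key=lambda c: (means[c], tuple(-ord(ch) for ch in c)))
            best_copy[comp_attr] = best
        survivors = [
            t
            for t in trips
            if t.cna_id == best_copy["cna_id"] and t.cnb_id == best_copy["cnb_id"]
        ]
        if not survivors:
            warnings.warn(f"organism {org}: no triplet uses both selected copies; skipped")
        kept.extend(survivors)
    return TripletSet(ts.substrate_id, ts.seeds, kept, ts.slim_start)


def filter_triplets(ts: TripletSet, scores: ConsistencyScores | None = None) -> tuple[TripletSet, ConsistencyScores]:
    """Threshold candidates at the minimum seed R_l, so every seed is kept."""
    if scores is None:
        scores = triplet_consistency(ts)
    n_seeds = len(ts.seeds)
    threshold = scores.r_mean[:n_seeds].min()
    kept_mask = np.ones(len(scores.triplet_ids), dtype=bool)
    kept_candidates = []
    for j, t in enumerate(ts.candidates):
        l = n_seeds + j
        if scores.r_mean[l] >= threshold:
            kept_candidates.append(t)
        else:
            kept_mask[l] = False
    scores.kept = kept_mask
    return TripletSet(ts.substrate_id, ts.seeds, kept_candidates, ts.slim_start), scores


def extract_fragments(
    ts: TripletSet,
    sp_alignment: dict[str, str],
    window_left: int = 10,
    window_right: int = 16,
) -> tuple[list[str], list[str]]:
    """Extract ungapped fragments around the SLiM from aligned substrates.

    ``sp_alignment`` maps triplet id to the *aligned* (gapped) substrate
    sequence. The window spans alignment columns slim_start - window_left to
    slim_start + window_right (1-based, inclusive, clipped to bounds);
    insertions inside the window are retained, so fragments may be longer than
    the column span. Fully-gapped windows are dropped with a warning.

    Returns (ids, fragments).
    """
    if ts.slim_start is None:
        raise ValueError("slim_start is not defined for this triplet set")
    ids, frags = [], []
    for trip in ts.seeds + ts.candidates:
        if trip.triplet_id not in sp_alignment:
            continue
        row = sp_alignment[trip.triplet_id]
        lo = ts.slim_start - window_left
        hi = ts.slim_start + window_right
        if lo < 1 or hi > len(row):
            warnings.warn(
                f"{trip.triplet_id}: window [{lo}, {hi}] clipped to alignment bounds"
            )
            lo, hi = max(1, lo), min(len(row), hi)
        fragment = row[lo - 1 : hi].replace("-", "")
        if not fragment:
            warnings.warn(f"{trip.triplet_id}: fully gapped in window; dropped")
            continue
        ids.append(trip.triplet_id)
        frags.append(fragment)
    return ids, frags
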