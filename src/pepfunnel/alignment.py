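"""Gapped fragment alignments: I/O, reweighting, clustering, splits, profiles.

An :class:`Alignment` is a set of equal-length sequences over the 21-symbol
gapped alphabet, with optional per-record annotations (gene, organism, taxon)
parsed from FASTA headers of the form ``id|gene=...|organism=...``.

Sequence reweighting follows the standard MSA convention: each record gets
weight 1 / (number of records within a Hamming radius, itself included), so
dense clusters of near-duplicates do not dominate model training.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.cluster.hierarchy import fcluster, single
from scipy.spatial.distance import pdist, squareform

from .alphabet import AlphabetError, encode_many

__all__ = [
    "Alignment",
    "AlignmentShapeError",
    "read_alignment",
    "write_alignment",
    "sequence_weights",
    "hamming_matrix",
    "cluster_labels",
    "cluster_representatives",
    "train_validation_split",
    "profile_matrix",
]


class AlignmentShapeError(ValueError):
    """Records of unequal length or an otherwise malformed alignment."""


_ANNOTATION_KEYS = ("gene", "organism", "taxon")


@dataclass
class Alignment:
    """Equal-length gapped sequences with unique ids and optional annotations."""

    ids: list[str]
    sequences: list[str]
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise AlignmentShapeError("ids and sequences differ in length")
        if len(self.ids) == 0:
            raise AlignmentShapeError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentShapeError("record ids are not unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"ragged sequence lengths: {sorted(lengths)}")
        # validates the alphabet as a side effect
        self._codes = encode_many(self.sequences)

    @property
    def n_records(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """Integer-encoded (n_records, n_columns) matrix."""
        return self._codes

    def subset(self, ids) -> "Alignment":
        wanted = list(ids)
        index = {rid: k for k, rid in enumerate(self.ids)}
        rows = [index[rid] for rid in wanted]
        ann = None
        if self.annotations is not None:
            ann = self.annotations.iloc[rows].reset_index(drop=True)
        return Alignment(
            ids=[self.ids[r] for r in rows],
            sequences=[self.sequences[r] for r in rows],
            annotations=ann,
        )

    def annotation(self, key: str) -> np.ndarray:
        if self.annotations is None or key not in self.annotations:
            return np.array([None] * self.n_records, dtype=object)
        return self.annotations[key].to_numpy()


def _parse_header(header: str) -> tuple[str, dict]:
    parts = header.split("|")
    ann = {}
    for part in parts[1:]:
        if "=" in part:
            key, value = part.split("=", 1)
            if key in _ANNOTATION_KEYS:
                ann[key] = value
    return parts[0], ann


def read_alignment(path) -> Alignment:
    """Read a gapped FASTA alignment, enforcing alignment invariants.

    Raises :class:`AlignmentShapeError` on ragged lengths and
    :class:`AlphabetError` on characters outside the 21-symbol alphabet.
    """
    handle = io.StringIO(path) if isinstance(path, str) and path.startswith(">") else path
    records = list(SeqIO.parse(handle if handle is not path else str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"no FASTA records found in {path}")
    ids, seqs, anns = [], [], []
    for rec in records:
        rid, ann = _parse_header(rec.description or rec.id)
        ids.append(rid)
        seqs.append(str(rec.seq).upper())
        anns.append(ann)
    annotations = pd.DataFrame(anns) if any(anns) else None
    return Alignment(ids=ids, sequences=seqs, annotations=annotations)


def write_alignment(aln: Alignment, path) -> None:
    records = []
    for k, (rid, seq) in enumerate(zip(aln.ids, aln.sequences)):
        header = rid
        if aln.annotations is not None:
            row = aln.annotations.iloc[k]
            for key in _ANNOTATION_KEYS:
                if key in row and pd.notna(row[key]):
                    header += f"|{key}={row[key]}"
            rid_out, rest = header.split("|", 1) if "|" in header else (header, "")
            header = rid_out + ("|" + rest if rest else "")
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def hamming_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise Hamming distances (counts of differing columns, gaps included)."""
    codes = aln.codes()
    if aln.n_records == 1:
        return np.zeros((1, 1))
    return squareform(pdist(codes, metric="hamming") * aln.n_columns)


def sequence_weights(aln: Alignment, max_mismatch: int = 1) -> np.ndarray:
    """Inverse neighbourhood-size weights.

    weight(s) = 1 / |{s' : Hamming(s, s') <= max_mismatch}| with s in its own
    neighbourhood, so every weight lies in (0, 1].
    """
    if aln.n_records == 0:
        raise ValueError("empty alignment")
    dist = hamming_matrix(aln)
    counts = (dist <= max_mismatch + 1e-9).sum(axis=1)
    return 1.0 / counts


def cluster_labels(aln: Alignment, cut_distance: float) -> np.ndarray:
    """Single-linkage cluster labels after cutting the tree at ``cut_distance``."""
    if cut_distance < 0:
        raise ValueError("cut_distance must be non-negative")
    if aln.n_records == 1:
        return np.array([1])
    dist = pdist(aln.codes(), metric="hamming") * aln.n_columns
    linkage = single(dist)
    return fcluster(linkage, t=cut_distance, criterion="distance")


def cluster_representatives(
    aln: Alignment, cut_distance: float, scores
) -> list[str]:
    """One representative id per single-linkage cluster: the member with the
    highest score, ties broken lexicographically by id."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != aln.n_records:
        raise ValueError("scores length must equal record count")
    labels = cluster_labels(aln, cut_distance)
    reps = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        best = max(members, key=lambda m: (scores[m], _neg_lex(aln.ids[m])))
        reps.append(aln.ids[best])
    return sorted(reps, key=lambda rid: aln.ids.index(rid))


def _neg_lex(s: str):
    # max() with lexicographically *smallest* id on score ties
    return tuple(-ord(c) for c in s)


def train_validation_split(
    aln: Alignment,
    cut_distance: float = 2,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Cluster-aware split: whole single-linkage clusters are assigned to the
    validation set, so any train/validation pair differs by at least
    ``cut_distance + 1`` columns."""
    labels = cluster_labels(aln, cut_distance)
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError(
            "single cluster at this cut distance; cluster-aware split infeasible"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    n_val = max(1, int(round(val_fraction * unique.size)))
    n_val = min(n_val, unique.size - 1)
    val_clusters = set(order[:n_val].tolist())
    train_ids = [rid for rid, lab in zip(aln.ids, labels) if lab not in val_clusters]
    val_ids = [rid for rid, lab in zip(aln.ids, labels) if lab in val_clusters]
    return train_ids, val_ids


def profile_matrix(
    aln: Alignment, weights=None, pseudocount: float = 0.0
) -> np.ndarray:
    """Weighted, pseudocount-smoothed column frequency matrix (N x 21).

    Rows sum to one. ``pseudocount`` is added to every (column, symbol) cell.
    """
    from .alphabet import Q

    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    codes = aln.codes()
    if weights is None:
        weights = np.ones(aln.n_records)
    weights = np.asarray(weights, dtype=float)
    counts = np.zeros((aln.n_columns, Q))
    for i in range(aln.n_columns):
        np.add.at(counts[i], codes[:, i], weights)
    counts += pseudocount
    return counts / counts.sum(axis=1, keepdims=True)
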