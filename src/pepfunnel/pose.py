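"""Geometry-only scoring of docked receptor-peptide poses.

A candidate placement is scored by
``Coverage + 0.05 * NumAtomContacts + 0.05 * Extension`` where
NumAtomContacts counts receptor-peptide heavy-atom pairs closer than 4 A,
Coverage the peptide residues with at least one such contact, and Extension
the distance between the terminal C-alpha atoms (favoring extended, beta-like
conformations). Clashing poses (any pair under 2 A) are rigidly translated
away from the receptor before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ComplexPose", "count_contacts", "pose_cost", "resolve_clashes", "pose_from_pdb"]


@dataclass
class ComplexPose:
    """Heavy-atom coordinates of a receptor and a posed peptide.

    ``peptide_residue`` assigns each peptide atom to a residue index,
    ordered N to C; terminal C-alpha atom indices are stored explicitly.
    """

    receptor_xyz: np.ndarray
    peptide_xyz: np.ndarray
    peptide_residue: np.ndarray
    n_term_ca: int | None = None
    c_term_ca: int | None = None

    def __post_init__(self):
        self.receptor_xyz = np.asarray(self.receptor_xyz, dtype=float)
        self.peptide_xyz = np.asarray(self.peptide_xyz, dtype=float)
        self.peptide_residue = np.asarray(self.peptide_residue, dtype=int)
        if self.peptide_xyz.shape[0] == 0:
            raise ValueError("empty peptide")
        for xyz in (self.receptor_xyz, self.peptide_xyz):
            if not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite coordinates")


def count_contacts(pose: ComplexPose, cutoff: float = 4.0) -> tuple[int, int]:
    """(NumAtomContacts, Coverage) under the center-center distance cutoff."""
    if pose.receptor_xyz.shape[0] == 0:
        return 0, 0
    from scipy.spatial.distance import cdist

    # strict inequality: pairs exactly at the cutoff are not contacts
    close = cdist(pose.peptide_xyz, pose.receptor_xyz) < cutoff
    per_atom = close.sum(axis=1)
    touched = pose.peptide_residue[per_atom > 0]
    return int(per_atom.sum()), int(np.unique(touched).size)


def pose_cost(pose: ComplexPose, cutoff: float = 4.0) -> float:
    """Coverage + 0.05 * NumAtomContacts + 0.05 * Extension."""
    if pose.n_term_ca is None or pose.c_term_ca is None:
        raise ValueError("terminal C-alpha atoms are not defined for this pose")
    n_contacts, coverage = count_contacts(pose, cutoff=cutoff)
    extension = float(
        np.linalg.norm(pose.peptide_xyz[pose.c_term_ca] - pose.peptide_xyz[pose.n_term_ca])
    )
    return coverage + 0.05 * n_contacts + 0.05 * extension


def resolve_clashes(
    pose: ComplexPose, clash_cutoff: float = 2.0, step: float = 0.5
) -> ComplexPose:
    """Translate the peptide rigidly away from the receptor until no atom
    pair is closer than ``clash_cutoff``; internal geometry is unchanged.

    The translation direction is the receptor-centroid to peptide-centroid
    vector.
    """
    tree = cKDTree(pose.receptor_xyz)
    direction = pose.peptide_xyz.mean(axis=0) - pose.receptor_xyz.mean(axis=0)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("coincident centroids: translation direction undefined")
    direction = direction / norm
    xyz = pose.peptide_xyz.copy()
    while tree.query(xyz, k=1)[0].min() < clash_cutoff:
        xyz = xyz + step * direction
    return ComplexPose(
        receptor_xyz=pose.receptor_xyz,
        peptide_xyz=xyz,
        peptide_residue=pose.peptide_residue,
        n_term_ca=pose.n_term_ca,
        c_term_ca=pose.c_term_ca,
    )


def pose_from_pdb(path, receptor_chains, peptide_chain) -> ComplexPose:
    """Build a pose from ATOM records of a PDB file (heavy atoms only;
    waters and hetero records ignored)."""
    from biotite.structure.io.pdb import PDBFile

    structure = PDBFile.read(str(path)).get_structure(model=1)
    mask = (
        (structure.element != "H")
        & ~structure.hetero
        & (structure.res_name != "HOH")
    )
    structure = structure[mask]
    receptor = structure[np.isin(structure.chain_id, list(receptor_chains))]
    peptide = structure[structure.chain_id == peptide_chain]
    if peptide.array_length() == 0:
        raise ValueError(f"no peptide atoms found in chain {peptide_chain!r}")
    res_ids = peptide.res_id
    order = np.unique(res_ids)
    residue_index = np.searchsorted(order, res_ids)
    ca = np.flatnonzero(peptide.atom_name == "CA")
    n_term = int(ca[np.argmin(residue_index[ca])]) if ca.size else None
    c_term = int(ca[np.argmax(residue_index[ca])]) if ca.size else None
    return ComplexPose(
        receptor_xyz=receptor.coord,
        peptide_xyz=peptide.coord,
        peptide_residue=residue_index,
        n_term_ca=n_term,
        c_term_ca=c_term,
    )
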