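"""Grouping molecules into contact clusters and cluster kinematics.

Two molecules are in contact when the smallest distance between any of their
atoms is strictly below a cutoff (default 0.3 nm; a pair at exactly the
cutoff is *not* in contact). Clusters are the connected components of the
contact graph. The neighbor search uses a k-d tree over all atoms, which by
construction finds every atom pair below the cutoff, so the result equals the
all-pairs computation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .molecules import MoleculeSet
from .trajectory import Frame


def min_intermolecular_distance(mol_a, mol_b, frame: Frame) -> float:
    """Smallest Euclidean distance (nm) between atoms of two molecules."""
    if len(mol_a.atom_ids) == 0 or len(mol_b.atom_ids) == 0:
        raise ValueError("empty molecule")
    if set(map(int, mol_a.atom_ids)) & set(map(int, mol_b.atom_ids)):
        raise ValueError("molecules share atoms; atom sets must be disjoint")
    pa = frame.positions[frame.rows_of(mol_a.atom_ids)]
    pb = frame.positions[frame.rows_of(mol_b.atom_ids)]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


@dataclass
class Cluster:
    """One contact cluster: member molecules plus mass-weighted kinematics."""

    cluster_id: int
    molecule_ids: list[int]
    composition: dict[str, int]      # species -> count
    mass: float                      # amu
    com: np.ndarray                  # nm
    com_velocity: np.ndarray         # nm/ps

    def __len__(self) -> int:
        return len(self.molecule_ids)


@dataclass
class ClusterSet:
    """Partition of a frame's molecules into contact clusters."""

    time: float
    molecule_set: MoleculeSet
    labels: np.ndarray               # per molecule id -> cluster id
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_of_molecule(self, mol_id: int) -> Cluster:
        return self.clusters[int(self.labels[mol_id])]


def cluster_kinematics(atom_rows: np.ndarray, frame: Frame
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Mass-weighted center of mass, COM velocity and total mass of atoms."""
    if len(atom_rows) == 0:
        raise ValueError("empty cluster")
    m = frame.masses()[atom_rows]
    total = float(m.sum())
    com = (m[:, None] * frame.positions[atom_rows]).sum(axis=0) / total
    vcom = (m[:, None] * frame.velocities[atom_rows]).sum(axis=0) / total
    return com, vcom, total


def identify_clusters(frame: Frame, molecule_set: MoleculeSet,
                      contact_cutoff: float = 0.3) -> ClusterSet:
    """Partition molecules into clusters of mutual contact.

    Edges of the contact graph are molecule pairs whose minimum atom-atom
    distance is strictly less than ``contact_cutoff`` (nm). Cluster ids are
    deterministic: ordered by the smallest member molecule id.
    """
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    n_mol = len(molecule_set.molecules)
    mol_label = molecule_set.labels
    tree = cKDTree(frame.positions)
    pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(frame.positions[pairs[:, 0]]
                           - frame.positions[pairs[:, 1]], axis=1)
        pairs = pairs[d < contact_cutoff]          # strict inequality
    if len(pairs):
        mi = mol_label[pairs[:, 0]]
        mj = mol_label[pairs[:, 1]]
        cross = mi != mj
        adj = coo_matrix((np.ones(cross.sum()), (mi[cross], mj[cross])),
                         shape=(n_mol, n_mol))
    else:
        adj = coo_matrix((n_mol, n_mol))
    n_comp, comp = connected_components(adj, directed=False)

    # deterministic relabelling by smallest member molecule id
    first_member = np.full(n_comp, n_mol, dtype=np.intp)
    np.minimum.at(first_member, comp, np.arange(n_mol, dtype=np.intp))
    new_id = np.empty(n_comp, dtype=np.intp)
    new_id[np.argsort(first_member)] = np.arange(n_comp)
    labels = new_id[comp]

    clusters = []
    for cid in range(n_comp):
        members = sorted(int(m) for m in np.nonzero(labels == cid)[0])
        rows = np.concatenate([molecule_set.molecule_rows(m) for m in members])
        com, vcom, mass = cluster_kinematics(rows, frame)
        composition = dict(Counter(molecule_set.molecules[m].species
                                   for m in members))
        clusters.append(Cluster(cid, members, composition, mass, com, vcom))
    return ClusterSet(frame.time, molecule_set, labels, clusters)
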