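"""Molecule identification from bond-order connectivity.

A molecule is a connected component of the graph whose vertices are the atoms
of a frame and whose edges are bonds with a ReaxFF bond order above a
threshold (default 0.3 — low enough that a stretched but intact bond still
counts, high enough that van-der-Waals neighbors do not). Each molecule gets
a chemical formula, a mass from standard atomic masses, and a species label
relative to the sample/solvent templates (intact trehalose, water, or
fragment).

Stable identities across frames are assigned by majority atom overlap, so
lifetimes can be followed even though per-frame component labels are
arbitrary; splits and merges are logged as reaction events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import BondTable, Frame
from .units import atomic_mass

#: Default templates: the intact sample molecule and the solvent.
DEFAULT_TEMPLATES = {
    "intact_trehalose": {"C": 12, "H": 22, "O": 11},
    "water": {"H": 2, "O": 1},
}

TREHALOSE_MASS = 342.297  # amu, C12H22O11 from the packaged atomic masses


def formula_and_mass(formula_or_elements) -> tuple[dict[str, int], float]:
    """Chemical formula (element → count) and mass (amu).

    Accepts either a formula mapping or an iterable of element symbols.
    Mass is the sum of standard atomic masses; unknown symbols raise.
    """
    if isinstance(formula_or_elements, dict):
        formula = {k: int(v) for k, v in formula_or_elements.items()}
    else:
        formula = dict(Counter(formula_or_elements))
    mass = float(sum(n * atomic_mass(el) for el, n in formula.items()))
    return formula, mass


def classify_species(formula: dict[str, int],
                     templates: dict[str, dict[str, int]] = DEFAULT_TEMPLATES) -> str:
    """Label a formula as ``water``, ``intact_trehalose`` or ``fragment``.

    Classification is per-frame and by formula only: any composition that is
    neither the solvent nor the intact sample template is a fragment (this
    includes a trehalose that transiently lost or gained atoms).
    """
    clean = {el: n for el, n in formula.items() if n}
    for label, template in templates.items():
        if clean == template:
            return label
    return "fragment"


@dataclass
class Molecule:
    """One identified molecule within a frame."""

    mol_id: int
    atom_ids: np.ndarray
    formula: dict[str, int]
    mass: float
    species: str

    def __len__(self) -> int:
        return len(self.atom_ids)


@dataclass
class MoleculeSet:
    """Partition of a frame's atoms into molecules.

    ``labels[i]`` is the molecule id of the atom in frame row ``i``; molecule
    ids are deterministic (ordered by smallest member atom id). ``stable_ids``
    is filled by :func:`track_molecule_identity`.
    """

    time: float
    frame: Frame
    labels: np.ndarray
    molecules: list[Molecule]
    stable_ids: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def total_mass(self) -> float:
        return float(sum(m.mass for m in self.molecules))

    def molecule_of_atom(self, atom_id: int) -> Molecule:
        row = self.frame.rows_of([atom_id])[0]
        return self.molecules[int(self.labels[row])]

    def molecule_rows(self, mol_id: int) -> np.ndarray:
        return self.frame.rows_of(self.molecules[mol_id].atom_ids)


def identify_molecules(frame: Frame, bond_table: BondTable,
                       bo_threshold: float = 0.3,
                       templates: dict[str, dict[str, int]] = DEFAULT_TEMPLATES,
                       ) -> MoleculeSet:
    """Partition a frame into molecules by thresholded bond-order connectivity.

    Two atoms are connected when their bond order strictly exceeds
    ``bo_threshold``; molecules are the connected components of that graph and
    isolated atoms form single-atom molecules. Bond records referencing atom
    ids absent from the frame raise (association-time check).
    """
    if bo_threshold <= 0:
        raise ValueError("bo_threshold must be positive")
    n = len(frame)
    if len(bond_table):
        keep = bond_table.orders > bo_threshold
        pairs = bond_table.pairs[keep]
        try:
            rows_i = frame.rows_of(pairs[:, 0]) if len(pairs) else np.empty(0, np.intp)
            rows_j = frame.rows_of(pairs[:, 1]) if len(pairs) else np.empty(0, np.intp)
        except KeyError as exc:
            raise ValueError(f"bond table references atom id absent from frame: {exc}")
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (rows_i, rows_j)), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)

    # deterministic relabelling: order components by their smallest atom id
    order = {}
    min_atom = np.full(n_comp, np.iinfo(np.int64).max)
    np.minimum.at(min_atom, comp, frame.ids)
    for new_id, c in enumerate(np.argsort(min_atom)):
        order[int(c)] = new_id
    labels = np.array([order[int(c)] for c in comp], dtype=np.intp)

    molecules = []
    for mol_id in range(n_comp):
        rows = np.nonzero(labels == mol_id)[0]
        formula, mass = formula_and_mass(frame.elements[rows])
        species = classify_species(formula, templates)
        molecules.append(Molecule(mol_id, np.sort(frame.ids[rows]), formula,
                                  mass, species))
    return MoleculeSet(frame.time, frame, labels, molecules)


@dataclass
class ReactionEvent:
    """A change of molecular identity between consecutive frames."""

    time: float            # time of the later frame
    kind: str              # "split" or "merge"
    parent_stable_ids: tuple[int, ...]
    child_stable_ids: tuple[int, ...]


def track_molecule_identity(molecule_sets: list[MoleculeSet]
                            ) -> list[ReactionEvent]:
    """Assign stable molecule ids across frames (filled in-place).

    A molecule in frame *t+1* inherits the stable id of the frame-*t* molecule
    with which it shares more than half of both molecules' atoms; anything
    else (a split half, a merge product, a fresh molecule) gets a new id and
    the corresponding reaction event is recorded. Returns the event log.
    """
    if len(molecule_sets) < 2:
        raise ValueError("need at least two molecule sets to track identity")
    events: list[ReactionEvent] = []
    next_stable = 0
    first = molecule_sets[0]
    first.stable_ids = {m.mol_id: m.mol_id for m in first.molecules}
    next_stable = len(first.molecules)

    for prev, cur in zip(molecule_sets[:-1], molecule_sets[1:]):
        # map atom id -> previous molecule id
        prev_of_atom = {}
        for m in prev.molecules:
            for a in m.atom_ids:
                prev_of_atom[int(a)] = m.mol_id
        cur.stable_ids = {}
        children_of: dict[int, list[int]] = {}
        parents_of: dict[int, list[int]] = {}
        for m in cur.molecules:
            overlap: Counter = Counter()
            for a in m.atom_ids:
                p = prev_of_atom.get(int(a))
                if p is not None:
                    overlap[p] += 1
            if overlap:
                best_p, best_n = overlap.most_common(1)[0]
                parents_of[m.mol_id] = sorted(overlap)
                for p in overlap:
                    children_of.setdefault(p, []).append(m.mol_id)
                if (best_n * 2 > len(m)
                        and best_n * 2 > len(prev.molecules[best_p])):
                    cur.stable_ids[m.mol_id] = prev.stable_ids[best_p]
                    continue
            cur.stable_ids[m.mol_id] = next_stable
            next_stable += 1
        # log splits (one parent feeding several children) and merges
        for p, children in children_of.items():
            if len(children) > 1:
                events.append(ReactionEvent(
                    cur.time, "split",
                    (prev.stable_ids[p],),
                    tuple(cur.stable_ids[c] for c in sorted(children))))
        for c, parents in parents_of.items():
            if len(parents) > 1:
                events.append(ReactionEvent(
                    cur.time, "merge",
                    tuple(prev.stable_ids[p] for p in parents),
                    (cur.stable_ids[c],)))
    return events
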