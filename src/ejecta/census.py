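"""Sputtered-yield census.

A cluster counts as sputtered when, at the end of the impact phase (default
75 ps), its center of mass sits at least 15 nm above the surface reference
and its center-of-mass velocity points upward (vz > 0). Sputtered material is
decomposed into the five trajectory-census categories — single and multiple
bare trehalose, single and multiple solvated trehalose, and molecular
fragments — with yields expressed as dimensionless multiples of the
trehalose mass (342.3 amu). Pure-water ejecta are tallied separately and are
not part of the five categories.

The surface reference z0 is not defined by the ejection criterion itself; by
default it is the maximum z coordinate of the sample atoms in the initial
frame (conservative for a hemispherical sample), with the mean of the top
decile available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clusters import Cluster, ClusterSet
from .molecules import MoleculeSet
from .trajectory import Frame
from .units import KE_AMU_NM2_PS2_TO_EV

CATEGORIES = ("single_bare", "multiple_bare", "single_solvated",
              "multiple_solvated", "fragments")

DEFAULT_REFERENCE_MASS = 342.3   # amu, trehalose as printed on the yield axis
DEFAULT_HEIGHT_MIN = 15.0        # nm above the surface reference
DEFAULT_EVAL_TIME = 75.0         # ps, end of the impact phase


def surface_reference(initial_frame: Frame, sample_atom_ids,
                      method: str = "max") -> float:
    """Surface reference height z0 (nm) from the initial sample atoms.

    ``method='max'`` uses the topmost sample atom; ``'top_decile_mean'``
    averages the highest tenth of sample atoms, which is less sensitive to a
    single protruding atom.
    """
    sample_atom_ids = np.atleast_1d(sample_atom_ids)
    if len(sample_atom_ids) == 0:
        raise ValueError("sample atom set is empty")
    z = initial_frame.positions[initial_frame.rows_of(sample_atom_ids), 2]
    if method == "max":
        return float(z.max())
    if method == "top_decile_mean":
        k = max(1, len(z) // 10)
        return float(np.sort(z)[-k:].mean())
    raise ValueError(f"unknown surface-reference method {method!r}")


@dataclass
class SputterRecord:
    """Sputter verdict for one cluster at one evaluation time."""

    cluster_id: int
    time: float
    height: float          # COM height above z0 (nm)
    vz: float              # COM velocity z component (nm/ps)
    sputtered: bool


def is_sputtered(cluster: Cluster, time: float, z0: float,
                 height_min: float = DEFAULT_HEIGHT_MIN,
                 require_positive_vz: bool = True) -> SputterRecord:
    """Apply the ejection criterion to one cluster."""
    height = float(cluster.com[2] - z0)
    vz = float(cluster.com_velocity[2])
    ok = height >= height_min and (vz > 0 or not require_positive_vz)
    return SputterRecord(cluster.cluster_id, time, height, vz, ok)


def categorize_cluster(members: list[tuple[str, float]]) -> dict[str, float]:
    """Allocate a sputtered cluster's mass to yield categories.

    ``members`` is a list of (species, mass) per member molecule. Fragment
    mass always goes to ``fragments`` and the residual intact composition is
    re-categorized on its own; a cluster of waters only contributes to the
    separate ``water`` tally. Returns a mapping category → mass (amu)
    containing only non-zero entries.
    """
    if not members:
        raise ValueError("empty cluster composition")
    out: dict[str, float] = {}
    frag_mass = sum(m for s, m in members if s == "fragment")
    if frag_mass:
        out["fragments"] = frag_mass
    n_treh = sum(1 for s, _ in members if s == "intact_trehalose")
    n_water = sum(1 for s, _ in members if s == "water")
    residual_mass = sum(m for s, m in members if s != "fragment")
    if n_treh == 0:
        if n_water and residual_mass:
            out["water"] = residual_mass
        return out
    if n_treh == 1:
        cat = "single_solvated" if n_water else "single_bare"
    else:
        cat = "multiple_solvated" if n_water else "multiple_bare"
    out[cat] = residual_mass
    return out


@dataclass
class ImpactCensus:
    """Per-impact census: category masses (amu), water tally, records."""

    category_mass: dict[str, float]
    water_mass: float
    records: list[SputterRecord]
    sputtered_molecule_masses: np.ndarray
    sputtered_molecule_species: list[str]


def census_impact(cluster_set: ClusterSet, z0: float,
                  height_min: float = DEFAULT_HEIGHT_MIN,
                  require_positive_vz: bool = True,
                  include_water_mass_in_solvated: bool = True) -> ImpactCensus:
    """Run the sputter criterion over every cluster of one impact.

    ``include_water_mass_in_solvated=False`` switches the solvated categories
    to trehalose-only mass (the adjoining waters then join the water tally);
    the yield axis of the census does not state which convention it uses, so
    both are available.
    """
    mset = cluster_set.molecule_set
    cat_mass = {c: 0.0 for c in CATEGORIES}
    water_mass = 0.0
    records = []
    sput_masses: list[float] = []
    sput_species: list[str] = []
    for cluster in cluster_set.clusters:
        rec = is_sputtered(cluster, cluster_set.time, z0, height_min,
                           require_positive_vz)
        records.append(rec)
        if not rec.sputtered:
            continue
        members = [(mset.molecules[m].species, mset.molecules[m].mass)
                   for m in cluster.molecule_ids]
        alloc = categorize_cluster(members)
        if not include_water_mass_in_solvated:
            for cat in ("single_solvated", "multiple_solvated"):
                if cat in alloc:
                    w = sum(m for s, m in members if s == "water")
                    alloc[cat] -= w
                    alloc["water"] = alloc.get("water", 0.0) + w
        for cat, m in alloc.items():
            if cat == "water":
                water_mass += m
            else:
                cat_mass[cat] += m
        for s, m in members:
            sput_masses.append(m)
            sput_species.append(s)
    return ImpactCensus(cat_mass, water_mass, records,
                        np.array(sput_masses), sput_species)


@dataclass
class YieldBreakdown:
    """Mean ± population std of per-category yields over repeated impacts.

    Yields are dimensionless multiples of ``reference_mass`` (342.3 amu by
    default), matching the units of the census figure; ``total`` is the sum
    of the five categories and excludes the pure-water tally.
    """

    n_impacts: int
    reference_mass: float
    mean: dict[str, float]
    std: dict[str, float]
    water_mean: float = 0.0

    @property
    def total_mean(self) -> float:
        return self.mean["total"]


def compute_yields(impacts: list[ImpactCensus],
                   reference_mass: float = DEFAULT_REFERENCE_MASS
                   ) -> YieldBreakdown:
    """Average per-category yields (in reference-mass units) over impacts."""
    if not impacts:
        raise ValueError("need at least one impact")
    per_cat = {c: np.array([imp.category_mass[c] for imp in impacts])
               / reference_mass for c in CATEGORIES}
    per_cat["total"] = sum(per_cat[c] for c in CATEGORIES)
    water = np.array([imp.water_mass for imp in impacts]) / reference_mass
    return YieldBreakdown(
        n_impacts=len(impacts),
        reference_mass=reference_mass,
        mean={c: float(v.mean()) for c, v in per_cat.items()},
        std={c: float(v.std(ddof=0)) for c, v in per_cat.items()},
        water_mean=float(water.mean()),
    )


def mass_spectrum(impacts: list[ImpactCensus], bin_width: float = 1.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of sputtered-molecule masses, normalized per impact.

    Returns ``(bin_edges, counts_per_impact)`` with bins of ``bin_width`` amu
    starting at zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    masses = np.concatenate([imp.sputtered_molecule_masses for imp in impacts]
                            or [np.empty(0)])
    if len(masses) == 0:
        return np.array([0.0, bin_width]), np.zeros(1)
    top = float(masses.max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    counts, _ = np.histogram(masses, bins=edges)
    return edges, counts / len(impacts)


def per_molecule_kinetic_energy(frame: Frame, molecule_set: MoleculeSet
                                ) -> np.ndarray:
    """Kinetic energy of each molecule (eV), KE = ½ Σ_atoms m v²."""
    m = frame.masses()
    v2 = np.einsum("ij,ij->i", frame.velocities, frame.velocities)
    ke_atom = 0.5 * m * v2 * KE_AMU_NM2_PS2_TO_EV
    out = np.zeros(len(molecule_set.molecules))
    np.add.at(out, molecule_set.labels, ke_atom)
    return out
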