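"""End-to-end orchestration: trajectory + bonds → census + complex traces.

Thin glue over the stage modules so scripts and tests can run the whole
post-processing chain in one call. Each frame is paired with its nearest
bond table, partitioned into molecules and contact clusters, and stable
molecule identities are threaded through time; the sputter census is then
evaluated at the end of the impact phase and complex traces over the full
(impact + extended) span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .census import (DEFAULT_EVAL_TIME, DEFAULT_HEIGHT_MIN, ImpactCensus,
                     census_impact, surface_reference)
from .clusters import ClusterSet, identify_clusters
from .complexes import ComplexTrace, apply_stability_filter, build_complex_traces
from .molecules import (DEFAULT_TEMPLATES, MoleculeSet, ReactionEvent,
                        identify_molecules, track_molecule_identity)
from .trajectory import BondTable, Trajectory, match_bonds_to_frame


@dataclass
class ImpactAnalysis:
    """All per-frame products of one analyzed impact."""

    trajectory: Trajectory
    molecule_sets: list[MoleculeSet]
    cluster_sets: list[ClusterSet]
    reaction_events: list[ReactionEvent]
    z0: float
    eval_time: float
    census: ImpactCensus
    traces: list[ComplexTrace]
    included_complexes: int


def analyze_impact(trajectory: Trajectory, bond_tables: list[BondTable],
                   sample_atom_ids,
                   bo_threshold: float = 0.3,
                   contact_cutoff: float = 0.3,
                   height_min: float = DEFAULT_HEIGHT_MIN,
                   eval_time: float = DEFAULT_EVAL_TIME,
                   min_stable: float = 320.0,
                   max_final_waters: int = 1,
                   templates=DEFAULT_TEMPLATES,
                   include_water_mass_in_solvated: bool = True
                   ) -> ImpactAnalysis:
    """Run the full census + complex-lifetime chain on one impact."""
    molecule_sets: list[MoleculeSet] = []
    cluster_sets: list[ClusterSet] = []
    for frame in trajectory.frames:
        _, table, _ = match_bonds_to_frame(trajectory, bond_tables, frame.time)
        mset = identify_molecules(frame, table, bo_threshold, templates)
        molecule_sets.append(mset)
        cluster_sets.append(identify_clusters(frame, mset, contact_cutoff))
    events = track_molecule_identity(molecule_sets)

    z0 = surface_reference(trajectory.frames[0], sample_atom_ids)
    times = trajectory.times
    eval_idx = int(np.searchsorted(times, eval_time - 1e-9))
    eval_idx = min(eval_idx, len(times) - 1)
    census = census_impact(
        cluster_sets[eval_idx], z0, height_min,
        include_water_mass_in_solvated=include_water_mass_in_solvated)
    traces = build_complex_traces(molecule_sets, cluster_sets, z0, height_min)
    included = apply_stability_filter(traces, min_stable, max_final_waters)
    return ImpactAnalysis(trajectory, molecule_sets, cluster_sets, events,
                          z0, float(times[eval_idx]), census, traces, included)
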