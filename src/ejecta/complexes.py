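"""(Single trehalose)–water complex lifetimes over the extended phase.

After the 75 ps impact phase, sputtered material is followed for up to
900 ps. A complex is a sputtered contact-cluster containing exactly one
intact trehalose plus at least one water at the moment of ejection (the first
frame at which its cluster satisfies the sputter criterion). Per-water
contact intervals are built from consecutive frames in which the water
belongs to the trehalose's cluster (same 0.3 nm contact cutoff as the
census).

The stability filter mirrors the complex-count analysis: complexes stable for
less than 320 ps, or still carrying more than one water at the last frame,
are excluded. "Stable" here means continuous contact with at least one water
from ejection until the first water-free frame (the strictest reading; a
"net presence" variant tolerating single-frame gaps is available via
``allow_gap_frames``). A complex that sheds all waters *after* 320 ps is
included — only ">1 water at the end" is an exclusion — and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import DEFAULT_HEIGHT_MIN, is_sputtered
from .clusters import ClusterSet
from .molecules import MoleculeSet

DEFAULT_MIN_STABLE = 320.0     # ps
DEFAULT_MAX_FINAL_WATERS = 1
DEFAULT_MIN_DISPLAY = 40.0     # ps, contact-map display threshold


@dataclass
class ComplexTrace:
    """Lifetime record of one (single trehalose)–water complex."""

    trehalose_stable_id: int
    ejection_time: float
    contact_intervals: dict[int, list[tuple[float, float]]]
    stable_duration: float
    final_water_count: int
    single_trehalose_throughout: bool
    included: bool | None = None
    flags: list[str] = field(default_factory=list)

    def total_contact(self, water_stable_id: int) -> float:
        """Summed contact duration (ps) of one water with this complex."""
        return float(sum(t1 - t0 for t0, t1
                         in self.contact_intervals.get(water_stable_id, [])))


def _stable_map(mset: MoleculeSet) -> dict[int, int]:
    if not mset.stable_ids:
        raise ValueError("molecule sets must carry stable ids; "
                         "run track_molecule_identity first")
    return {sid: mid for mid, sid in mset.stable_ids.items()}


def build_complex_traces(molecule_sets: list[MoleculeSet],
                         cluster_sets: list[ClusterSet],
                         z0: float,
                         height_min: float = DEFAULT_HEIGHT_MIN,
                         require_positive_vz: bool = True,
                         allow_gap_frames: int = 0) -> list[ComplexTrace]:
    """Build one trace per sputtered single-trehalose complex.

    ``molecule_sets``/``cluster_sets`` must cover the impact *and* extended
    phases frame by frame, with stable ids already assigned. Ejection is the
    first frame whose enclosing cluster is sputtered; traces are only created
    for clusters holding exactly one trehalose and at least one water then.
    """
    if len(molecule_sets) < 2:
        raise ValueError("no extended frames available beyond the first frame")
    if len(molecule_sets) != len(cluster_sets):
        raise ValueError("molecule and cluster sets must be frame-aligned")
    times = [ms.time for ms in molecule_sets]
    stable_maps = [_stable_map(ms) for ms in molecule_sets]

    # candidate trehaloses: intact at any frame
    candidates: set[int] = set()
    for ms in molecule_sets:
        for mol in ms.molecules:
            if mol.species == "intact_trehalose":
                candidates.add(ms.stable_ids[mol.mol_id])

    traces: list[ComplexTrace] = []
    for sid in sorted(candidates):
        eject_idx = None
        for fi, (ms, cs) in enumerate(zip(molecule_sets, cluster_sets)):
            mid = stable_maps[fi].get(sid)
            if mid is None or ms.molecules[mid].species != "intact_trehalose":
                continue
            cluster = cs.cluster_of_molecule(mid)
            if is_sputtered(cluster, cs.time, z0, height_min,
                            require_positive_vz).sputtered:
                eject_idx = fi
                break
        if eject_idx is None:
            continue
        ms = molecule_sets[eject_idx]
        cs = cluster_sets[eject_idx]
        mid = stable_maps[eject_idx][sid]
        cluster = cs.cluster_of_molecule(mid)
        species = [ms.molecules[m].species for m in cluster.molecule_ids]
        if species.count("intact_trehalose") != 1 or species.count("water") == 0:
            continue

        # follow the cluster of this trehalose through the remaining frames
        contact_frames: dict[int, list[int]] = {}
        single_throughout = True
        waters_per_frame: list[set[int]] = []
        for fi in range(eject_idx, len(molecule_sets)):
            msf = molecule_sets[fi]
            midf = stable_maps[fi].get(sid)
            waters: set[int] = set()
            if midf is not None and msf.molecules[midf].species == "intact_trehalose":
                cl = cluster_sets[fi].cluster_of_molecule(midf)
                n_treh = sum(1 for m in cl.molecule_ids
                             if msf.molecules[m].species == "intact_trehalose")
                if n_treh > 1:
                    single_throughout = False
                for m in cl.molecule_ids:
                    if msf.molecules[m].species == "water":
                        waters.add(msf.stable_ids[m])
            else:
                single_throughout = False  # trehalose reacted or vanished
            waters_per_frame.append(waters)
            for w in waters:
                contact_frames.setdefault(w, []).append(fi)

        intervals: dict[int, list[tuple[float, float]]] = {}
        for w, fidx in contact_frames.items():
            runs: list[tuple[float, float]] = []
            start = prev = fidx[0]
            for f in fidx[1:]:
                if f == prev + 1:
                    prev = f
                else:
                    runs.append((times[start], times[prev]))
                    start = prev = f
            runs.append((times[start], times[prev]))
            intervals[w] = runs

        # stability: first frame (after ejection) with zero waters in contact,
        # tolerating up to allow_gap_frames consecutive empty frames
        t_eject = times[eject_idx]
        end_time = times[-1]
        gap = 0
        for k, waters in enumerate(waters_per_frame):
            if waters:
                gap = 0
            else:
                gap += 1
                if gap > allow_gap_frames:
                    end_time = times[eject_idx + k - gap + 1]
                    break
        stable_duration = end_time - t_eject
        final_count = len(waters_per_frame[-1])
        traces.append(ComplexTrace(sid, t_eject, intervals, stable_duration,
                                   final_count, single_throughout))
    return traces


def apply_stability_filter(traces: list[ComplexTrace],
                           min_stable: float = DEFAULT_MIN_STABLE,
                           max_final_waters: int = DEFAULT_MAX_FINAL_WATERS
                           ) -> int:
    """Set each trace's ``included`` flag; return the included count.

    Included ⇔ stable for at least ``min_stable`` ps, at most
    ``max_final_waters`` waters at the last frame, and exactly one trehalose
    throughout. Complexes that end bare but were stable long enough are kept
    and flagged ``bare_at_end``.
    """
    count = 0
    for tr in traces:
        tr.included = (tr.stable_duration >= min_stable
                       and tr.final_water_count <= max_final_waters
                       and tr.single_trehalose_throughout)
        tr.flags = [f for f in tr.flags if f != "bare_at_end"]
        if tr.included and tr.final_water_count == 0:
            tr.flags.append("bare_at_end")
        count += tr.included
    return count


def sweep_cutoffs(traces: list[ComplexTrace], min_stable_grid,
                  max_final_grid) -> pd.DataFrame:
    """Included-complex counts over a grid of filter settings.

    Returns a tidy frame with columns ``min_stable``, ``max_final_waters``,
    ``included``; counts are non-increasing along the ``min_stable`` axis.
    The traces' ``included`` flags are restored afterwards.
    """
    min_stable_grid = list(min_stable_grid)
    max_final_grid = list(max_final_grid)
    if not min_stable_grid or not max_final_grid:
        raise ValueError("cutoff grids must be non-empty")
    saved = [(tr.included, list(tr.flags)) for tr in traces]
    rows = []
    for ms in min_stable_grid:
        for mf in max_final_grid:
            rows.append({"min_stable": ms, "max_final_waters": mf,
                         "included": apply_stability_filter(traces, ms, mf)})
    for tr, (inc, flags) in zip(traces, saved):
        tr.included, tr.flags = inc, flags
    return pd.DataFrame(rows)


def contact_time_map(traces: list[ComplexTrace],
                     first_molecule_set: MoleculeSet,
                     min_display: float = DEFAULT_MIN_DISPLAY) -> pd.DataFrame:
    """Map complex-forming waters back to their initial projectile positions.

    For every water appearing in any trace with summed contact duration of at
    least ``min_display`` ps, emit its molecular center-of-mass position in
    the first frame together with the duration. Waters with no molecule in
    the first frame (sample-derived or re-identified) are tagged
    ``sample-origin`` and emitted with NaN coordinates.
    """
    smap = _stable_map(first_molecule_set)
    frame = first_molecule_set.frame
    totals: dict[int, float] = {}
    for tr in traces:
        for w in tr.contact_intervals:
            totals[w] = totals.get(w, 0.0) + tr.total_contact(w)
    rows = []
    for w, dur in sorted(totals.items()):
        if dur < min_display:
            continue
        mid = smap.get(w)
        if mid is not None and first_molecule_set.molecules[mid].species == "water":
            r = first_molecule_set.molecule_rows(mid)
            m = frame.masses()[r]
            com = (m[:, None] * frame.positions[r]).sum(axis=0) / m.sum()
            origin = "projectile"
        else:
            com = np.full(3, np.nan)
            origin = "sample-origin"
        rows.append({"water_stable_id": w, "x0": com[0], "y0": com[1],
                     "z0": com[2], "contact_duration": dur, "origin": origin})
    return pd.DataFrame(rows, columns=["water_stable_id", "x0", "y0", "z0",
                                       "contact_duration", "origin"])
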