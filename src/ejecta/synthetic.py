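"""Synthetic sputtering scenes with planted ground truth.

Real inputs to this pipeline are reactive-MD trajectories of a 60 nm
trehalose hemisphere hit by a 20 keV water cluster — far beyond desk scale
and with no public accession. This module builds toy scenes whose kinematics
are *scripted* (ballistic motion, no forces): template trehalose molecules on
a flat-topped sample, a water-cluster projectile arriving at 45° in the xz
plane, scripted ejections crossing the 15 nm sputter height mid-way between
two frames, scripted water detachments at mid-interval times, and scripted
C–O scissions splitting a trehalose into the two half-sugar fragments
(C6H11O5 + C6H11O6). Bond orders are 0.9 within molecules and absent between
them, so the 0.3 bond-order threshold is unambiguous.

Alongside the trajectory the generator emits a :class:`Manifest` of expected
truths (sputter labels, categories, yields, complex stable durations, contact
durations, initial water positions) derived from the scene script alone — the
tests compare pipeline output against it end to end. Scenes are deterministic
under their seed; the seed only jitters placements, never the planted truths.

The module also builds the cross-section fixtures for the electron Monte
Carlo: analytic toy tables whose ionization-count distribution has a closed
form, and a clearly SYNTHETIC stand-in for realistic liquid-water tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .electron_mc import CrossSectionTable, ProcessTable
from .trajectory import BondTable, Frame, Trajectory
from .units import KE_AMU_NM2_PS2_TO_EV, atomic_mass

WATER_MASS = 2 * atomic_mass("H") + atomic_mass("O")
TREHALOSE_MASS = 12 * atomic_mass("C") + 22 * atomic_mass("H") + 11 * atomic_mass("O")


class GenerationError(RuntimeError):
    """Raised when a scene script produces an invalid geometry."""


# ---------------------------------------------------------------------------
# molecular templates


def trehalose_template() -> tuple[np.ndarray, list[str], np.ndarray]:
    """Fixed 45-atom C12H22O11 arrangement on a 0.15 nm grid.

    Returns (positions (45,3) nm, elements, chain bonds (44,2) of local atom
    indices). The element order is chosen so that cutting the chain bond
    (21, 22) yields the two ring-scission fragments C6H11O5 and C6H11O6.
    Internal geometry is irrelevant to the census except for spatial extent
    (≈0.45 × 0.45 × 0.30 nm, well inside a 1.2 nm bounding sphere).
    """
    pos = []
    for k in range(45):
        z, rem = divmod(k, 16)
        y, x = divmod(rem, 4)
        pos.append((0.15 * x, 0.15 * y, 0.15 * z))
    elements = (["C"] * 6 + ["O"] * 5 + ["H"] * 11
                + ["C"] * 6 + ["O"] * 6 + ["H"] * 11)
    bonds = np.array([(i, i + 1) for i in range(44)], dtype=np.int64)
    return np.array(pos), elements, bonds

#: local index pair whose removal splits the template into the two fragments
SCISSION_BOND = (21, 22)


def water_template() -> tuple[np.ndarray, list[str], np.ndarray]:
    """O + 2H water template (0.1 nm bonds along ±y)."""
    pos = np.array([(0.0, 0.0, 0.0), (0.0, 0.1, 0.0), (0.0, -0.1, 0.0)])
    return pos, ["O", "H", "H"], np.array([(0, 1), (0, 2)], dtype=np.int64)


_TREH_POS, _TREH_EL, _TREH_BONDS = trehalose_template()
_WAT_POS, _WAT_EL, _WAT_BONDS = water_template()
_TREH_TOP = 0.30          # local z of the template's top layer
_ATTACH_DZ = 0.25         # adjoining water sits 0.25 nm above a top atom
_TREH_SPAN_X = 0.70       # x offset between trehaloses placed in contact
_DETACH_DZ = 0.45         # extra z offset of a detached water (> 0.5 total gap)


# ---------------------------------------------------------------------------
# scene specification


@dataclass
class ScriptedEvent:
    """One scripted ejection (or retention) at its own surface site.

    ``water_detach_times`` has one entry per adjoining water; ``math.inf``
    means the water never detaches. ``eject_velocity_z = 0`` keeps the
    molecule in place (a retained event). For sputtered events the generator
    overrides ``eject_velocity_z`` so the 15 nm height is crossed mid-way
    between two frames (set ``sputter_cross_time`` to pick the frame).
    """

    kind: str = "trehalose"            # "trehalose" or "water_blob"
    n_trehalose: int = 1
    n_waters: int = 0                  # adjoining (or blob) waters
    eject_time: float = 15.0           # ps, a frame time of the impact phase
    eject_velocity_z: float = 0.0      # nm/ps; 0 → retained
    sputter_cross_time: float | None = None   # ps, frame at which sputtered
    water_detach_times: tuple = ()
    fragment_time: float | None = None  # ps; scission of one trehalose


@dataclass
class SceneSpec:
    """Stated world of one synthetic impact.

    Defaults mirror the simulated setup where one exists: hemisphere diameter
    60 nm, 45° incidence in the xz plane, 20 keV total projectile energy,
    75 ps impact phase and 900 ps extended phase. Frame cadences and the toy
    projectile size are generator choices (the real save cadence is not
    stated); 15 ps keeps full scenes around a hundred frames.
    """

    events: list[ScriptedEvent] = field(default_factory=list)
    hemisphere_diameter: float = 60.0
    projectile_size: int = 32
    projectile_energy: float = 20000.0   # eV total
    incidence_angle_deg: float = 45.0
    n_decoy_molecules: int = 4           # untouched sample trehaloses
    impact_end: float = 75.0
    extended_end: float = 900.0
    impact_cadence: float = 15.0
    extended_cadence: float = 15.0
    lane_spacing: float = 3.0
    surface_z: float = 30.0              # z of the sample top plane
    seed: int = 0

    def frame_times(self) -> np.ndarray:
        imp = np.arange(0.0, self.impact_end + 1e-9, self.impact_cadence)
        ext = np.arange(self.impact_end + self.extended_cadence,
                        self.extended_end + 1e-9, self.extended_cadence)
        return np.concatenate([imp, ext])


@dataclass
class ExpectedWater:
    atom_ids: np.ndarray
    initial_com: np.ndarray          # position at t = 0 (projectile frame)
    detach_time: float               # scripted, may be inf
    contact_duration: float | None   # planted trace duration (None: no trace)


@dataclass
class ExpectedEvent:
    """Planted truth for one scripted event."""

    kind: str
    trehalose_atom_ids: list[np.ndarray]
    waters: list[ExpectedWater]
    sputtered: bool
    category: str | None             # census category or "water"/None
    category_mass: float             # amu allocated to that category at eval
    ejection_time: float | None      # first sputtered frame (ps)
    stable_duration: float | None    # planted complex lifetime (ps)
    final_water_count: int | None
    included: bool | None            # survives the 320 ps / ≤1-water filter
    scission_time: float | None      # first frame showing the fragmentation


@dataclass
class Manifest:
    """Ground truth of a generated scene, derived from the script alone."""

    z0: float
    eval_time: float
    frame_times: np.ndarray
    sample_atom_ids: np.ndarray
    projectile_atom_ids: np.ndarray
    atom_count: int
    events: list[ExpectedEvent]
    yields: dict[str, float]            # category -> trehalose-mass units
    water_yield: float                  # pure-water tally, same units
    n_sputtered_molecules: int          # molecules in sputtered clusters at eval
    n_included_complexes: int
    reference_mass: float = 342.3


# ---------------------------------------------------------------------------
# scene construction


class _Assembly:
    """A rigid group of molecules sharing one scripted motion."""

    def __init__(self):
        self.molecules: list[dict] = []   # local pos, elements, bonds, ids

    def add_molecule(self, offset, pos, elements, bonds, next_id):
        ids = np.arange(next_id, next_id + len(pos), dtype=np.int64)
        self.molecules.append({
            "offset": np.asarray(offset, dtype=float),
            "pos": pos, "elements": list(elements), "bonds": bonds,
            "ids": ids,
        })
        return next_id + len(pos)


def _first_frame_at_or_after(times: np.ndarray, t: float) -> float:
    idx = np.searchsorted(times, t - 1e-9)
    if idx >= len(times):
        return float(times[-1])
    return float(times[idx])


def build_scene(spec: SceneSpec) -> tuple[Trajectory, list[BondTable], Manifest]:
    """Realize a scene spec as (trajectory, bond tables, manifest).

    Every scripted event occupies its own surface "lane" along x and ejects
    straight up, so ejecta never interact across events. Molecules closer
    than 0.1 nm across molecule boundaries abort generation.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.frame_times()
    eval_time = _first_frame_at_or_after(times, spec.impact_end)
    z0 = spec.surface_z
    treh_origin_z = z0 - _TREH_TOP

    half = spec.hemisphere_diameter / 2.0
    n_lanes = len(spec.events) + spec.n_decoy_molecules
    if (n_lanes - 1) * spec.lane_spacing > 2 * half:
        raise GenerationError("too many events for the sample diameter")
    lane_x = -0.5 * (n_lanes - 1) * spec.lane_spacing \
        + spec.lane_spacing * np.arange(n_lanes)

    next_id = 1
    assemblies: list[dict] = []   # assembly dicts with motion scripts
    sample_ids: list[np.ndarray] = []
    manifest_events: list[ExpectedEvent] = []

    # --- scripted events, one lane each -----------------------------------
    ball_members: list[dict] = []     # adjoining waters that start in the ball
    for ev_idx, ev in enumerate(spec.events):
        jitter = np.array([rng.uniform(-0.02, 0.02),
                           rng.uniform(-0.02, 0.02), 0.0])
        base = np.array([lane_x[ev_idx], 0.0, treh_origin_z]) + jitter
        asm = _Assembly()
        treh_ids: list[np.ndarray] = []
        if ev.kind == "trehalose":
            if ev.n_trehalose < 1:
                raise GenerationError("trehalose event needs n_trehalose >= 1")
            if ev.n_waters > 4 * ev.n_trehalose:
                raise GenerationError("at most 4 adjoining waters per trehalose")
            for k in range(ev.n_trehalose):
                nid0 = next_id
                next_id = asm.add_molecule(
                    base + np.array([k * _TREH_SPAN_X, 0.0, 0.0]),
                    _TREH_POS, _TREH_EL, _TREH_BONDS, next_id)
                treh_ids.append(np.arange(nid0, next_id, dtype=np.int64))
                sample_ids.append(treh_ids[-1])
        elif ev.kind == "water_blob":
            if ev.n_waters < 1:
                raise GenerationError("water blob needs waters")
        else:
            raise GenerationError(f"unknown event kind {ev.kind!r}")

        water_ids: list[np.ndarray] = []
        attach_offsets: list[np.ndarray] = []
        for w in range(ev.n_waters):
            nid0 = next_id
            if ev.kind == "trehalose":
                host, slot = divmod(w, 4)
                off = np.array([host * _TREH_SPAN_X + 0.15 * slot, 0.0,
                                _TREH_TOP + _ATTACH_DZ])
            else:
                off = np.array([0.25 * w, 0.0, _TREH_TOP])
            next_id = asm.add_molecule(base + off, _WAT_POS, _WAT_EL,
                                       _WAT_BONDS, next_id)
            water_ids.append(np.arange(nid0, next_id, dtype=np.int64))
            attach_offsets.append(base + off)

        # eject velocity: cross the sputter height mid-way between frames
        vz = ev.eject_velocity_z
        cross = ev.sputter_cross_time
        sputtered = cross is not None
        if sputtered:
            cross = _first_frame_at_or_after(times, cross)
            if cross <= ev.eject_time:
                raise GenerationError("sputter_cross_time must follow eject_time")
            # COM depth below z0 of the whole co-moving assembly
            com_num = np.zeros(3)
            com_den = 0.0
            for mol in asm.molecules:
                m = np.array([atomic_mass(e) for e in mol["elements"]])
                com_num += (m[:, None] * (mol["offset"] + mol["pos"])).sum(axis=0)
                com_den += m.sum()
            depth = z0 - (com_num / com_den)[2]
            cadence = times[1] - times[0] if len(times) > 1 else 1.0
            # use the local inter-frame gap at the crossing
            ci = int(np.searchsorted(times, cross - 1e-9))
            gap = times[ci] - times[ci - 1] if ci > 0 else cadence
            vz = (15.0 + depth) / (cross - gap / 2.0 - ev.eject_time)

        if ev.fragment_time is not None and (ev.kind != "trehalose"
                                             or ev.n_trehalose != 1
                                             or ev.n_waters > 0):
            raise GenerationError("fragmentation is only scripted for a bare "
                                  "single-trehalose event")
        water_detach = {}
        if ev.kind == "trehalose":
            water_detach = {tuple(wid): (t, aoff) for wid, t, aoff in
                            zip(map(tuple, water_ids),
                                list(ev.water_detach_times) + [math.inf] * 99,
                                attach_offsets)}
            for wid in water_ids:
                ball_members.append({"ids": tuple(wid),
                                     "arrive": ev.eject_time})
        assemblies.append({
            "assembly": asm, "eject_time": ev.eject_time, "vz": vz,
            "fragment_time": ev.fragment_time,
            "water_detach": water_detach,
        })

        # ---- manifest bookkeeping ----
        detach = list(ev.water_detach_times) + [math.inf] * (ev.n_waters
                                                             - len(ev.water_detach_times))
        frag = ev.fragment_time is not None and ev.kind == "trehalose"
        if not sputtered:
            category, cat_mass, t_eject = None, 0.0, None
        elif ev.kind == "water_blob":
            category, cat_mass, t_eject = "water", ev.n_waters * WATER_MASS, cross
        elif frag and ev.n_trehalose == 1 and ev.n_waters == 0:
            category, cat_mass, t_eject = "fragments", TREHALOSE_MASS, cross
        else:
            single = ev.n_trehalose == 1
            solvated = ev.n_waters > 0
            category = (("single_" if single else "multiple_")
                        + ("solvated" if solvated else "bare"))
            cat_mass = ev.n_trehalose * TREHALOSE_MASS + ev.n_waters * WATER_MASS
            t_eject = cross
        has_trace = (sputtered and ev.kind == "trehalose" and not frag
                     and ev.n_trehalose == 1 and ev.n_waters >= 1)
        stable_duration = final_count = included = None
        exp_waters = []
        for wid, td in zip(water_ids, detach):
            dur = None
            if has_trace:
                last_attached = times[times < td][-1] if np.any(times < td) \
                    else t_eject
                dur = float(max(last_attached - t_eject, 0.0))
            exp_waters.append(ExpectedWater(np.asarray(wid), np.zeros(3),
                                            td, dur))
        if has_trace:
            finite = [td for td in detach if math.isfinite(td)]
            if len(finite) == len(detach) and detach:
                t_zero = _first_frame_at_or_after(times, max(finite))
            else:
                t_zero = float(times[-1])
            stable_duration = float(t_zero - t_eject)
            final_count = sum(1 for td in detach if td > times[-1])
            included = stable_duration >= 320.0 and final_count <= 1
        scission = (_first_frame_at_or_after(times, ev.fragment_time)
                    if frag else None)
        manifest_events.append(ExpectedEvent(
            ev.kind, treh_ids, exp_waters, sputtered, category, cat_mass,
            t_eject, stable_duration, final_count, included, scission))

    # --- decoy sample molecules -------------------------------------------
    for d in range(spec.n_decoy_molecules):
        jitter = np.array([rng.uniform(-0.02, 0.02),
                           rng.uniform(-0.02, 0.02), 0.0])
        base = np.array([lane_x[len(spec.events) + d], 0.0, treh_origin_z]) + jitter
        asm = _Assembly()
        nid0 = next_id
        next_id = asm.add_molecule(base, _TREH_POS, _TREH_EL, _TREH_BONDS,
                                   next_id)
        sample_ids.append(np.arange(nid0, next_id, dtype=np.int64))
        assemblies.append({"assembly": asm, "eject_time": math.inf, "vz": 0.0,
                           "fragment_time": None, "water_detach": {}})

    # --- projectile ball ---------------------------------------------------
    n_adjoin = len(ball_members)
    n_filler = max(spec.projectile_size - n_adjoin, 0)
    ball_center0 = np.array([0.0, -6.0, z0 + 10.0])
    ball_center1 = np.array([0.0, -6.0, z0 + 2.0])
    ball_jitter = np.array([rng.uniform(-0.02, 0.02),
                            rng.uniform(-0.02, 0.02), 0.0])
    # cubic grid of slots, spacing 0.45 nm, centered on the ball
    n_slots = n_adjoin + n_filler
    side = int(np.ceil(n_slots ** (1 / 3)))
    slots = []
    for k in range(side ** 3):
        zi, rem = divmod(k, side * side)
        yi, xi = divmod(rem, side)
        slots.append((np.array([xi, yi, zi]) - (side - 1) / 2.0) * 0.45)
    slots = np.array(slots)
    # adjoining waters take slots ordered by x; events are laid out in lane
    # order, so transit paths toward the lanes stay roughly parallel
    order = np.lexsort((slots[:, 2], slots[:, 1], slots[:, 0]))
    slots = slots[order]
    ball_slot_of = {b["ids"]: slots[i] for i, b in enumerate(ball_members)}
    filler_slots = slots[n_adjoin:n_slots]

    ball_asm = _Assembly()
    filler_ids: list[np.ndarray] = []
    for s in filler_slots:
        nid0 = next_id
        next_id = ball_asm.add_molecule(s, _WAT_POS, _WAT_EL, _WAT_BONDS,
                                        next_id)
        filler_ids.append(np.arange(nid0, next_id, dtype=np.int64))

    n_atoms = next_id - 1
    theta = math.radians(spec.incidence_angle_deg)
    # per-molecule speed giving the full projectile its total kinetic energy
    n_proj = n_adjoin + n_filler
    if n_proj > 0:
        ke_int = spec.projectile_energy / KE_AMU_NM2_PS2_TO_EV
        speed = math.sqrt(2.0 * ke_int / (n_proj * WATER_MASS))
        v_incidence = speed * np.array([math.sin(theta), 0.0, -math.cos(theta)])
    else:
        v_incidence = np.zeros(3)

    # --- frame assembly ----------------------------------------------------
    def ball_center(t: float) -> np.ndarray:
        f = min(t / 10.0, 1.0)
        return ball_center0 + f * (ball_center1 - ball_center0) + ball_jitter

    frames: list[Frame] = []
    bond_tables: list[BondTable] = []
    all_elements = np.empty(n_atoms, dtype=object)

    for entry in assemblies + [{"assembly": ball_asm}]:
        for mol in entry["assembly"].molecules:
            for local, aid in enumerate(mol["ids"]):
                all_elements[int(aid) - 1] = mol["elements"][local]

    for t in times:
        pos = np.empty((n_atoms, 3))
        vel = np.zeros((n_atoms, 3))
        for entry in assemblies:
            te, vz = entry["eject_time"], entry["vz"]
            dt = max(t - te, 0.0) if math.isfinite(te) else 0.0
            moving = math.isfinite(te) and t >= te and vz != 0.0
            shift = np.array([0.0, 0.0, vz * dt])
            v_now = np.array([0.0, 0.0, vz]) if moving else np.zeros(3)
            for mol in entry["assembly"].molecules:
                ids = tuple(mol["ids"])
                rows = mol["ids"] - 1
                detach = entry["water_detach"].get(ids)
                if detach is not None:
                    td, aoff = detach
                    if t < te:           # transit from the projectile ball
                        slot = ball_slot_of[ids]
                        start = ball_center(0.0) + slot
                        end = aoff
                        f = t / te if te > 0 else 1.0
                        base_pos = start + f * (end - start)
                        pos[rows] = base_pos + mol["pos"]
                        vel[rows] = ((end - start) / te if te > 0
                                     else np.zeros(3))
                        continue
                    extra = np.zeros(3)
                    v_extra = np.zeros(3)
                    if t >= td:
                        extra = np.array([0.0, 0.0,
                                          _DETACH_DZ + 0.05 * (t - td)])
                        v_extra = np.array([0.0, 0.0, 0.05])
                    pos[rows] = mol["offset"] + shift + extra + mol["pos"]
                    vel[rows] = v_now + v_extra
                else:
                    pos[rows] = mol["offset"] + shift + mol["pos"]
                    vel[rows] = v_now
        bc = ball_center(t)
        for mol in ball_asm.molecules:
            rows = mol["ids"] - 1
            pos[rows] = bc + mol["offset"] + mol["pos"]
            if 0.0 < t < 10.0:
                vel[rows] = (ball_center1 - ball_center0) / 10.0
        if t == 0.0:
            # physical incidence velocity of the whole projectile at launch
            for mol in ball_asm.molecules:
                vel[mol["ids"] - 1] = v_incidence
            for b in ball_members:
                vel[np.array(b["ids"]) - 1] = v_incidence

        ids = np.arange(1, n_atoms + 1, dtype=np.int64)
        frames.append(Frame(float(t), ids, all_elements.copy(), pos, vel))

        pairs = []
        orders = []
        for entry in assemblies:
            ft = entry["fragment_time"]
            cut = (ft is not None and t >= ft)
            first_mol = entry["assembly"].molecules[0] if entry["assembly"].molecules else None
            for mol in entry["assembly"].molecules:
                for (a, b) in mol["bonds"]:
                    if (cut and mol is first_mol
                            and (a, b) == SCISSION_BOND):
                        continue
                    pairs.append((int(mol["ids"][a]), int(mol["ids"][b])))
                    orders.append(0.9)
        for mol in ball_asm.molecules:
            for (a, b) in mol["bonds"]:
                pairs.append((int(mol["ids"][a]), int(mol["ids"][b])))
                orders.append(0.9)
        bond_tables.append(BondTable(float(t), np.array(pairs, dtype=np.int64),
                                     np.array(orders)))

    trajectory = Trajectory(frames, frame_interval=float(spec.impact_cadence))
    _check_overlaps(trajectory, assemblies, ball_asm)

    # fill manifest water initial positions from frame 0
    f0 = frames[0]
    masses = f0.masses()
    for mev in manifest_events:
        for w in mev.waters:
            rows = w.atom_ids - 1
            m = masses[rows]
            w.initial_com = (m[:, None] * f0.positions[rows]).sum(axis=0) / m.sum()

    yields = {c: 0.0 for c in ("single_bare", "multiple_bare",
                               "single_solvated", "multiple_solvated",
                               "fragments")}
    water_yield = 0.0
    n_sput_mol = 0
    n_included = 0
    for mev in manifest_events:
        if not mev.sputtered:
            continue
        if mev.category == "water":
            water_yield += mev.category_mass / 342.3
            n_sput_mol += len(mev.waters)
        else:
            yields[mev.category] += mev.category_mass / 342.3
            n_treh_mols = (2 if mev.category == "fragments"
                           else len(mev.trehalose_atom_ids))
            n_sput_mol += n_treh_mols + len(mev.waters)
        if mev.included:
            n_included += 1

    manifest = Manifest(
        z0=z0, eval_time=eval_time, frame_times=times,
        sample_atom_ids=np.concatenate(sample_ids) if sample_ids
        else np.empty(0, dtype=np.int64),
        projectile_atom_ids=np.concatenate(
            [np.array(b["ids"]) for b in ball_members]
            + [fid for fid in filler_ids]) if (ball_members or filler_ids)
        else np.empty(0, dtype=np.int64),
        atom_count=n_atoms, events=manifest_events, yields=yields,
        water_yield=water_yield, n_sputtered_molecules=n_sput_mol,
        n_included_complexes=n_included)
    return trajectory, bond_tables, manifest


def _check_overlaps(trajectory: Trajectory, assemblies, ball_asm,
                    min_gap: float = 0.1) -> None:
    """Abort when any two molecules come closer than ``min_gap`` nm."""
    mol_label = np.empty(len(trajectory.frames[0]), dtype=np.intp)
    label = 0
    for entry in assemblies + [{"assembly": ball_asm}]:
        for mol in entry["assembly"].molecules:
            mol_label[mol["ids"] - 1] = label
            label += 1
    for frame in trajectory.frames:
        tree = cKDTree(frame.positions)
        pairs = tree.query_pairs(min_gap, output_type="ndarray")
        if len(pairs):
            cross = mol_label[pairs[:, 0]] != mol_label[pairs[:, 1]]
            if np.any(cross):
                i, j = pairs[cross][0]
                raise GenerationError(
                    f"molecules overlap (<{min_gap} nm) at t={frame.time} ps "
                    f"between atoms {frame.ids[i]} and {frame.ids[j]}")


# ---------------------------------------------------------------------------
# randomized scene specs (for property-style end-to-end tests)


def random_scene_spec(seed: int, max_events: int = 6) -> SceneSpec:
    """A randomized but always-valid scene script.

    Event kinds, categories, ejection frames, detachment times and decoy
    counts all vary with the seed; detachment times sit mid-way between
    frames so every planted truth is exactly recoverable at the scene's
    cadence.
    """
    rng = np.random.default_rng(seed)
    spec = SceneSpec(seed=int(rng.integers(0, 2 ** 31 - 1)))
    times = spec.frame_times()
    imp = times[(times > 0) & (times <= spec.impact_end)]
    ext = times[times > spec.impact_end]
    n_events = int(rng.integers(2, max_events + 1))
    events = []
    for _ in range(n_events):
        kind = rng.choice(["single_solvated", "single_bare", "multi",
                           "fragment", "retained", "blob"],
                          p=[0.35, 0.1, 0.15, 0.1, 0.15, 0.15])
        t_eject = float(rng.choice(imp[:-2]))
        later = imp[imp > t_eject + spec.impact_cadence / 2]
        cross = float(rng.choice(later))
        if kind == "blob":
            events.append(ScriptedEvent(kind="water_blob",
                                        n_waters=int(rng.integers(2, 5)),
                                        eject_time=t_eject,
                                        sputter_cross_time=cross))
            continue
        if kind == "retained":
            events.append(ScriptedEvent(n_trehalose=1,
                                        n_waters=int(rng.integers(0, 3)),
                                        eject_time=t_eject,
                                        water_detach_times=(math.inf,) * 4))
            continue
        if kind == "fragment":
            ft = float(rng.choice(imp[imp <= t_eject]))
            events.append(ScriptedEvent(n_trehalose=1, n_waters=0,
                                        eject_time=t_eject,
                                        sputter_cross_time=cross,
                                        fragment_time=ft - spec.impact_cadence / 2))
            continue
        n_treh = int(rng.integers(2, 4)) if kind == "multi" else 1
        n_wat = (int(rng.integers(1, 4)) if kind != "single_bare"
                 else 0)
        if kind == "multi" and rng.uniform() < 0.5:
            n_wat = 0
        detach = []
        for _ in range(n_wat):
            if rng.uniform() < 0.3:
                detach.append(math.inf)
            else:
                detach.append(float(rng.choice(ext[:-1]))
                              + spec.extended_cadence / 2)
        events.append(ScriptedEvent(n_trehalose=n_treh, n_waters=n_wat,
                                    eject_time=t_eject,
                                    sputter_cross_time=cross,
                                    water_detach_times=tuple(detach)))
    spec.events = events
    spec.n_decoy_molecules = int(rng.integers(1, 5))
    spec.projectile_size = int(rng.integers(24, 48))
    return spec


# ---------------------------------------------------------------------------
# cross-section fixtures for the electron Monte Carlo


def make_toy_cross_sections(mean_free_path: float, ionization_loss: float,
                            variant: str = "ionization_only",
                            elastic_mean_free_path: float | None = None
                            ) -> CrossSectionTable:
    """Analytic toy tables whose ionization-count law is closed-form.

    ``ionization_only``: constant ionization rate 1/``mean_free_path`` for
    E ≥ ``ionization_loss``, zero-energy secondaries, no deflection — along a
    chord of length d the ionization count is a Poisson(d/λ) censored at the
    energy cap. ``elastic_ionization`` adds constant-rate isotropic elastic
    scattering. ``inert`` has no interactions at all.
    """
    if variant == "inert":
        return CrossSectionTable({}, ionization_threshold=ionization_loss,
                                 angular_rule="straight",
                                 metadata={"variant": variant})
    if mean_free_path <= 0:
        raise ValueError("mean_free_path must be positive")
    c = 1.0 / mean_free_path
    grid = np.array([ionization_loss, 1e4])
    tables = {"ionization": ProcessTable(grid, np.array([c, c]))}
    if variant == "elastic_ionization":
        ce = 1.0 / (elastic_mean_free_path or mean_free_path)
        tables["elastic"] = ProcessTable(np.array([0.0, 1e4]),
                                         np.array([ce, ce]))
        angular = "isotropic"
    elif variant == "ionization_only":
        angular = "straight"
    else:
        raise ValueError(f"unknown toy variant {variant!r}")
    return CrossSectionTable(
        tables, ionization_threshold=ionization_loss,
        secondary_rule="fixed", secondary_params={"energy": 0.0},
        angular_rule=angular,
        metadata={"variant": variant, "mean_free_path": mean_free_path,
                  "loss_per_ionization": ionization_loss})


#: number density of liquid water, nm^-3
WATER_NUMBER_DENSITY = 33.4


def make_synthetic_water_table() -> CrossSectionTable:
    """SYNTHETIC stand-in for realistic liquid-water cross sections.

    Magnitudes follow standard low-energy electron/water data (cross sections
    in 1e-16 cm² converted with n = 33.4 nm⁻³): ionization peaks near
    1.6e-16 cm² around 100 eV above a 13 eV effective threshold, excitation
    loses 8 eV per event, and elastic scattering uses momentum-transfer-scale
    cross sections with isotropic deflection. This table is NOT a published
    model and is shipped only so the nanodosimetry campaign can run without
    external data; absolute numbers derived from it carry that caveat.
    """
    E = np.array([11.0, 15.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0])
    to_imfp = 1e-2 * WATER_NUMBER_DENSITY          # 1e-16 cm² -> nm⁻¹
    elastic = np.array([12.0, 9.0, 7.0, 4.5, 3.5, 2.5, 2.0, 1.7]) * to_imfp
    excitation = np.array([0.3, 0.6, 0.8, 0.8, 0.7, 0.55, 0.45, 0.4]) * to_imfp
    ionization = np.array([0.0, 0.05, 0.4, 0.9, 1.2, 1.5, 1.6, 1.6]) * to_imfp
    return CrossSectionTable(
        {"elastic": ProcessTable(E, elastic),
         "excitation": ProcessTable(E, excitation),
         "ionization": ProcessTable(E, ionization)},
        excitation_loss=8.0, ionization_threshold=13.0,
        secondary_rule="uniform", angular_rule="isotropic",
        metadata={"provenance": "synthetic stand-in, not a published model"})
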