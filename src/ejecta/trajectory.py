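"""Trajectory frames and per-frame bond tables.

This module defines the in-memory data model every later stage consumes and
reads/writes the two line-oriented text dialects used around reactive-MD
sputtering runs:

* a LAMMPS-dump-like columnar format for atom positions and velocities
  (``ITEM:`` headers, one atom per line, ``#`` comments allowed);
* bond tables carrying ReaxFF-style bond orders, either as a neighbor-list
  dialect (atom id, neighbor count, neighbor ids, bond orders) or as a
  simplified 3-column ``i j bond_order`` dialect convenient for fixtures.

Internally everything is nm / ps / amu / eV; readers convert on ingestion via
:class:`~ejecta.units.UnitMap`. Velocities are mandatory because the sputter
criterion needs the z component of the center-of-mass velocity. There is no
periodic-boundary handling anywhere: the simulated sample is a free hemisphere
in vacuum, so all distances are plain Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .units import UnitMap, atomic_mass

logger = logging.getLogger(__name__)

DEFAULT_ELEMENTS = ("H", "C", "O")

_REQUIRED_COLUMNS = ("id", "element", "x", "y", "z", "vx", "vy", "vz")


class ParseError(ValueError):
    """Raised for malformed trajectory or bond-table files; names the line."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass
class Frame:
    """One saved snapshot: atom ids, elements, positions (nm), velocities (nm/ps)."""

    time: float
    ids: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        n = len(self.ids)
        if not (len(self.elements) == n and len(self.positions) == n
                and len(self.velocities) == n):
            raise ValueError("frame arrays are not congruent in length")
        if len(np.unique(self.ids)) != n:
            raise ValueError(f"duplicate atom ids in frame at t={self.time} ps")
        self._index = {int(a): i for i, a in enumerate(self.ids)}
        self._masses = None

    def __len__(self) -> int:
        return len(self.ids)

    def rows_of(self, atom_ids) -> np.ndarray:
        """Row indices of the given atom ids (KeyError for unknown ids)."""
        return np.array([self._index[int(a)] for a in np.atleast_1d(atom_ids)],
                        dtype=np.intp)

    def masses(self) -> np.ndarray:
        """Per-atom standard atomic masses (amu), cached."""
        if self._masses is None:
            self._masses = np.array([atomic_mass(e) for e in self.elements])
        return self._masses


@dataclass
class Trajectory:
    """Time-ordered frames sharing one atom-id universe."""

    frames: list[Frame]
    frame_interval: float = 1.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory has no frames")
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        universe = set(map(int, self.frames[0].ids))
        for f in self.frames[1:]:
            if set(map(int, f.ids)) != universe:
                raise ValueError(
                    f"frame at t={f.time} ps does not share the atom-id universe")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def frame_at(self, time: float, atol: float = 1e-9) -> Frame:
        idx = int(np.argmin(np.abs(self.times - time)))
        if abs(self.frames[idx].time - time) > atol:
            raise KeyError(f"no frame at t={time} ps "
                           f"(nearest is {self.frames[idx].time} ps)")
        return self.frames[idx]

    def nearest_frame(self, time: float) -> Frame:
        return self.frames[int(np.argmin(np.abs(self.times - time)))]


@dataclass
class BondTable:
    """Bond-order records for one snapshot.

    ``pairs`` is an (M, 2) int array of atom-id pairs, ``orders`` the matching
    ReaxFF bond orders (dimensionless, 0–3). At most one record per unordered
    pair; orders must be non-negative and self-bonds are rejected.
    """

    time: float
    pairs: np.ndarray
    orders: np.ndarray

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.orders = np.asarray(self.orders, dtype=float).reshape(-1)
        if len(self.pairs) != len(self.orders):
            raise ValueError("pairs and orders differ in length")
        if np.any(self.orders < 0):
            raise ValueError(f"negative bond order in table at t={self.time} ps")
        if len(self.pairs):
            if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
                raise ValueError("self-bond (i == j) in bond table")
            canon = np.sort(self.pairs, axis=1)
            uniq = {(int(a), int(b)) for a, b in canon}
            if len(uniq) != len(canon):
                raise ValueError("duplicate unordered pair in bond table")

    def __len__(self) -> int:
        return len(self.orders)


# ---------------------------------------------------------------------------
# trajectory text format


def write_trajectory(trajectory: Trajectory, path, units: UnitMap = UnitMap(),
                     columns=_REQUIRED_COLUMNS) -> None:
    """Write a LAMMPS-dump-style text file (canonical text form)."""
    lu = units.length_to_nm
    tu = units.time_to_ps
    vu = units.velocity_to_nm_ps
    with open(path, "w") as fh:
        fh.write(f"# ejecta trajectory; units length={units.length} time={units.time}\n")
        for step, frame in enumerate(trajectory.frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{step}\n")
            fh.write("ITEM: TIME\n")
            fh.write(f"{frame.time / tu:.10g}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{len(frame)}\n")
            fh.write("ITEM: ATOMS " + " ".join(columns) + "\n")
            for i in range(len(frame)):
                vals = {
                    "id": str(int(frame.ids[i])),
                    "element": str(frame.elements[i]),
                    "x": f"{frame.positions[i, 0] / lu:.12g}",
                    "y": f"{frame.positions[i, 1] / lu:.12g}",
                    "z": f"{frame.positions[i, 2] / lu:.12g}",
                    "vx": f"{frame.velocities[i, 0] / vu:.12g}",
                    "vy": f"{frame.velocities[i, 1] / vu:.12g}",
                    "vz": f"{frame.velocities[i, 2] / vu:.12g}",
                }
                fh.write(" ".join(vals[c] for c in columns) + "\n")


def read_trajectory(path, units: UnitMap = UnitMap(),
                    frame_interval: float | None = None,
                    alphabet=DEFAULT_ELEMENTS) -> Trajectory:
    """Read a LAMMPS-dump-style file into a :class:`Trajectory`.

    Column order is taken from the ``ITEM: ATOMS`` header of each frame, so any
    ordering is accepted as long as the required columns (including the
    velocity components) are all present. Unknown ``ITEM:`` sections (e.g.
    ``BOX BOUNDS``) are skipped. Values are converted to nm/ps via ``units``.
    """
    lu = units.length_to_nm
    tu = units.time_to_ps
    vu = units.velocity_to_nm_ps
    alphabet = set(alphabet) if alphabet is not None else None

    with open(path) as fh:
        lines = fh.readlines()

    frames: list[Frame] = []
    i = 0
    n_lines = len(lines)

    def is_skippable(s: str) -> bool:
        s = s.strip()
        return not s or s.startswith("#")

    while i < n_lines:
        line = lines[i]
        if is_skippable(line):
            i += 1
            continue
        if not line.startswith("ITEM: TIMESTEP"):
            raise ParseError(path, i + 1, f"expected 'ITEM: TIMESTEP', got {line.strip()!r}")
        i += 1
        while i < n_lines and is_skippable(lines[i]):
            i += 1
        try:
            step = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(path, i + 1, "malformed TIMESTEP value") from None
        i += 1
        time = None
        natoms = None
        columns = None
        # headers until the ATOMS section
        while i < n_lines:
            line = lines[i]
            if is_skippable(line):
                i += 1
                continue
            if line.startswith("ITEM: TIME"):
                i += 1
                try:
                    time = float(lines[i].split()[0]) * tu
                except (ValueError, IndexError):
                    raise ParseError(path, i + 1, "malformed TIME value") from None
                i += 1
            elif line.startswith("ITEM: NUMBER OF ATOMS"):
                i += 1
                try:
                    natoms = int(lines[i].split()[0])
                except (ValueError, IndexError):
                    raise ParseError(path, i + 1, "malformed NUMBER OF ATOMS") from None
                i += 1
            elif line.startswith("ITEM: ATOMS"):
                columns = line.split()[2:]
                i += 1
                break
            elif line.startswith("ITEM:"):
                # unknown section: skip its data lines
                i += 1
                while i < n_lines and not lines[i].startswith("ITEM:"):
                    i += 1
            else:
                raise ParseError(path, i + 1, f"unexpected line {line.strip()!r}")
        if natoms is None or columns is None:
            raise ParseError(path, i, "frame header incomplete (missing NUMBER OF ATOMS or ATOMS)")
        missing = [c for c in _REQUIRED_COLUMNS if c not in columns]
        if missing:
            what = ", ".join(missing)
            raise ParseError(path, i, f"ATOMS header missing required column(s): {what}"
                             + (" (velocities are required by the sputter criterion)"
                                if any(c.startswith("v") for c in missing) else ""))
        col = {c: k for k, c in enumerate(columns)}
        if time is None:
            if frame_interval is None:
                time = float(step)  # fall back: timestep index as time
            else:
                time = float(step) * frame_interval
        ids = np.empty(natoms, dtype=np.int64)
        elements = np.empty(natoms, dtype=object)
        pos = np.empty((natoms, 3))
        vel = np.empty((natoms, 3))
        for k in range(natoms):
            while i < n_lines and is_skippable(lines[i]):
                i += 1
            if i >= n_lines:
                raise ParseError(path, n_lines, "unexpected end of file inside ATOMS block")
            parts = lines[i].split()
            if len(parts) < len(columns):
                raise ParseError(path, i + 1, "atom line has too few columns")
            try:
                ids[k] = int(parts[col["id"]])
                elements[k] = parts[col["element"]]
                pos[k] = [float(parts[col[c]]) for c in ("x", "y", "z")]
                vel[k] = [float(parts[col[c]]) for c in ("vx", "vy", "vz")]
            except ValueError:
                raise ParseError(path, i + 1, "malformed atom line") from None
            i += 1
        if alphabet is not None:
            bad = sorted(set(elements) - alphabet)
            if bad:
                raise ParseError(path, i, f"element(s) {bad} outside the declared alphabet")
        try:
            frames.append(Frame(time, ids, elements, pos * lu, vel * vu))
        except ValueError as exc:
            raise ParseError(path, i, str(exc)) from None

    if not frames:
        raise ParseError(path, 1, "no frames found")
    frames.sort(key=lambda f: f.time)
    if frame_interval is None:
        times = np.array([f.time for f in frames])
        frame_interval = float(np.min(np.diff(times))) if len(frames) > 1 else 1.0
    return Trajectory(frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# bond-table text formats


def write_bond_tables(tables: list[BondTable], path, dialect: str = "pair") -> None:
    """Write bond tables; ``dialect`` is ``'pair'`` (i j bo) or ``'reaxff'``
    (per-atom neighbor lists, each bond emitted in both directions)."""
    if dialect not in ("pair", "reaxff"):
        raise ValueError(f"unknown bond dialect {dialect!r}")
    with open(path, "w") as fh:
        for table in tables:
            if dialect == "pair":
                fh.write(f"# time {table.time:.10g}\n")
                for (a, b), bo in zip(table.pairs, table.orders):
                    fh.write(f"{int(a)} {int(b)} {bo:.10g}\n")
            else:
                fh.write(f"# Timestep {table.time:.10g}\n")
                neigh: dict[int, list[tuple[int, float]]] = {}
                for (a, b), bo in zip(table.pairs, table.orders):
                    neigh.setdefault(int(a), []).append((int(b), float(bo)))
                    neigh.setdefault(int(b), []).append((int(a), float(bo)))
                for a in sorted(neigh):
                    ns = sorted(neigh[a])
                    ids = " ".join(str(b) for b, _ in ns)
                    bos = " ".join(f"{bo:.10g}" for _, bo in ns)
                    fh.write(f"{a} {len(ns)} {ids} {bos}\n".replace("  ", " "))
                fh.write("#\n")


def read_bond_tables(path, dialect: str = "auto") -> list[BondTable]:
    """Read bond tables from either dialect (auto-detected by header line)."""
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = [k for k, ln in enumerate(lines)
                  if ln.startswith("# time") or ln.startswith("# Timestep")]
    if not header_idx:
        raise ParseError(path, 1, "no '# time'/'# Timestep' frame headers found")
    tables = []
    header_idx.append(len(lines))
    for h, nxt in zip(header_idx[:-1], header_idx[1:]):
        head = lines[h].split()
        is_pair = head[1] == "time"
        if dialect == "pair" and not is_pair or dialect == "reaxff" and is_pair:
            raise ParseError(path, h + 1, f"header does not match dialect {dialect!r}")
        try:
            time = float(head[2])
        except (ValueError, IndexError):
            raise ParseError(path, h + 1, "malformed frame-time header") from None
        pairs: list[tuple[int, int]] = []
        orders: list[float] = []
        seen: dict[tuple[int, int], float] = {}
        for k in range(h + 1, nxt):
            s = lines[k].strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            try:
                if is_pair:
                    a, b, bo = int(parts[0]), int(parts[1]), float(parts[2])
                    records = [(a, b, bo)]
                else:
                    a, nb = int(parts[0]), int(parts[1])
                    if len(parts) != 2 + 2 * nb:
                        raise ValueError
                    records = [(a, int(parts[2 + j]), float(parts[2 + nb + j]))
                               for j in range(nb)]
            except (ValueError, IndexError):
                raise ParseError(path, k + 1, "malformed bond record") from None
            for a, b, bo in records:
                key = (min(a, b), max(a, b))
                if key in seen:
                    if is_pair or abs(seen[key] - bo) > 1e-9:
                        raise ParseError(path, k + 1,
                                         f"duplicate/conflicting record for pair {key}")
                    continue
                seen[key] = bo
                pairs.append(key)
                orders.append(bo)
        try:
            tables.append(BondTable(time,
                                    np.array(pairs, dtype=np.int64).reshape(-1, 2),
                                    np.array(orders)))
        except ValueError as exc:
            raise ParseError(path, h + 1, str(exc)) from None
    tables.sort(key=lambda t: t.time)
    return tables


def match_bonds_to_frame(trajectory: Trajectory, bond_tables: list[BondTable],
                         time: float) -> tuple[Frame, BondTable, float]:
    """Pair the frame at ``time`` with the nearest-in-time bond table.

    Returns ``(frame, table, gap)`` where ``gap`` is the absolute time offset
    between the two. Bond tables may be saved less often than frames; a gap
    larger than one ``frame_interval`` is logged as a warning.
    """
    if not bond_tables:
        raise ValueError("no bond tables supplied")
    frame = trajectory.frame_at(time)
    bt_times = np.array([t.time for t in bond_tables])
    j = int(np.argmin(np.abs(bt_times - frame.time)))
    gap = float(abs(bt_times[j] - frame.time))
    if gap > trajectory.frame_interval:
        logger.warning("bond table nearest to t=%.6g ps is %.6g ps away "
                       "(> frame interval %.6g ps)", frame.time, gap,
                       trajectory.frame_interval)
    return frame, bond_tables[j], gap
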