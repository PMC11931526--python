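"""Table-driven Monte Carlo electron transport in a nanoscale water sphere.

The physics is entirely contained in a :class:`CrossSectionTable` supplying
inverse mean free paths (nm⁻¹) on an energy grid for elastic scattering,
molecular excitation and ionization, plus the energy costs and the sampling
rules for secondary energies and scattering angles. The transport itself is
the standard competing-process scheme: free paths are exponential in the
total inverse MFP, the process is chosen proportionally to its rate, and
secondaries from ionization are cascaded with the same rules.

An electron terminates by leaving the sphere (escape, it carries its charge
away) or by dropping below the solvation threshold while inside (default
11 eV — it is then retained as a solvated electron). Every ionization is
assumed to produce one hydronium ion at the ionization point: in cryogenic
ice the nascent H2O⁺ protonates a neighbor within femtoseconds and proton
diffusion is frozen, so the hydronium count equals the ionization count and
hydronium positions equal ionization positions. The net cluster charge of an
event is (ionizations) − (electrons solvated inside); campaigns typically
select events with net charge +1, the charge state of a SIMS ice-cluster
projectile.

Energy bookkeeping is exact by construction: the primary energy always equals
deposited ionization-threshold + excitation losses plus the terminal kinetic
energies of every electron (escaped or solvated).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

PROCESSES = ("elastic", "excitation", "ionization")

DEFAULT_E0 = 100.0                 # eV, gun electron energy
DEFAULT_SOLVATION_THRESHOLD = 11.0  # eV, below this an electron solvates


@dataclass
class ProcessTable:
    """Inverse mean free path (nm⁻¹) on a strictly increasing energy grid."""

    energies: np.ndarray
    imfp: np.ndarray

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.imfp = np.asarray(self.imfp, dtype=float)
        if len(self.energies) != len(self.imfp):
            raise ValueError("energy grid and imfp differ in length")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.imfp < 0):
            raise ValueError("inverse mean free paths must be non-negative")

    def __call__(self, E: float) -> float:
        # linear interpolation; zero below the grid (process not open yet),
        # clamped to the last value above it
        return float(np.interp(E, self.energies, self.imfp, left=0.0))


@dataclass
class CrossSectionTable:
    """All physics inputs of the transport: rates, losses, sampling rules.

    ``secondary_rule`` is ``'fixed'`` (constant secondary energy
    ``secondary_params['energy']``, clipped to the available energy) or
    ``'uniform'`` (uniform on [0, (E−I)/2], the indistinguishable-electron
    convention). ``angular_rule`` applies to elastic scattering and is
    ``'isotropic'`` or ``'straight'`` (no deflection); ionization and
    excitation do not deflect the primary, and secondaries are launched
    isotropically (``'straight'`` launches them forward).
    """

    tables: dict[str, ProcessTable]
    excitation_loss: float = 8.0
    ionization_threshold: float = 13.0
    secondary_rule: str = "fixed"
    secondary_params: dict = field(default_factory=lambda: {"energy": 0.0})
    angular_rule: str = "isotropic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in self.tables:
            if name not in PROCESSES:
                raise ValueError(f"unknown process {name!r}")
        if self.secondary_rule not in ("fixed", "uniform"):
            raise ValueError(f"unknown secondary rule {self.secondary_rule!r}")
        if self.angular_rule not in ("isotropic", "straight"):
            raise ValueError(f"unknown angular rule {self.angular_rule!r}")
        if self.excitation_loss <= 0 or self.ionization_threshold <= 0:
            raise ValueError("energy costs must be positive")

    def imfp(self, process: str, E: float) -> float:
        t = self.tables.get(process)
        return t(E) if t is not None else 0.0

    def total_imfp(self, E: float) -> float:
        return sum(self.imfp(p, E) for p in PROCESSES)

    # -- CSV round trip (energy + one column per process; metadata in '#')
    def to_csv(self, path) -> None:
        grid = np.unique(np.concatenate([t.energies
                                         for t in self.tables.values()]))
        meta = {
            "excitation_loss": self.excitation_loss,
            "ionization_threshold": self.ionization_threshold,
            "secondary_rule": self.secondary_rule,
            "secondary_params": self.secondary_params,
            "angular_rule": self.angular_rule,
            **self.metadata,
        }
        with open(path, "w") as fh:
            fh.write("# cross-section table; energies eV, inverse MFP nm^-1\n")
            fh.write("# meta " + json.dumps(meta) + "\n")
            fh.write("energy," + ",".join(PROCESSES) + "\n")
            for E in grid:
                fh.write(f"{E:.10g}," + ",".join(
                    f"{self.imfp(p, float(E)):.10g}" for p in PROCESSES) + "\n")

    @classmethod
    def from_csv(cls, path) -> "CrossSectionTable":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if s.startswith("# meta "):
                    meta = json.loads(s[len("# meta "):])
                elif not s or s.startswith("#") or s.startswith("energy"):
                    continue
                else:
                    rows.append([float(v) for v in s.split(",")])
        arr = np.array(rows)
        if arr.ndim != 2 or arr.shape[1] != 1 + len(PROCESSES):
            raise ValueError(f"{path}: expected energy + {len(PROCESSES)} columns")
        tables = {}
        for k, p in enumerate(PROCESSES):
            if np.any(arr[:, 1 + k] > 0):
                tables[p] = ProcessTable(arr[:, 0], arr[:, 1 + k])
        known = {"excitation_loss", "ionization_threshold", "secondary_rule",
                 "secondary_params", "angular_rule"}
        return cls(tables,
                   excitation_loss=meta.get("excitation_loss", 8.0),
                   ionization_threshold=meta.get("ionization_threshold", 13.0),
                   secondary_rule=meta.get("secondary_rule", "fixed"),
                   secondary_params=meta.get("secondary_params", {"energy": 0.0}),
                   angular_rule=meta.get("angular_rule", "isotropic"),
                   metadata={k: v for k, v in meta.items() if k not in known})


def sample_step(E: float, tables: CrossSectionTable, rng: np.random.Generator
                ) -> tuple[float, str | None]:
    """Draw a free path (nm) and the process ending it.

    The path is exponential with mean 1/(total inverse MFP at E); the process
    is chosen with probability proportional to its inverse MFP. A zero total
    rate yields an infinite path and ``None`` (the electron streams out).
    """
    r_el = tables.imfp("elastic", E)
    r_ex = tables.imfp("excitation", E)
    r_io = tables.imfp("ionization", E)
    total = r_el + r_ex + r_io
    if total <= 0:
        return np.inf, None
    path = rng.exponential(1.0 / total)
    u = rng.uniform(0.0, total)
    if u < r_el:
        proc = "elastic"
    elif u < r_el + r_ex:
        proc = "excitation"
    else:
        proc = "ionization"
    return float(path), proc


@dataclass
class EventRecord:
    """Outcome of one primary electron (with its full cascade)."""

    ionization_positions: np.ndarray   # (k, 3) nm
    n_ionizations: int
    n_solvated_inside: int
    n_escaped: int
    net_charge: int                    # ionizations − solvated inside
    E0: float
    energy_ionization: float           # Σ ionization thresholds paid
    energy_excitation: float           # Σ excitation losses paid
    energy_terminal: float             # Σ terminal kinetic energies


def _isotropic_direction(rng: np.random.Generator) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - z * z)
    return np.array([s * np.cos(phi), s * np.sin(phi), z])


def _entry_point(R: float, entry_rule: str, rng: np.random.Generator
                 ) -> np.ndarray:
    if entry_rule == "axis":
        return np.array([0.0, 0.0, R])
    if entry_rule == "disk":
        # uniform over the projected disk, entering at the sphere surface
        r = R * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        x, y = r * np.cos(phi), r * np.sin(phi)
        return np.array([x, y, np.sqrt(max(R * R - r * r, 0.0))])
    if entry_rule == "hemisphere":
        d = _isotropic_direction(rng)
        d[2] = abs(d[2])
        return R * d
    raise ValueError(f"unknown entry rule {entry_rule!r}")


def transport_electron(sphere_diameter: float, tables: CrossSectionTable,
                       rng: np.random.Generator,
                       E0: float = DEFAULT_E0,
                       solvation_threshold: float = DEFAULT_SOLVATION_THRESHOLD,
                       entry_rule: str = "disk",
                       max_steps: int = 1_000_000) -> EventRecord:
    """Transport one primary electron (and its secondaries) through the sphere.

    The sphere of water is centered at the origin with radius d/2; the
    primary starts on the upper surface moving straight down (−z). Returns
    the full event record; energy bookkeeping closes exactly.
    """
    if E0 <= solvation_threshold:
        raise ValueError("primary energy must exceed the solvation threshold")
    R = sphere_diameter / 2.0
    Rsq = R * R
    I = tables.ionization_threshold
    W = tables.excitation_loss
    down = np.array([0.0, 0.0, -1.0])
    stack: list[tuple[np.ndarray, np.ndarray, float]] = [
        (_entry_point(R, entry_rule, rng), down.copy(), E0)]
    ion_pos: list[np.ndarray] = []
    n_solv = n_esc = 0
    e_ion = e_exc = e_term = 0.0
    steps = 0
    while stack:
        pos, direction, E = stack.pop()
        while True:
            steps += 1
            if steps > max_steps:
                raise RuntimeError(f"electron cascade exceeded {max_steps} steps")
            if E < solvation_threshold:
                n_solv += 1
                e_term += E
                break
            path, proc = sample_step(E, tables, rng)
            if not np.isfinite(path):
                n_esc += 1
                e_term += E
                break
            pos = pos + path * direction
            if pos @ pos > Rsq:
                n_esc += 1
                e_term += E
                break
            if proc == "elastic":
                if tables.angular_rule == "isotropic":
                    direction = _isotropic_direction(rng)
            elif proc == "excitation":
                if E < W:      # interpolated rate below the cost: null collision
                    continue
                e_exc += W
                E -= W
            else:  # ionization
                if E < I:      # null collision; keeps energy bookkeeping exact
                    continue
                ion_pos.append(pos.copy())
                e_ion += I
                avail = E - I
                if tables.secondary_rule == "fixed":
                    Es = min(float(tables.secondary_params["energy"]), avail)
                else:
                    Es = rng.uniform(0.0, avail / 2.0)
                E = avail - Es
                if Es < solvation_threshold:
                    n_solv += 1
                    e_term += Es
                else:
                    sec_dir = (direction.copy() if tables.angular_rule == "straight"
                               else _isotropic_direction(rng))
                    stack.append((pos.copy(), sec_dir, Es))
    k = len(ion_pos)
    return EventRecord(
        ionization_positions=(np.array(ion_pos) if k else np.empty((0, 3))),
        n_ionizations=k,
        n_solvated_inside=n_solv,
        n_escaped=n_esc,
        net_charge=k - n_solv,
        E0=E0,
        energy_ionization=e_ion,
        energy_excitation=e_exc,
        energy_terminal=e_term,
    )


@dataclass
class IonizationEventSet:
    """Kept events of a campaign plus selection bookkeeping."""

    sphere_diameter: float
    events: list[EventRecord]
    selection_net_charge: int | None
    n_attempts: int

    @property
    def acceptance_fraction(self) -> float:
        return len(self.events) / self.n_attempts if self.n_attempts else 0.0


def run_campaign(sphere_diameter: float, tables: CrossSectionTable,
                 n_events: int, seed: int | np.random.Generator,
                 selection_net_charge: int | None = 1,
                 E0: float = DEFAULT_E0,
                 solvation_threshold: float = DEFAULT_SOLVATION_THRESHOLD,
                 entry_rule: str = "disk",
                 max_attempts: int | None = None) -> IonizationEventSet:
    """Repeat :func:`transport_electron` until ``n_events`` kept events.

    Events are kept when their net charge equals ``selection_net_charge``
    (``None`` keeps everything). A fixed ``seed`` makes the campaign
    bit-identical; ``max_attempts`` defaults to 1000 × ``n_events``.
    """
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if max_attempts is None:
        max_attempts = 1000 * n_events
    kept: list[EventRecord] = []
    attempts = 0
    while len(kept) < n_events:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"only {len(kept)}/{n_events} events with net charge "
                f"{selection_net_charge} after {attempts} attempts")
        ev = transport_electron(sphere_diameter, tables, rng, E0,
                                solvation_threshold, entry_rule)
        attempts += 1
        if selection_net_charge is None or ev.net_charge == selection_net_charge:
            kept.append(ev)
    return IonizationEventSet(sphere_diameter, kept, selection_net_charge,
                              attempts)


def ionization_depth_map(events: list[EventRecord] | IonizationEventSet,
                         slab_thickness: float = 1.0,
                         bin_size: float = 0.1,
                         extent: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized x–z histogram of ionization positions in a central slab.

    Only ionizations with |y| < ``slab_thickness``/2 are counted (a section
    through the middle of the cluster). Returns ``(H, x_edges, z_edges)``
    with ``H`` summing to 1 when any ionization falls in the slab.
    """
    if isinstance(events, IonizationEventSet):
        extent = extent if extent is not None else events.sphere_diameter / 2.0
        events = events.events
    pts = [ev.ionization_positions for ev in events
           if len(ev.ionization_positions)]
    pos = np.concatenate(pts) if pts else np.empty((0, 3))
    if len(pos):
        pos = pos[np.abs(pos[:, 1]) < slab_thickness / 2.0]
    if extent is None:
        extent = float(np.abs(pos).max()) if len(pos) else 1.0
    nbin = max(1, int(np.ceil(2 * extent / bin_size)))
    edges = np.linspace(-extent, extent, nbin + 1)
    if len(pos) == 0:
        logger.warning("no ionizations inside the slab; returning empty map")
        return np.zeros((nbin, nbin)), edges, edges
    H, xe, ze = np.histogram2d(pos[:, 0], pos[:, 2], bins=(edges, edges))
    return H / H.sum(), xe, ze


def hydronium_count_distribution(events: list[EventRecord] | IonizationEventSet
                                 ) -> dict[int, float]:
    """P(k) of creating k hydronium ions per primary electron.

    One hydronium per ionization (cryogenic ice: the H2O⁺ → H3O⁺ + OH
    reaction is immediate and the cation does not diffuse), so P(k) is simply
    the fraction of events with k ionizations. Probabilities sum to 1.
    """
    if isinstance(events, IonizationEventSet):
        events = events.events
    if not events:
        return {}
    counts: dict[int, int] = {}
    for ev in events:
        counts[ev.n_ionizations] = counts.get(ev.n_ionizations, 0) + 1
    n = len(events)
    return {k: c / n for k, c in sorted(counts.items())}


def mean_ionization_depth(events: list[EventRecord] | IonizationEventSet,
                          sphere_radius: float | None = None) -> float:
    """Mean depth below the sphere's top (nm) over all ionizations."""
    if isinstance(events, IonizationEventSet):
        sphere_radius = (sphere_radius if sphere_radius is not None
                         else events.sphere_diameter / 2.0)
        events = events.events
    pts = [ev.ionization_positions for ev in events
           if len(ev.ionization_positions)]
    if not pts:
        return float("nan")
    pos = np.concatenate(pts)
    if sphere_radius is None:
        raise ValueError("sphere_radius required when passing a bare event list")
    return float(np.mean(sphere_radius - pos[:, 2]))
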