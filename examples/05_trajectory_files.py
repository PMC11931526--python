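"""Reading and writing trajectory dumps and bond tables.

Writes a synthetic scene to the two text dialects the pipeline consumes
(LAMMPS-dump-like frames, ReaxFF-like bond tables), reads them back —
optionally converting Å/fs file units to the internal nm/ps — and pairs a
frame with its nearest bond table.
"""

import tempfile
from pathlib import Path

import ejecta as ej

spec = ej.random_scene_spec(3)
trajectory, bond_tables, manifest = ej.build_scene(spec)

with tempfile.TemporaryDirectory() as tmp:
    dump = Path(tmp) / "scene.dump"
    bonds = Path(tmp) / "scene.bonds"

    # write in Å / fs, read back with the matching unit map
    units = ej.UnitMap(length="angstrom", time="fs")
    ej.write_trajectory(trajectory, dump, units=units)
    ej.write_bond_tables(bond_tables, bonds, dialect="reaxff")

    back = ej.read_trajectory(dump, units=units)
    tables = ej.read_bond_tables(bonds)

    print(f"round-tripped {len(back.frames)} frames of "
          f"{len(back.frames[0])} atoms via {dump.name} (Å/fs units)")
    frame, table, gap = ej.match_bonds_to_frame(back, tables, time=30.0)
    print(f"frame at t={frame.time} ps paired with bond table at "
          f"t={table.time} ps (gap {gap} ps, {len(table)} bond records)")

    mset = ej.identify_molecules(frame, table, bo_threshold=0.3)
    species = {}
    for mol in mset.molecules:
        species[mol.species] = species.get(mol.species, 0) + 1
    print("molecules identified at that frame:", species)
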