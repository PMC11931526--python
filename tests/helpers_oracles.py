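"""Independent brute-force oracles kept deliberately separate from the
package implementation (plain dictionaries + depth-first search, all-pairs
distance scans), so that the graph/neighbor-search code paths are checked
against something that shares no code with them."""

import numpy as np

import ejecta as ej


def dfs_partition(node_ids, edges):
    """Connected components by explicit DFS; returns frozenset of frozensets."""
    adj = {int(n): set() for n in node_ids}
    for a, b in edges:
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    seen = set()
    comps = []
    for n in adj:
        if n in seen:
            continue
        stack = [n]
        comp = set()
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.add(u)
            stack.extend(adj[u] - seen)
        comps.append(frozenset(comp))
    return frozenset(comps)


def molecule_partition_oracle(frame, bond_table, bo_threshold=0.3):
    edges = [(a, b) for (a, b), bo in zip(bond_table.pairs, bond_table.orders)
             if bo > bo_threshold]
    return dfs_partition(frame.ids, edges)


def molecule_partition_of(mset):
    return frozenset(frozenset(int(a) for a in m.atom_ids)
                     for m in mset.molecules)


def cluster_partition_oracle(frame, mset, cutoff=0.3):
    """All-pairs minimum-distance contact graph + DFS, no k-d tree."""
    n = len(mset.molecules)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            pi = frame.positions[frame.rows_of(mset.molecules[i].atom_ids)]
            pj = frame.positions[frame.rows_of(mset.molecules[j].atom_ids)]
            d = np.sqrt(((pi[:, None, :] - pj[None, :, :]) ** 2).sum(-1)).min()
            if d < cutoff:
                edges.append((i, j))
    return dfs_partition(range(n), edges)


def cluster_partition_of(cset):
    return frozenset(frozenset(int(m) for m in c.molecule_ids)
                     for c in cset.clusters)


def random_bonded_frame(rng, n_atoms=150, p_edge=0.015):
    """Random atoms with shuffled non-contiguous ids and a random bond graph."""
    ids = rng.choice(np.arange(1, 10 * n_atoms), size=n_atoms, replace=False)
    elements = rng.choice(["H", "C", "O"], size=n_atoms)
    pos = rng.uniform(-3, 3, size=(n_atoms, 3))
    vel = rng.normal(0, 0.3, size=(n_atoms, 3))
    frame = ej.Frame(0.0, ids, elements, pos, vel)
    pairs = []
    orders = []
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            if rng.uniform() < p_edge:
                pairs.append((ids[i], ids[j]))
                orders.append(rng.uniform(0.0, 1.0))
    table = ej.BondTable(0.0, np.array(pairs, dtype=np.int64).reshape(-1, 2),
                         np.array(orders))
    return frame, table


def random_molecular_scene(rng, n_molecules=40, box=3.0):
    """Random waters/trehaloses thrown into a box (for clustering oracles)."""
    from ejecta.synthetic import trehalose_template, water_template
    tpos_t, tel_t, tb_t = trehalose_template()
    tpos_w, tel_w, tb_w = water_template()
    ids = []
    elements = []
    pos = []
    pairs = []
    next_id = 1
    for _ in range(n_molecules):
        if rng.uniform() < 0.8:
            tpos, tel, tb = tpos_w, tel_w, tb_w
        else:
            tpos, tel, tb = tpos_t, tel_t, tb_t
        origin = rng.uniform(-box, box, size=3)
        mol_ids = np.arange(next_id, next_id + len(tpos))
        next_id += len(tpos)
        ids.extend(mol_ids)
        elements.extend(tel)
        pos.extend(origin + tpos)
        pairs.extend((mol_ids[a], mol_ids[b]) for a, b in tb)
    frame = ej.Frame(0.0, np.array(ids), np.array(elements, dtype=object),
                     np.array(pos), np.zeros((len(ids), 3)))
    table = ej.BondTable(0.0, np.array(pairs, dtype=np.int64),
                         np.full(len(pairs), 0.9))
    return frame, table
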