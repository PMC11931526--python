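import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ejecta as ej
from conftest import make_frame
from helpers_oracles import (molecule_partition_of, molecule_partition_oracle,
                             random_bonded_frame)


def water_with_orders(bo):
    frame = make_frame([1, 2, 3], ["O", "H", "H"],
                       [[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0]])
    table = ej.BondTable(0.0, np.array([[1, 2], [1, 3]]), np.array([bo, bo]))
    return frame, table


def test_bond_order_threshold_splits_or_joins():
    """O–H bond orders above/below 0.3 decide whether a water is one molecule."""
    frame, table = water_with_orders(0.8)
    mset = ej.identify_molecules(frame, table)
    assert len(mset) == 1
    assert mset.molecules[0].formula == {"H": 2, "O": 1}
    frame, table = water_with_orders(0.2)
    mset = ej.identify_molecules(frame, table)
    assert len(mset) == 3
    assert all(len(m) == 1 for m in mset.molecules)


def test_unknown_bond_atom_rejected(water_frame):
    table = ej.BondTable(0.0, np.array([[1, 99]]), np.array([0.9]))
    with pytest.raises(ValueError, match="absent from frame"):
        ej.identify_molecules(water_frame, table)


@pytest.mark.parametrize("formula, expected, decimals", [
    ({"C": 12, "H": 22, "O": 11}, 342.3, 1),   # trehalose, as printed
    ({"H": 2, "O": 1}, 18.02, 2),
    ({"C": 1}, 12.011, 3),
])
def test_formula_and_mass(formula, expected, decimals):
    _, mass = ej.formula_and_mass(formula)
    assert round(mass, decimals) == expected


def test_mass_from_element_list():
    _, mass = ej.formula_and_mass(["O", "H", "H"])
    assert mass == pytest.approx(18.015)
    with pytest.raises(KeyError, match="Xx"):
        ej.formula_and_mass({"Xx": 1})


@pytest.mark.parametrize("formula, label", [
    ({"C": 12, "H": 22, "O": 11}, "intact_trehalose"),
    ({"H": 2, "O": 1}, "water"),
    ({"C": 6, "H": 11, "O": 5}, "fragment"),    # half-sugar after C–O scission
    ({"C": 12, "H": 21, "O": 11}, "fragment"),  # trehalose missing one H
])
def test_classify_species(formula, label):
    assert ej.classify_species(formula) == label


@pytest.mark.parametrize("seed", range(12))
def test_molecule_partition_matches_dfs_oracle(seed):
    """Threshold-graph components equal an independent DFS on random graphs."""
    rng = np.random.default_rng(seed)
    frame, table = random_bonded_frame(rng, n_atoms=200)
    mset = ej.identify_molecules(frame, table)
    assert molecule_partition_of(mset) == molecule_partition_oracle(frame, table)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000),
       thresholds=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=4))
def test_threshold_monotonicity(seed, thresholds):
    """Raising the bond-order threshold never decreases the molecule count."""
    rng = np.random.default_rng(seed)
    frame, table = random_bonded_frame(rng, n_atoms=80, p_edge=0.03)
    counts = [len(ej.identify_molecules(frame, table, bo_threshold=t))
              for t in sorted(thresholds)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_mass_conservation_random_frames():
    rng = np.random.default_rng(5)
    for _ in range(5):
        frame, table = random_bonded_frame(rng, n_atoms=120)
        mset = ej.identify_molecules(frame, table)
        assert mset.total_mass == pytest.approx(frame.masses().sum(), abs=1e-9)


def test_identity_tracking_stable_for_identical_partitions(water_frame):
    table = ej.BondTable(0.0, np.array([[1, 2], [1, 3]]), np.array([0.9, 0.9]))
    m0 = ej.identify_molecules(water_frame, table)
    f1 = make_frame([1, 2, 3], ["O", "H", "H"],
                    [[0, 0, 1], [0.1, 0, 1], [0, 0.1, 1]], time=1.0)
    m1 = ej.identify_molecules(f1, ej.BondTable(1.0, table.pairs, table.orders))
    events = ej.track_molecule_identity([m0, m1])
    assert events == []
    assert m0.stable_ids == m1.stable_ids


def test_identity_tracking_logs_scission():
    """An even split creates two fresh ids and one scission event."""
    ids = [1, 2, 3, 4]
    f0 = make_frame(ids, ["C", "C", "C", "C"],
                    [[0, 0, 0], [0.15, 0, 0], [0.3, 0, 0], [0.45, 0, 0]])
    bonds0 = ej.BondTable(0.0, np.array([[1, 2], [2, 3], [3, 4]]),
                          np.full(3, 0.9))
    f1 = make_frame(ids, ["C", "C", "C", "C"],
                    [[0, 0, 0], [0.15, 0, 0], [0.9, 0, 0], [1.05, 0, 0]],
                    time=1.0)
    bonds1 = ej.BondTable(1.0, np.array([[1, 2], [3, 4]]), np.full(2, 0.9))
    m0 = ej.identify_molecules(f0, bonds0)
    m1 = ej.identify_molecules(f1, bonds1)
    events = ej.track_molecule_identity([m0, m1])
    assert len(events) == 1
    ev = events[0]
    assert ev.kind == "split" and ev.time == 1.0
    assert set(ev.child_stable_ids).isdisjoint({0})  # both halves get new ids
    assert len(set(m1.stable_ids.values())) == 2


def test_scripted_fragmentation_reported_at_first_frame(demo_scene,
                                                        demo_analysis):
    """The planted C–O scission shows up exactly at the first frame ≥ its time."""
    _, _, manifest = demo_scene
    expected = [e.scission_time for e in manifest.events
                if e.scission_time is not None]
    splits = [ev.time for ev in demo_analysis.reaction_events
              if ev.kind == "split"]
    assert sorted(splits) == sorted(expected)


def test_no_reaction_scene_has_no_events():
    """Without scripted scissions molecules stay intact: zero reaction events."""
    spec = ej.SceneSpec(events=[
        ej.ScriptedEvent(n_trehalose=1, n_waters=1, eject_time=15.0,
                         sputter_cross_time=45.0,
                         water_detach_times=(397.5,))], seed=2)
    traj, bts, man = ej.build_scene(spec)
    res = ej.analyze_impact(traj, bts, man.sample_atom_ids)
    assert res.reaction_events == []
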