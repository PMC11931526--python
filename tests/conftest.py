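import math

import numpy as np
import pytest

import ejecta as ej


def make_frame(ids, elements, positions, velocities=None, time=0.0):
    positions = np.asarray(positions, dtype=float)
    if velocities is None:
        velocities = np.zeros_like(positions)
    return ej.Frame(time, np.asarray(ids), np.asarray(elements, dtype=object),
                    positions, velocities)


@pytest.fixture
def water_frame():
    """A lone water: O at origin, two H within bonding range."""
    return make_frame([1, 2, 3], ["O", "H", "H"],
                      [[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0]])


@pytest.fixture(scope="session")
def demo_scene():
    """One scripted scene exercising every census category and a complex."""
    spec = ej.SceneSpec(events=[
        ej.ScriptedEvent(n_trehalose=1, n_waters=2, eject_time=15.0,
                         sputter_cross_time=45.0,
                         water_detach_times=(397.5, math.inf)),
        ej.ScriptedEvent(n_trehalose=2, n_waters=1, eject_time=30.0,
                         sputter_cross_time=60.0,
                         water_detach_times=(202.5,)),
        ej.ScriptedEvent(n_trehalose=1, n_waters=0, eject_time=15.0,
                         sputter_cross_time=60.0, fragment_time=7.5),
        ej.ScriptedEvent(kind="water_blob", n_waters=3, eject_time=15.0,
                         sputter_cross_time=45.0),
        ej.ScriptedEvent(n_trehalose=1, n_waters=1, eject_time=15.0,
                         water_detach_times=(math.inf,)),
        ej.ScriptedEvent(n_trehalose=1, n_waters=0, eject_time=30.0,
                         sputter_cross_time=75.0),
    ], seed=11)
    return ej.build_scene(spec)


@pytest.fixture(scope="session")
def demo_analysis(demo_scene):
    traj, bond_tables, manifest = demo_scene
    return ej.analyze_impact(traj, bond_tables, manifest.sample_atom_ids)
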