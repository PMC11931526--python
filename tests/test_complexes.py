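import math

import numpy as np
import pytest

import ejecta as ej


@pytest.fixture(scope="module")
def lifetime_scene():
    """Scripted detachments spanning the 320 ps stability threshold."""
    spec = ej.SceneSpec(events=[
        # detaches at ~400 ps after ejection at 45 ps → stable well past 320
        ej.ScriptedEvent(n_trehalose=1, n_waters=1, eject_time=15.0,
                         sputter_cross_time=45.0,
                         water_detach_times=(442.5,)),
        # all waters gone ~155 ps after ejection → excluded (< 320 ps)
        ej.ScriptedEvent(n_trehalose=1, n_waters=2, eject_time=15.0,
                         sputter_cross_time=45.0,
                         water_detach_times=(142.5, 202.5)),
        # three waters still attached at 900 ps → excluded (> 1 at end)
        ej.ScriptedEvent(n_trehalose=1, n_waters=3, eject_time=30.0,
                         sputter_cross_time=60.0,
                         water_detach_times=(math.inf, math.inf, math.inf)),
        # one water kept through 900 ps → included
        ej.ScriptedEvent(n_trehalose=1, n_waters=1, eject_time=30.0,
                         sputter_cross_time=60.0,
                         water_detach_times=(math.inf,)),
        # two-trehalose cluster → no complex trace at all
        ej.ScriptedEvent(n_trehalose=2, n_waters=2, eject_time=15.0,
                         sputter_cross_time=45.0,
                         water_detach_times=(math.inf, math.inf)),
        # short contact: ejected at 60 ps, water gone at ~97 ps → 30 ps contact
        ej.ScriptedEvent(n_trehalose=1, n_waters=1, eject_time=30.0,
                         sputter_cross_time=60.0,
                         water_detach_times=(97.5,)),
    ], seed=17)
    traj, bts, man = ej.build_scene(spec)
    res = ej.analyze_impact(traj, bts, man.sample_atom_ids)
    return traj, man, res


def test_traces_match_script(lifetime_scene):
    traj, man, res = lifetime_scene
    cadence = 15.0
    expected = [(e.ejection_time, e.stable_duration, e.final_water_count,
                 e.included)
                for e in man.events if e.stable_duration is not None]
    got = [(t.ejection_time, t.stable_duration, t.final_water_count,
            t.included) for t in res.traces]
    assert sorted(got) == sorted(expected)
    # detachment at 442.5 ps recovered within one frame cadence
    tr = next(t for t in res.traces if abs(t.ejection_time - 45.0) < 1e-9
              and t.final_water_count == 0)
    intervals = next(iter(tr.contact_intervals.values()))
    t0, t1 = intervals[0]
    assert t0 == tr.ejection_time
    assert abs(t1 - 442.5) <= cadence


def test_two_trehalose_cluster_yields_no_trace(lifetime_scene):
    _, man, res = lifetime_scene
    # 6 scripted events, one is a two-trehalose cluster → 5 traces
    assert len(res.traces) == sum(
        1 for e in man.events if e.stable_duration is not None)
    assert all(t.single_trehalose_throughout for t in res.traces)


def test_stability_filter_rules(lifetime_scene):
    _, man, res = lifetime_scene
    included = ej.apply_stability_filter(res.traces)
    assert included == man.n_included_complexes == 2
    by_final = {t.final_water_count: t for t in res.traces if t.included}
    # the long-stable complex that ends bare is included and flagged
    assert 0 in by_final and "bare_at_end" in by_final[0].flags
    assert 1 in by_final


def test_filter_monotonicity_and_sweep(lifetime_scene):
    _, _, res = lifetime_scene
    grid = ej.sweep_cutoffs(res.traces, [0.0, 160.0, 320.0, 640.0, 1200.0],
                            [0, 1, 10])
    # no filter at all keeps every trace
    top = grid.query("min_stable == 0 and max_final_waters == 10")
    assert int(top["included"].iloc[0]) == len(res.traces)
    for mf, sub in grid.groupby("max_final_waters"):
        counts = sub.sort_values("min_stable")["included"].tolist()
        assert all(a >= b for a, b in zip(counts, counts[1:]))
    for ms, sub in grid.groupby("min_stable"):
        counts = sub.sort_values("max_final_waters")["included"].tolist()
        assert all(a <= b for a, b in zip(counts, counts[1:]))
    # sweeping must not clobber the traces' own verdicts
    assert sum(t.included for t in res.traces) == 2


def test_contact_time_map(lifetime_scene):
    traj, man, res = lifetime_scene
    cmap = ej.contact_time_map(res.traces, res.molecule_sets[0],
                               min_display=40.0)
    # the 30 ps contact is omitted; all durations shown are ≥ 40 ps
    assert (cmap["contact_duration"] >= 40.0).all()
    # emitted waters come from the projectile with known launch positions
    assert set(cmap["origin"]) == {"projectile"}
    expected = {}
    for e in man.events:
        for w in e.waters:
            if w.contact_duration is not None and w.contact_duration >= 40.0:
                expected[tuple(np.round(w.initial_com, 6))] = w.contact_duration
    got = {tuple(np.round([r.x0, r.y0, r.z0], 6)): r.contact_duration
           for r in cmap.itertuples()}
    assert got == pytest.approx(expected)
    short = [w for e in man.events for w in e.waters
             if w.contact_duration is not None and w.contact_duration < 40.0]
    assert len(short) >= 1  # the scripted 30 ps water really was omitted


def test_stable_ids_required():
    spec = ej.SceneSpec(events=[], n_decoy_molecules=2, seed=0)
    traj, bts, man = ej.build_scene(spec)
    table = bts[0]
    msets = [ej.identify_molecules(f, table) for f in traj.frames[:3]]
    csets = [ej.identify_clusters(f, m) for f, m in zip(traj.frames[:3], msets)]
    with pytest.raises(ValueError, match="stable ids"):
        ej.build_complex_traces(msets, csets, z0=man.z0)
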