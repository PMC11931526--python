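import numpy as np
import pytest

import ejecta as ej
from ejecta.census import ImpactCensus, categorize_cluster
from ejecta.clusters import Cluster
from conftest import make_frame

TREH = 342.297
WATER = 18.015


def make_cluster(com_z, vz, mass=TREH):
    return Cluster(0, [0], {}, mass, np.array([0.0, 0.0, com_z]),
                   np.array([0.0, 0.0, vz]))


def test_surface_reference():
    frame = make_frame([1, 2, 3], ["O", "O", "O"],
                       [[0, 0, 28.0], [1, 0, 30.0], [2, 0, 29.0]])
    assert ej.surface_reference(frame, [1, 2, 3]) == pytest.approx(30.0)
    assert ej.surface_reference(frame, [1, 2, 3],
                                method="top_decile_mean") == pytest.approx(30.0)
    with pytest.raises(ValueError, match="empty"):
        ej.surface_reference(frame, [])


@pytest.mark.parametrize("height, vz, expect", [
    (16.0, 0.5, True),    # high enough, moving up
    (16.0, -0.5, False),  # moving down
    (14.0, 0.5, False),   # not high enough
    (15.0, 0.5, True),    # exactly at the 15 nm threshold counts
])
def test_is_sputtered_rule(height, vz, expect):
    rec = ej.is_sputtered(make_cluster(30.0 + height, vz), 75.0, z0=30.0)
    assert rec.sputtered is expect
    assert rec.height == pytest.approx(height)


def test_height_min_monotonicity():
    """Lowering the height threshold can only add sputtered clusters."""
    rng = np.random.default_rng(0)
    clusters = [make_cluster(30 + rng.uniform(0, 30), rng.uniform(-1, 1))
                for _ in range(50)]
    counts = [sum(ej.is_sputtered(c, 75.0, 30.0, height_min=h).sputtered
                  for c in clusters) for h in (20.0, 15.0, 10.0, 5.0)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_categorize_cluster_taxonomy():
    t = ("intact_trehalose", TREH)
    w = ("water", WATER)
    f = ("fragment", 163.0)
    assert categorize_cluster([t]) == {"single_bare": pytest.approx(TREH)}
    assert categorize_cluster([t, t]) == {"multiple_bare": pytest.approx(2 * TREH)}
    assert categorize_cluster([t, w, w, w]) == {
        "single_solvated": pytest.approx(TREH + 3 * WATER)}
    assert categorize_cluster([t, t, w]) == {
        "multiple_solvated": pytest.approx(2 * TREH + WATER)}
    # fragment mass always pools into `fragments`; the residue re-categorizes
    assert categorize_cluster([f, w]) == {"fragments": pytest.approx(163.0),
                                          "water": pytest.approx(WATER)}
    assert categorize_cluster([f, t]) == {"fragments": pytest.approx(163.0),
                                          "single_bare": pytest.approx(TREH)}
    assert categorize_cluster([w, w]) == {"water": pytest.approx(2 * WATER)}
    with pytest.raises(ValueError, match="empty"):
        categorize_cluster([])


def impact_with(category_mass, water=0.0):
    masses = {c: 0.0 for c in ej.CATEGORIES}
    masses.update(category_mass)
    return ImpactCensus(masses, water, [], np.empty(0), [])


def test_compute_yields_examples():
    # two bare trehaloses in one impact → single_bare yield 2.0 (684.6/342.3)
    yb = ej.compute_yields([impact_with({"single_bare": 684.6})])
    assert yb.mean["single_bare"] == pytest.approx(2.0)
    assert yb.mean["total"] == pytest.approx(2.0)
    # a lone sputtered water: categories zero, water tally 18.02/342.3
    yb = ej.compute_yields([impact_with({}, water=18.02)])
    assert yb.mean["total"] == 0.0
    assert yb.water_mean == pytest.approx(18.02 / 342.3)
    with pytest.raises(ValueError, match="impact"):
        ej.compute_yields([])


def test_yields_sum_and_spread():
    imps = [impact_with({"single_bare": 342.3, "fragments": 171.15}),
            impact_with({"single_bare": 684.6})]
    yb = ej.compute_yields(imps)
    assert yb.mean["total"] == pytest.approx(
        sum(yb.mean[c] for c in ej.CATEGORIES))
    assert yb.std["single_bare"] == pytest.approx(0.5)


def test_mass_spectrum():
    imp = ImpactCensus({c: 0.0 for c in ej.CATEGORIES}, 0.0, [],
                       np.array([18.015, 18.015, 18.015, 342.297]), [])
    edges, counts = ej.mass_spectrum([imp], bin_width=1.0)
    assert counts[18] == pytest.approx(3.0)
    assert counts[342] == pytest.approx(1.0)
    assert counts.sum() == pytest.approx(4.0)
    with pytest.raises(ValueError, match="bin_width"):
        ej.mass_spectrum([imp], bin_width=0.0)


def test_per_molecule_kinetic_energy(water_frame):
    table = ej.BondTable(0.0, np.array([[1, 2], [1, 3]]), np.full(2, 0.9))
    mset = ej.identify_molecules(water_frame, table)
    # all atoms at 1 nm/ps along z → KE = ½·18.015 amu·nm²/ps² ≈ 0.0934 eV
    water_frame.velocities[:] = [0.0, 0.0, 1.0]
    ke = ej.per_molecule_kinetic_energy(water_frame, mset)
    assert ke[0] == pytest.approx(0.5 * 18.015 * ej.KE_AMU_NM2_PS2_TO_EV,
                                  rel=1e-12)
    assert ke[0] == pytest.approx(0.0934, abs=5e-4)
    water_frame.velocities[:] = 0.0
    assert ej.per_molecule_kinetic_energy(water_frame, mset)[0] == 0.0


def test_projectile_carries_20_keV(demo_scene, demo_analysis):
    """At launch the whole projectile holds 20 keV → E/n per water molecule."""
    traj, _, manifest = demo_scene
    mset = demo_analysis.molecule_sets[0]
    ke = ej.per_molecule_kinetic_energy(traj.frames[0], mset)
    proj_rows = traj.frames[0].rows_of(manifest.projectile_atom_ids)
    proj_mols = sorted(set(mset.labels[proj_rows]))
    n = len(proj_mols)
    np.testing.assert_allclose(ke[proj_mols], 20000.0 / n, rtol=1e-9)
    assert ke[proj_mols].sum() == pytest.approx(20000.0, rel=1e-9)


def test_census_recovers_demo_scene(demo_scene, demo_analysis):
    _, _, manifest = demo_scene
    yb = ej.compute_yields([demo_analysis.census])
    for cat in ej.CATEGORIES:
        assert yb.mean[cat] == pytest.approx(manifest.yields[cat], abs=1e-9)
    assert yb.water_mean == pytest.approx(manifest.water_yield, abs=1e-9)
    edges, counts = ej.mass_spectrum([demo_analysis.census])
    assert counts.sum() == pytest.approx(manifest.n_sputtered_molecules)


def test_solvated_mass_convention_switch(demo_scene):
    """Trehalose-only accounting moves the adjoining waters to the water tally."""
    traj, bts, manifest = demo_scene
    res = ej.analyze_impact(traj, bts, manifest.sample_atom_ids,
                            include_water_mass_in_solvated=False)
    n_solv_waters = sum(
        len(e.waters) for e in manifest.events
        if e.sputtered and e.category in ("single_solvated", "multiple_solvated"))
    expected_water = manifest.water_yield + n_solv_waters * 18.015 / 342.3
    assert res.census.water_mass / 342.3 == pytest.approx(expected_water)
    got = res.census.category_mass
    want = {c: manifest.yields[c] * 342.3 for c in ej.CATEGORIES}
    for cat in ("single_solvated", "multiple_solvated"):
        n_w = sum(len(e.waters) for e in manifest.events
                  if e.sputtered and e.category == cat)
        want[cat] -= n_w * 18.015
    for cat in ej.CATEGORIES:
        assert got[cat] == pytest.approx(want[cat], abs=1e-9)
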