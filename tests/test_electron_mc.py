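import numpy as np
import pytest
from scipy import stats

import ejecta as ej
from ejecta.electron_mc import EventRecord, _entry_point


def censored_poisson_pmf(mu, cap, kmax):
    """Independent closed form: Poisson censored at the energy cap."""
    pmf = np.zeros(kmax + 1)
    for k in range(cap):
        pmf[k] = stats.poisson.pmf(k, mu)
    pmf[cap] = 1.0 - pmf[:cap].sum()
    return pmf


def energy_cap(E0, loss):
    """Ionizations possible on the deterministic energy ladder."""
    cap, E = 0, E0
    while E >= loss:
        cap += 1
        E -= loss
    return cap


def test_sample_step_exponential_free_path():
    """With one constant-rate process the free path is Exponential(λ⁻¹)."""
    tables = ej.make_toy_cross_sections(2.0, 20.0)
    rng = np.random.default_rng(0)
    paths = np.array([ej.sample_step(100.0, tables, rng)[0]
                      for _ in range(100_000)])
    assert paths.mean() == pytest.approx(2.0, rel=0.02)
    ks = stats.kstest(paths, "expon", args=(0, 2.0))
    assert ks.pvalue > 1e-3


def test_sample_step_process_selection_ratio():
    """Rates 2:1 (elastic:ionization) select processes 2/3 : 1/3."""
    tables = ej.make_toy_cross_sections(2.0, 20.0, "elastic_ionization",
                                        elastic_mean_free_path=1.0)
    rng = np.random.default_rng(1)
    n = 30_000
    picks = [ej.sample_step(100.0, tables, rng)[1] for _ in range(n)]
    frac = picks.count("elastic") / n
    assert frac == pytest.approx(2 / 3, abs=3 * np.sqrt(2 / 9 / n) + 0.01)


def test_zero_total_rate_streams_out():
    tables = ej.make_toy_cross_sections(1.0, 20.0, "inert")
    rng = np.random.default_rng(2)
    path, proc = ej.sample_step(50.0, tables, rng)
    assert np.isinf(path) and proc is None
    ev = ej.transport_electron(5.0, tables, rng)
    assert ev.n_ionizations == 0 and ev.n_escaped == 1


def test_no_ionization_below_threshold():
    """E0 below the ionization cost can never ionize (energy bookkeeping)."""
    tables = ej.make_toy_cross_sections(0.5, 60.0)
    rng = np.random.default_rng(3)
    for _ in range(50):
        ev = ej.transport_electron(5.0, tables, rng, E0=50.0)
        assert ev.n_ionizations == 0


def test_censored_poisson_oracle_small():
    """Straight-line constant-rate toy: count law is the censored Poisson."""
    d, lam, loss, E0 = 6.0, 2.0, 20.0, 100.0
    tables = ej.make_toy_cross_sections(lam, loss)
    rng = np.random.default_rng(4)
    n = 20_000
    cap = energy_cap(E0, loss)
    counts = np.zeros(cap + 2)
    for _ in range(n):
        ev = ej.transport_electron(d, tables, rng, E0=E0, entry_rule="axis")
        counts[ev.n_ionizations] += 1
        closure = ev.E0 - ev.energy_ionization - ev.energy_excitation \
            - ev.energy_terminal
        assert abs(closure) < 1e-9
        assert ev.n_solvated_inside <= ev.n_ionizations + 1
    counts /= n
    pmf = censored_poisson_pmf(d / lam, cap, cap + 1)
    tv = 0.5 * np.abs(counts - pmf).sum()
    assert counts[cap + 1] == 0.0          # cap is a hard energy bound
    assert tv < 0.025                      # Monte-Carlo error at n = 2e4


def test_energy_closure_with_cascade():
    """Closure also holds with excitation + cascaded uniform secondaries."""
    tables = ej.make_synthetic_water_table()
    rng = np.random.default_rng(5)
    for _ in range(200):
        ev = ej.transport_electron(7.0, tables, rng)
        closure = ev.E0 - ev.energy_ionization - ev.energy_excitation \
            - ev.energy_terminal
        assert abs(closure) < 1e-9
        if len(ev.ionization_positions):
            r = np.linalg.norm(ev.ionization_positions, axis=1)
            assert (r <= 3.5 + 1e-9).all()  # ionizations inside the sphere


def test_campaign_selects_single_ionization_events():
    """When secondaries and the primary always escape, net +1 ⇔ one ionization."""
    # one ionization spends 60 (threshold) + 25 (secondary); the 15 eV
    # remainder and the 25 eV secondary are both below the 60 eV ionization
    # threshold, so both stream out of the sphere and escape
    tables = ej.CrossSectionTable(
        {"ionization": ej.ProcessTable(np.array([60.0, 1e4]),
                                       np.array([0.5, 0.5]))},
        ionization_threshold=60.0, secondary_rule="fixed",
        secondary_params={"energy": 25.0}, angular_rule="straight")
    camp = ej.run_campaign(6.0, tables, 500, 6, selection_net_charge=1)
    assert all(ev.n_ionizations == 1 for ev in camp.events)
    assert all(ev.net_charge == 1 for ev in camp.events)


def test_campaign_deterministic_under_seed():
    tables = ej.make_toy_cross_sections(2.0, 20.0)
    a = ej.run_campaign(6.0, tables, 200, 42, selection_net_charge=None)
    b = ej.run_campaign(6.0, tables, 200, 42, selection_net_charge=None)
    assert a.n_attempts == b.n_attempts
    for x, y in zip(a.events, b.events):
        assert x.n_ionizations == y.n_ionizations
        np.testing.assert_array_equal(x.ionization_positions,
                                      y.ionization_positions)


def test_acceptance_fraction_self_consistent():
    """Selection acceptance matches the directly estimated P(net = +1)."""
    tables = ej.make_synthetic_water_table()
    camp = ej.run_campaign(5.0, tables, 400, 7, selection_net_charge=1)
    everything = ej.run_campaign(5.0, tables, 4000, 8, selection_net_charge=None)
    p_direct = np.mean([ev.net_charge == 1 for ev in everything.events])
    se = np.sqrt(p_direct * (1 - p_direct) / 4000) + \
        np.sqrt(p_direct * (1 - p_direct) / camp.n_attempts)
    assert camp.acceptance_fraction == pytest.approx(p_direct, abs=4 * se)


def _event_at(points):
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return EventRecord(pts, len(pts), 0, 1, len(pts), 100.0, 0.0, 0.0, 100.0)


def test_depth_map_normalization_and_localization():
    events = [_event_at([[0.0, 0.0, 0.0]])] * 5
    H, xe, ze = ej.ionization_depth_map(events, extent=2.0)
    assert H.sum() == pytest.approx(1.0)
    assert (H > 0).sum() == 1
    # ionizations outside the 1 nm slab are not counted
    H2, _, _ = ej.ionization_depth_map([_event_at([[0.0, 2.0, 0.0]])],
                                       extent=2.0)
    assert H2.sum() == 0.0


def test_stronger_absorption_means_shallower_ionization():
    rng = np.random.default_rng(9)
    depths = []
    for lam in (3.0, 0.5):
        tables = ej.make_toy_cross_sections(lam, 20.0)
        evs = [ej.transport_electron(7.0, tables,
                                     np.random.default_rng(100 + i),
                                     entry_rule="axis") for i in range(3000)]
        depths.append(ej.mean_ionization_depth(evs, sphere_radius=3.5))
    assert depths[1] < depths[0] < 3.5


def test_hydronium_distribution_sums_to_one():
    events = [_event_at([[0, 0, 0]]), _event_at([[0, 0, 0], [0, 0, 1]]),
              _event_at([[0, 0, 0]])]
    dist = ej.hydronium_count_distribution(events)
    assert sum(dist.values()) == pytest.approx(1.0)
    assert dist[1] == pytest.approx(2 / 3)
    assert dist[2] == pytest.approx(1 / 3)


def test_cross_section_csv_roundtrip(tmp_path):
    tables = ej.make_synthetic_water_table()
    path = tmp_path / "water.csv"
    tables.to_csv(path)
    back = ej.CrossSectionTable.from_csv(path)
    for E in (11.0, 17.3, 55.0, 100.0, 240.0, 5.0):
        for p in ("elastic", "excitation", "ionization"):
            assert back.imfp(p, E) == pytest.approx(tables.imfp(p, E))
    assert back.ionization_threshold == tables.ionization_threshold
    assert back.secondary_rule == "uniform"
    assert back.metadata["provenance"].startswith("synthetic")


def test_entry_rules_start_on_upper_surface():
    rng = np.random.default_rng(11)
    for rule in ("disk", "axis", "hemisphere"):
        for _ in range(100):
            p = _entry_point(3.5, rule, rng)
            assert np.linalg.norm(p) == pytest.approx(3.5)
            assert p[2] >= 0
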