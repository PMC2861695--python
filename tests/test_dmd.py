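"""Event-driven engine: event prediction, collisions, conservation laws."""

import numpy as np
import pytest

from polyqmd.dmd import (DMDSimulation, next_pair_event,
                         radius_of_gyration, resolve_collision, run_dmd)
from polyqmd.constructs import build_construct
from polyqmd.potentials import SquareWellPotential


# --- next_pair_event ------------------------------------------------------

def test_head_on_approach_time():
    pot = SquareWellPotential((3.0,), ())
    ev = next_pair_event(np.array([5.0, 0, 0]), np.array([-1.0, 0, 0]), pot)
    assert ev is not None
    t, b = ev
    assert t == pytest.approx(2.0)
    assert b == 0


def test_receding_pair_has_no_event():
    pot = SquareWellPotential((3.0, 5.0), (-1.0,))
    ev = next_pair_event(np.array([6.0, 0, 0]), np.array([1.0, 0, 0]), pot)
    assert ev is None


def test_overlapping_pair_rejected():
    pot = SquareWellPotential((3.0,), ())
    with pytest.raises(ValueError):
        next_pair_event(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]), pot)


def _stepping_oracle(r0, v, boundaries, shell0, dt=1e-4, t_max=20.0):
    """First boundary crossing found by dense time stepping."""
    t_grid = np.arange(0.0, t_max, dt)
    d = np.linalg.norm(r0[None] + t_grid[:, None] * v[None], axis=1)
    bounds = np.asarray(boundaries)
    shells = np.searchsorted(bounds, d)
    change = np.nonzero(shells != shell0)[0]
    if change.size == 0:
        return None
    i = change[0]
    return t_grid[i], min(shells[i], shell0)


def test_oblique_approach_matches_stepping_oracle(rng):
    pot = SquareWellPotential((2.0, 4.0, 6.0), (-1.0, -0.3))
    n_checked = 0
    for _ in range(150):
        r0 = rng.normal(size=3)
        r0 *= rng.uniform(2.2, 8.0) / np.linalg.norm(r0)
        v = rng.normal(size=3)
        ev = next_pair_event(r0, v, pot)
        shell0 = int(np.searchsorted(pot.boundaries, np.linalg.norm(r0)))
        oracle = _stepping_oracle(r0, v, pot.boundaries, shell0)
        if ev is None:
            assert oracle is None or oracle[0] > 19.0
        else:
            assert oracle is not None
            t, b = ev
            assert abs(t - oracle[0]) < 2e-4
            assert b == oracle[1]
            n_checked += 1
    assert n_checked > 50


# --- resolve_collision ----------------------------------------------------

def test_equal_mass_head_on_exchange():
    vi, vj = resolve_collision([1.0, 0, 0], [-1.0, 0, 0],
                               r_hat=[-1.0, 0, 0], m_i=1.0, m_j=1.0,
                               delta_u=np.inf)
    assert np.allclose(vi, [-1.0, 0, 0])
    assert np.allclose(vj, [1.0, 0, 0])


def test_zero_step_leaves_velocities_unchanged():
    vi0, vj0 = np.array([0.7, 0.1, 0]), np.array([-0.2, 0.4, 0])
    vi, vj = resolve_collision(vi0, vj0, r_hat=[-1.0, 0, 0],
                               m_i=1.0, m_j=1.0, delta_u=0.0)
    assert np.allclose(vi, vi0) and np.allclose(vj, vj0)


def test_well_descent_energy_balance():
    # reduced mass 0.5 (two unit masses), falling into a -1 kcal/mol well
    mu = 0.5
    v_r = -0.4
    vi, vj = resolve_collision([-0.4, 0, 0], [0.0, 0, 0],
                               r_hat=[1.0, 0, 0], m_i=1.0, m_j=1.0,
                               delta_u=-1.0)
    v_r_new = np.dot(vi - vj, [1.0, 0, 0])
    assert v_r_new == pytest.approx(-np.sqrt(v_r**2 + 2 * 1.0 / mu))
    # total energy balance: dKE = -dU
    ke0 = 0.5 * 0.4**2
    ke1 = 0.5 * (vi @ vi) + 0.5 * (vj @ vj)
    assert ke1 - ke0 == pytest.approx(1.0)


def test_insufficient_energy_reflects():
    # reflection of the relative motion: equal masses exchange velocities
    vi, vj = resolve_collision([0.1, 0, 0], [0.0, 0, 0],
                               r_hat=[1.0, 0, 0], m_i=1.0, m_j=1.0,
                               delta_u=5.0)
    assert np.allclose(vi, [0.0, 0, 0])
    assert np.allclose(vj, [0.1, 0, 0])


# --- radius of gyration ---------------------------------------------------

def test_rg_trivial_cases():
    assert radius_of_gyration(np.zeros((1, 3))) == 0.0
    two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    assert radius_of_gyration(two) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        radius_of_gyration(np.empty((0, 3)))


def test_rg_matches_double_loop(rng):
    pts = rng.normal(size=(5, 3))
    m = rng.uniform(1, 3, size=5)
    # brute force: Rg^2 = sum_i w_i |r_i - com|^2
    com = (m[:, None] * pts).sum(0) / m.sum()
    expected = np.sqrt((m * ((pts - com) ** 2).sum(1)).sum() / m.sum())
    assert radius_of_gyration(pts, m) == pytest.approx(expected)


# --- full dynamics --------------------------------------------------------

def test_zero_duration_preserves_state(q4_system):
    sim = DMDSimulation(q4_system, 0.6, seed=5)
    p0 = sim.pos.copy()
    sim.advance(0.0)
    traj = sim.trajectory()
    assert traj.n_frames == 0
    assert np.array_equal(sim.pos, p0)


def test_microcanonical_conservation(q4_system):
    sim = DMDSimulation(q4_system, 0.6, seed=7, thermostat=False)
    e0 = sim.total_energy()
    p0 = (q4_system.mass[:, None] * sim.vel).sum(axis=0)
    sim.advance(100.0)
    assert sim.n_collisions > 10_000
    assert abs(sim.total_energy() - e0) <= 1e-9 * abs(e0)
    p1 = (q4_system.mass[:, None] * sim.vel).sum(axis=0)
    assert np.abs(p1 - p0).max() < 1e-9


def test_frame_times_ordered_and_hard_core_respected(q4_system):
    traj = run_dmd(build_construct("QN", 4), 0.7, 300.0, seed=9,
                   equilibration_tu=0.0)
    assert np.all(np.diff(traj.times) > 0)
    hard = q4_system.forcefield.hardcore
    for f in traj.positions[::5]:
        d = np.linalg.norm(f[:, None] - f[None], axis=2)
        nb = np.abs(np.arange(12)[:, None] - np.arange(12)[None]) >= 3
        assert d[nb].min() > hard - 1e-9


def test_thermostat_equipartition(q4_system):
    sim = DMDSimulation(q4_system, 0.7, seed=11)
    sim.advance(1500.0)
    traj = sim.trajectory()
    ke_per_dof = traj.kinetic[traj.analysis_mask] / (0.5 * 3 * 12)
    blocks = np.array_split(ke_per_dof, 10)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean() - 0.7) < 3 * se + 0.02


def test_collapse_energy_lower_at_low_temperature():
    model = build_construct("QN", 6)
    lo = run_dmd(model, 0.5, 1200.0, seed=13).analysis_frames()
    hi = run_dmd(model, 0.85, 1200.0, seed=13).analysis_frames()
    assert lo.potential.mean() < hi.potential.mean()


def test_invalid_simulation_inputs(q4_system):
    with pytest.raises(ValueError):
        DMDSimulation(q4_system, -0.5, seed=1)
    big = np.zeros((q4_system.n_beads, 3))
    big[0] = [0, 0, 10 * q4_system.box_edge]
    with pytest.raises(ValueError):
        DMDSimulation(q4_system, 0.5, start_positions=big)
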