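"""WHAM: density-of-states recovery, heat capacity, transition peaks."""

import numpy as np
import pytest

from polyqmd.synthetic import make_replica_energy_samples
from polyqmd.wham import (EnergyHistogramSet, average_transition_temperature,
                          find_transition, heat_capacity, HeatCapacityCurve,
                          solve_wham)
from polyqmd.units import KELVIN_PER_UNIT


def schottky_cv(t, eps=1.0, g=1.0):
    """Closed-form two-level heat capacity (k_B = 1)."""
    x = eps / t
    b = g * np.exp(-x)
    return x * x * b / (1 + b) ** 2


def exact_two_level_dos(eps=1.0, g=1.0):
    e = np.array([0.0, eps])
    lw = np.array([0.0, np.log(g)])
    from polyqmd.wham import DensityOfStates
    return DensityOfStates(e, lw, np.zeros(1), np.array([1.0]), 0, True, 0.0)


def test_single_replica_limit():
    # Ω(E) ∝ h(E) exp(E/T) when only one temperature is histogrammed
    t = 0.8
    edges = np.linspace(0.0, 5.0, 11)
    counts = np.array([[5, 9, 14, 20, 11, 7, 4, 3, 2, 1]], dtype=float)
    hists = EnergyHistogramSet(edges, np.array([t]), counts)
    dos = solve_wham(hists)
    centers = hists.bin_centers
    expected = np.log(counts[0]) + centers / t
    diff = dos.log_omega - expected
    assert np.allclose(diff, diff[0], atol=1e-9)   # equal up to a constant


def test_two_level_degeneracy_recovered():
    g = 4.0
    hists, _ = make_replica_energy_samples(
        np.array([0.0, 1.0]), np.array([0.0, np.log(g)]),
        temperatures=(1.2, 0.6), n_per_replica=40_000, seed=5)
    dos = solve_wham(hists)
    ratio = np.exp(dos.log_omega[1] - dos.log_omega[0])
    assert ratio == pytest.approx(g, rel=0.05)


def test_heat_capacity_trivial_and_schottky():
    # single level: no fluctuations
    from polyqmd.wham import DensityOfStates
    single = DensityOfStates(np.array([2.0]), np.array([0.0]),
                             np.zeros(1), np.array([1.0]), 0, True, 0.0)
    t_grid = np.linspace(0.2, 2.0, 20)
    assert np.allclose(heat_capacity(single, t_grid).c_v, 0.0)

    for g in (1.0, 3.0):
        dos = exact_two_level_dos(eps=1.0, g=g)
        curve = heat_capacity(dos, t_grid)
        assert np.allclose(curve.c_v, schottky_cv(t_grid, 1.0, g),
                           rtol=1e-6, atol=1e-12)


def test_gaussian_dos_gives_constant_variance():
    # Ω Gaussian with variance s²: energy variance ≈ s² for kT ≫ grid step
    s = 2.0
    e = np.linspace(-40, 40, 2001)
    from polyqmd.wham import DensityOfStates
    dos = DensityOfStates(e, -e**2 / (2 * s * s), np.zeros(1),
                          np.array([1.0]), 0, True, 0.0)
    for t in (1.0, 2.5):
        cv = heat_capacity(dos, np.array([t])).c_v[0]
        assert cv == pytest.approx(s * s / t**2, rel=1e-6)


def test_find_transition_matches_dense_scan_oracle():
    dos = exact_two_level_dos(eps=1.0, g=1.0)
    grid = np.linspace(0.1, 1.5, 300)
    curve = heat_capacity(dos, grid)
    peak = find_transition(curve)
    dense = np.arange(0.1, 1.5, 1e-5)
    t_star = dense[np.argmax(schottky_cv(dense))]
    assert peak is not None
    assert peak.temperature == pytest.approx(t_star, abs=5e-4)
    assert peak.temperature_kelvin == pytest.approx(
        t_star * KELVIN_PER_UNIT, rel=1e-3)


def test_find_transition_edge_cases():
    t = np.linspace(0.1, 1.0, 50)
    rising = HeatCapacityCurve(t, t.copy(), np.zeros_like(t))
    assert find_transition(rising) is None

    # two equal maxima: the lower-temperature one wins
    c = np.zeros_like(t)
    c[10] = c[30] = 5.0
    twin = HeatCapacityCurve(t, c, np.zeros_like(t))
    peak = find_transition(twin)
    assert peak.temperature == pytest.approx(t[10], abs=(t[1] - t[0]))

    with pytest.raises(ValueError):
        find_transition(HeatCapacityCurve(t[:2], c[:2], c[:2]))


def test_broad_peak_flagged_non_cooperative():
    # grid must bracket the transition: prominence is edge-sensitive
    t = np.linspace(0.05, 1.4, 200)
    sharp = heat_capacity(exact_two_level_dos(1.0, 50.0), t)
    assert find_transition(sharp).cooperative
    # a unit-degeneracy two-level system has a broad, shallow peak
    # (relative half-height width ~1.7): the weak coil-globule case
    broad = heat_capacity(exact_two_level_dos(1.0, 1.0), t)
    pk = find_transition(broad)
    assert pk is not None and not pk.cooperative


def test_average_transition_temperature_printed_values():
    # caption temperatures of the full-exon1 models and the ΔpolyP models
    assert round(average_transition_temperature([308, 308, 325, 304])) == 311
    assert average_transition_temperature([365, 335, 317, 343]) == 340.0
    assert average_transition_temperature([290.0]) == 290.0
    with pytest.raises(ValueError):
        average_transition_temperature([])


def test_wham_invariances():
    e_grid = np.linspace(-8, 8, 81)
    lw = -e_grid**2 / 6.0
    hists, _ = make_replica_energy_samples(e_grid, lw, (1.0, 0.7, 0.5),
                                           n_per_replica=5000, seed=9)
    dos = solve_wham(hists)
    # replica order invariance (up to gauge)
    perm = EnergyHistogramSet(hists.bin_edges, hists.temperatures[::-1],
                              hists.counts[::-1])
    dos_p = solve_wham(perm)
    d = dos.log_omega - dos_p.log_omega
    assert np.allclose(d - d.mean(), 0.0, atol=1e-6)
    # doubling the counts changes nothing (up to gauge)
    dbl = EnergyHistogramSet(hists.bin_edges, hists.temperatures,
                             2 * hists.counts)
    dos_d = solve_wham(dbl)
    d2 = dos.log_omega - dos_d.log_omega
    assert np.allclose(d2 - d2.mean(), 0.0, atol=1e-6)
    t_grid = np.linspace(0.4, 1.2, 30)
    assert np.allclose(heat_capacity(dos, t_grid).c_v,
                       heat_capacity(dos_d, t_grid).c_v, rtol=1e-6)
    assert np.all(heat_capacity(dos, t_grid).c_v >= 0)


def test_non_overlapping_histograms_rejected():
    edges = np.linspace(0, 10, 11)
    counts = np.zeros((2, 10))
    counts[0, :3] = 5
    counts[1, 7:] = 5
    with pytest.raises(ValueError):
        solve_wham(EnergyHistogramSet(edges, np.array([1.0, 0.5]), counts))


def test_empty_histogram_rejected():
    edges = np.linspace(0, 10, 11)
    counts = np.zeros((2, 10))
    counts[0, :5] = 5
    with pytest.raises(ValueError):
        solve_wham(EnergyHistogramSet(edges, np.array([1.0, 0.5]), counts))


def test_peak_sharpens_with_sample_size():
    # parameter recovery improves from 1e3 to 1e5 samples per replica
    eps, g = 1.0, 60.0
    e = np.array([0.0, eps])
    lw = np.array([0.0, np.log(g)])
    temps = (0.5, 0.4, 0.3, 0.2)
    dense = np.arange(0.05, 1.0, 1e-4)
    t_true = dense[np.argmax(schottky_cv(dense, eps, g))]
    errs = []
    for n in (1000, 100_000):
        hists, _ = make_replica_energy_samples(e, lw, temps, n, seed=21)
        curve = heat_capacity(solve_wham(hists), np.linspace(0.05, 1.0, 400))
        peak = find_transition(curve)
        errs.append(abs(peak.temperature - t_true))
    assert errs[1] <= errs[0] + 1e-3
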