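"""Compact-ensemble screening, crossing counts, and error formula."""

import numpy as np
import pytest

from polyqmd.screen import (ScreenHistogram, ScreenVariable, count_crossings,
                            probability_standard_error,
                            propose_energy_cutoff, propose_rg_cutoff,
                            select_compact)
from polyqmd.synthetic import make_two_state_energy_series


def hist_of(values, width=1.0):
    return ScreenHistogram.from_samples(ScreenVariable.RG, values, width)


# --- Rg cutoff ------------------------------------------------------------

def test_single_bin_histogram_cutoff_is_upper_edge():
    h = ScreenHistogram(ScreenVariable.RG, np.array([15.0, 16.0]),
                        np.array([42]))
    assert propose_rg_cutoff(h) == 16.0


def test_gaussian_rg_sample_lands_near_twenty(rng):
    # unimodal Rg distribution peaked near 16 Å, as in compact polypeptides
    sample = rng.normal(16.0, 1.2, size=100_000)
    cut = propose_rg_cutoff(hist_of(sample))
    assert 19.0 <= cut <= 21.0


def test_bimodal_cutoff_beyond_first_mode(rng):
    sample = np.concatenate([rng.normal(10.0, 0.8, 50_000),
                             rng.normal(25.0, 2.0, 10_000)])
    cut = propose_rg_cutoff(hist_of(sample))
    assert cut >= 12.0  # past the right flank (~mode + 2.5 sd) of the mode


def test_empty_histogram_rejected():
    h = ScreenHistogram(ScreenVariable.RG, np.array([0.0, 1.0]),
                        np.array([0]))
    with pytest.raises(ValueError):
        propose_rg_cutoff(h)


# --- energy cutoff --------------------------------------------------------

def test_mixture_cutoff_separates_components(rng):
    low = rng.normal(-300.0, 5.0, 30_000)
    high = rng.normal(-250.0, 8.0, 60_000)
    cut = propose_energy_cutoff(np.concatenate([low, high]), seed=0)
    assert (low <= cut).mean() >= 0.95
    assert (high <= cut).mean() <= 0.05


def test_single_gaussian_falls_back_to_decile(rng):
    x = rng.normal(-100.0, 3.0, 20_000)
    with pytest.warns(UserWarning):
        cut = propose_energy_cutoff(x, seed=0)
    assert cut == pytest.approx(np.percentile(x, 10))


def test_cutoff_translation_equivariance(rng):
    x = np.concatenate([rng.normal(-20.0, 1.0, 5000),
                        rng.normal(0.0, 2.0, 5000)])
    c0 = propose_energy_cutoff(x, seed=3)
    c1 = propose_energy_cutoff(x + 37.5, seed=3)
    assert c1 - c0 == pytest.approx(37.5, abs=1e-6)


# --- compact selection ----------------------------------------------------

def test_select_compact_matches_brute_force():
    rg = np.array([12.0, 25.0, 18.0, 20.0, 30.0, 15.0, 19.0, 21.0, 16.0, 9.0])
    en = np.array([-290, -280, -300, -285, -310, -250, -400, -290, -285, -100.])
    ens = select_compact(rg, en, rg_cutoff=20.0, energy_cutoff=-285.0)
    brute = [i for i in range(10) if rg[i] <= 20.0 and en[i] <= -285.0]
    assert list(ens.frame_indices) == brute
    assert ens.fraction == len(brute) / 10


def test_select_compact_extremes():
    rg = np.linspace(10, 20, 7)
    en = np.linspace(-300, -200, 7)
    assert select_compact(rg, en, 5.0, -400.0).fraction == 0.0
    assert select_compact(rg, en, 50.0, 0.0).fraction == 1.0


def test_select_compact_monotone_in_cutoffs(rng):
    rg = rng.uniform(10, 30, 200)
    en = rng.uniform(-320, -200, 200)
    base = select_compact(rg, en, 18.0, -260.0).n_frames
    assert select_compact(rg, en, 22.0, -260.0).n_frames >= base
    assert select_compact(rg, en, 18.0, -240.0).n_frames >= base


# --- crossing counts ------------------------------------------------------

@pytest.mark.parametrize("series,cutoff,expected", [
    ([5.0, 5.0, 5.0], 0.0, 0),                       # constant
    ([-300, -250, -300, -250], -285, 3),             # by-hand sign changes
    ([-200, -240, -280, -320, -360], -285, 1),       # monotone descent
    ([-300, -285, -250], -285, 1),                   # at-cutoff: previous sign
    ([-250, -285, -300], -285, 1),
    ([], -285, 0),
])
def test_count_crossings_examples(series, cutoff, expected):
    assert count_crossings(np.array(series, dtype=float), cutoff) == expected


def test_crossings_reversal_invariant(rng):
    e = rng.normal(-285, 10, 500)
    assert count_crossings(e, -285.0) == count_crossings(e[::-1], -285.0)


def test_crossings_match_telegraph_ground_truth():
    ts = make_two_state_energy_series(-300.0, -250.0, switch_rate=0.05,
                                      within_state_sd=2.0, n=5000, seed=4)
    counted = count_crossings(ts.energies, -275.0)
    assert counted == ts.true_transitions  # sd ≪ level gap: no extra crossings


def test_zero_switch_rate_never_crosses():
    ts = make_two_state_energy_series(-300.0, -250.0, switch_rate=0.0,
                                      within_state_sd=1.0, n=2000, seed=7)
    assert count_crossings(ts.energies, -275.0) == 0


# --- standard error -------------------------------------------------------

def test_standard_error_closed_form():
    assert probability_standard_error(0.0, 50) == 0.0
    assert probability_standard_error(1.0, 50) == 0.0
    assert probability_standard_error(0.5, 100) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        probability_standard_error(0.5, 0)
    with pytest.raises(ValueError):
        probability_standard_error(1.5, 10)


def test_standard_error_matches_resampling_oracle():
    # Repeatedly simulate two-state trajectories; the spread of the
    # occupancy estimate across runs should match the crossing-count
    # binomial error to within a factor ~2.
    occupancies, ses = [], []
    for seed in range(60):
        ts = make_two_state_energy_series(-300.0, -250.0, switch_rate=0.02,
                                          within_state_sd=2.0, n=4000,
                                          seed=100 + seed)
        p = float((ts.energies < -275.0).mean())
        n_ev = count_crossings(ts.energies, -275.0)
        occupancies.append(p)
        if n_ev >= 1:
            ses.append(probability_standard_error(p, n_ev))
    empirical = np.std(occupancies, ddof=1)
    formula = np.mean(ses)
    assert 0.4 < empirical / formula < 2.5
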