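"""LIF simulator: analytic oracle, determinism, refractoriness, calibration."""

import math

import numpy as np
import pytest

from neurorace.decision import IgnitionRule, detect_ignition
from neurorace.lif import (
    DEFAULT_DRIVE,
    DEFAULT_WEIGHT,
    LIFParams,
    SimConfig,
    StimulusSpec,
    calibrate_weight,
    choose_stimulated,
    simulate,
    single_neuron_first_spike,
)
from neurorace.topology import CATopology, generate_topology


def isolated_pair(weight=1e-9):
    """Two mutually connected neurons with negligible coupling: effectively
    isolated single neurons (the minimal legal topology)."""
    return CATopology(
        n_neurons=2, k_out=1, pre=np.array([0, 1]), post=np.array([1, 0]), weight=weight, seed=0
    )


def first_spike_of(record, neuron_id):
    mine = record.times[record.neuron_ids == neuron_id]
    return int(mine[0]) if len(mine) else None


class TestSingleNeuronOracle:
    def test_subthreshold_never_fires(self):
        params = LIFParams()
        # I*R = 0.5*20 = 10 mV < 15 mV gap
        assert single_neuron_first_spike(params, 0.5) is None

    def test_ir_twice_gap_gives_tau_ln2(self):
        params = LIFParams()
        gap = params.v_thresh - params.v_rest
        i_dc = 2 * gap / params.r_m
        assert single_neuron_first_spike(params, i_dc) == pytest.approx(
            params.tau_m * math.log(2)
        )

    def test_simulation_matches_closed_form_over_random_draws(self):
        """Discrete 1 ms simulation lands within one step of the continuous
        first-passage time across 20 random parameter/current draws."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            params = LIFParams(
                tau_m=float(rng.uniform(5, 40)),
                c_m=float(rng.uniform(0.5, 2.0)),
                v_thresh=float(rng.uniform(-55, -45)),
                t_refrac=float(rng.choice([0.1, 1.0, 2.0])),
            )
            gap = params.v_thresh - params.v_rest
            i_dc = float(rng.uniform(1.05, 3.0)) * gap / params.r_m
            t_star = single_neuron_first_spike(params, i_dc)
            assert t_star is not None
            rec = simulate(
                isolated_pair(),
                params,
                StimulusSpec(stimulated_ids=np.array([0]), drive=i_dc),
                SimConfig(t_max=max(300, int(t_star) + 10), stop_on_ignition=False),
            )
            t_sim = first_spike_of(rec, 0)
            assert t_sim is not None
            assert abs(t_sim - math.ceil(t_star)) <= 1


def test_resting_network_stays_silent():
    """No stimulation and no offset current: the record is empty."""
    topo = generate_topology(50, 5, seed=3)
    rec = simulate(topo, LIFParams(), StimulusSpec(stimulated_ids=np.array([], dtype=int)),
                   SimConfig(t_max=100, stop_on_ignition=False))
    assert rec.n_events == 0
    assert rec.counts_per_ms.sum() == 0


def test_determinism_identical_inputs_identical_record(default_topology):
    stim = StimulusSpec(stimulated_ids=choose_stimulated(500, 100, seed=5), drive=DEFAULT_DRIVE)
    cfg = SimConfig(t_max=80, stop_on_ignition=False)
    a = simulate(default_topology, LIFParams(), stim, cfg)
    b = simulate(default_topology, LIFParams(), stim, cfg)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.neuron_ids, b.neuron_ids)
    assert np.array_equal(a.counts_per_ms, b.counts_per_ms)


def test_population_count_conservation(default_topology):
    stim = StimulusSpec(stimulated_ids=choose_stimulated(500, 100, seed=5), drive=DEFAULT_DRIVE)
    rec = simulate(default_topology, LIFParams(), stim, SimConfig(t_max=70), IgnitionRule())
    assert rec.counts_per_ms.sum() == rec.n_events
    # no neuron spikes twice within one ms
    for t in np.unique(rec.times):
        ids = rec.neuron_ids[rec.times == t]
        assert len(ids) == len(np.unique(ids))


def test_refractory_blocks_consecutive_steps_when_long():
    """t_refrac=2 ms forces at least one silent step between spikes; the
    default 0.1 ms allows firing in consecutive steps."""
    strong = 5.0  # fires every few ms
    rec_long = simulate(
        isolated_pair(), LIFParams(t_refrac=2.0),
        StimulusSpec(stimulated_ids=np.array([0]), drive=strong),
        SimConfig(t_max=100, stop_on_ignition=False),
    )
    mine = rec_long.times[rec_long.neuron_ids == 0]
    assert len(mine) > 3
    assert np.all(np.diff(mine) >= 3)  # spike step + 2 refractory steps

    rec_fast = simulate(
        isolated_pair(), LIFParams(t_refrac=0.1),
        StimulusSpec(stimulated_ids=np.array([0]), drive=50.0),
        SimConfig(t_max=20, stop_on_ignition=False),
    )
    mine = rec_fast.times[rec_fast.neuron_ids == 0]
    assert np.any(np.diff(mine) == 1)


def test_non_finite_potential_aborts():
    with pytest.raises(FloatingPointError):
        simulate(
            isolated_pair(), LIFParams(i_offset=1e308),
            StimulusSpec(stimulated_ids=np.array([0]), drive=1e308),
            SimConfig(t_max=5, stop_on_ignition=False),
        )


def test_growth_faster_with_more_stimulated(default_topology):
    """On the same assembly the population count trends higher with 100
    stimulated neurons than with 50."""
    recs = {}
    for k in (50, 100):
        stim = StimulusSpec(stimulated_ids=choose_stimulated(500, k, seed=11), drive=DEFAULT_DRIVE)
        recs[k] = simulate(default_topology, LIFParams(), stim,
                           SimConfig(t_max=120, stop_on_ignition=False))
    c50 = np.cumsum(recs[50].counts_per_ms)
    c100 = np.cumsum(recs[100].counts_per_ms)
    assert c100[-1] > c50[-1]
    assert np.all(c100 >= c50)


def test_ignition_truncates_record(default_topology):
    stim = StimulusSpec(stimulated_ids=choose_stimulated(500, 100, seed=1 * 7919 + 100),
                        drive=DEFAULT_DRIVE)
    rule = IgnitionRule()
    rec = simulate(default_topology, LIFParams(), stim, SimConfig(t_max=300), rule)
    assert rec.truncated_at is not None
    assert rec.times.max() <= rec.truncated_at
    res = detect_ignition(rec, rule)
    assert res.ignited and res.t_ignite == rec.truncated_at


class TestCalibration:
    def test_weight_to_zero_never_ignites(self):
        """Without recurrent spread the stimulated neurons alone cannot reach
        1100 spikes in 10 ms (at most k spikes per window per cycle)."""
        topo = generate_topology(500, 30, weight=1e-6, seed=1)
        stim = StimulusSpec(stimulated_ids=choose_stimulated(500, 100, seed=7),
                            drive=DEFAULT_DRIVE)
        rec = simulate(topo, LIFParams(), stim, SimConfig(t_max=200), IgnitionRule())
        assert rec.truncated_at is None
        assert not detect_ignition(rec).ignited

    def test_larger_weight_ignites_no_later(self):
        times = []
        for w in (0.25, 0.30, 0.40):
            topo = generate_topology(500, 30, weight=w, seed=2)
            stim = StimulusSpec(stimulated_ids=choose_stimulated(500, 100, seed=13),
                                drive=DEFAULT_DRIVE)
            rec = simulate(topo, LIFParams(), stim, SimConfig(t_max=300), IgnitionRule())
            assert rec.truncated_at is not None
            times.append(rec.truncated_at)
        assert times[0] >= times[1] >= times[2]

    def test_grid_search_recovers_shipped_defaults(self):
        """A reduced grid containing the shipped defaults selects them."""
        w, d = calibrate_weight(
            weight_grid=(0.22, 0.30, 0.38),
            drive_grid=(0.85, 1.0),
            n_assemblies=3,
            t_max=300,
        )
        assert (w, d) == (DEFAULT_WEIGHT, DEFAULT_DRIVE)

    def test_non_bracketing_grid_reported(self):
        with pytest.raises(RuntimeError):
            calibrate_weight(
                weight_grid=(1e-6,), drive_grid=(0.85,), n_assemblies=2, t_max=150
            )


def test_config_json_roundtrip(tmp_path):
    from neurorace.lif import load_config, save_config

    p = tmp_path / "net.json"
    save_config(p, LIFParams(tau_m=25.0), weight=0.3, drive=0.85, seed=4)
    back = load_config(p)
    assert back["params"].tau_m == 25.0
    assert (back["weight"], back["drive"], back["seed"]) == (0.3, 0.85, 4)
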