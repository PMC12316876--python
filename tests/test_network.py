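"""Network construction: connectivity statistics, delays, determinism,
attractor preloading and ablation."""

import dataclasses
import math

import numpy as np
import pytest

from epimem.network import (
    ASSOC,
    BP,
    PB,
    WITHIN_PP,
    WITHIN_PPL,
    BuildError,
    MemoryPattern,
    ablate,
    build_network,
    default_patterns,
    preload_attractors,
    sample_delay,
)
from epimem.params import ConnectivityParams, ExperimentConfig, LayoutParams


@pytest.fixture(scope="module")
def small_model(tiny_config):
    return build_network(tiny_config, seed=11, n_items=4, n_contexts=2)


def test_seed_is_mandatory(tiny_config):
    with pytest.raises(BuildError):
        build_network(tiny_config, seed=None)


def test_neuron_totals(tiny_config, small_model):
    lay = tiny_config.layout
    n_pyr = 2 * lay.n_hc * lay.n_mc_per_hc * lay.n_pyr_per_mc
    n_bas = 2 * lay.n_hc * lay.n_mc_per_hc * lay.n_basket_per_mc
    assert small_model.n_neurons == n_pyr + n_bas
    assert small_model.is_pyr.sum() == n_pyr


def test_full_scale_layout_totals():
    """The full-scale grid carries 8640 pyramidal and 1152 basket cells
    across both networks."""
    lay = LayoutParams()
    assert 2 * lay.n_pyr == 8640
    assert 2 * lay.n_basket == 1152


def test_connection_counts_within_binomial_bounds(tiny_config, small_model):
    """Realized per-class edge counts lie within 4 SD of the binomial
    expectation."""
    lay = tiny_config.layout
    conn = tiny_config.connectivity
    n_pyr_net = lay.n_pyr
    counts = {c: int((small_model.conn_class == c).sum())
              for c in (WITHIN_PP, WITHIN_PPL, ASSOC, PB, BP)}
    n_within_pairs = 2 * n_pyr_net * (n_pyr_net - 1)
    expect_within = conn.cp_pp * n_within_pairs
    sd = math.sqrt(n_within_pairs * conn.cp_pp * (1 - conn.cp_pp))
    total_within = counts[WITHIN_PP] + counts[WITHIN_PPL]
    assert abs(total_within - expect_within) < 4 * sd
    n_assoc_pairs = 2 * n_pyr_net * n_pyr_net
    expect_assoc = conn.cp_ppa * n_assoc_pairs
    sd_a = math.sqrt(n_assoc_pairs * conn.cp_ppa * (1 - conn.cp_ppa))
    assert abs(counts[ASSOC] - expect_assoc) < 4 * sd_a


def test_build_is_deterministic(tiny_config):
    a = build_network(tiny_config, seed=5, n_items=4, n_contexts=2)
    b = build_network(tiny_config, seed=5, n_items=4, n_contexts=2)
    np.testing.assert_array_equal(a.post, b.post)
    np.testing.assert_array_equal(a.delay_ms, b.delay_ms)
    np.testing.assert_array_equal(a.w_ampa, b.w_ampa)
    c = build_network(tiny_config, seed=6, n_items=4, n_contexts=2)
    assert a.n_connections != c.n_connections or not np.array_equal(
        a.post[:100], c.post[:100])


def test_basket_connections_are_local(small_model):
    """Basket in/out connectivity never leaves the home hypercolumn."""
    small_model.validate()
    pre = np.repeat(np.arange(small_model.n_neurons),
                    np.diff(small_model.indptr))
    pb = small_model.conn_class == PB
    assert (small_model.hc_id[pre[pb]]
            == small_model.hc_id[small_model.post[pb]]).all()


class TestDelays:
    def test_all_delays_above_minimum(self, small_model):
        assert (small_model.delay_ms >= 1.5 - 1e-9).all()

    @pytest.mark.parametrize("dist,speed,mean", [
        (0.0, 0.2, 1.5),       # synaptic delay only
        (10.0, 2.0, 6.5),      # between networks, myelinated
        (0.5, 0.2, 4.0),       # within network
    ])
    def test_mean_delay_arithmetic(self, dist, speed, mean, rng):
        cfg = ConnectivityParams()
        pre = np.zeros((4000, 2))
        post = np.c_[np.full(4000, dist), np.zeros(4000)]
        d = sample_delay(pre, post, speed, rng, cfg)
        assert d.min() >= cfg.t_min_syn - 1e-12
        if dist == 0.0:
            # the distribution centres on t_min_syn; the lower clamp
            # collapses half the mass onto exactly 1.5 ms
            assert np.median(d) == pytest.approx(mean, abs=1e-6)
        else:
            sd = cfg.delay_rel_sd * mean / math.sqrt(4000)
            assert d.mean() == pytest.approx(mean, abs=max(5 * sd,
                                                           0.02 * mean))

    def test_relative_spread(self, rng):
        cfg = ConnectivityParams()
        pre = np.zeros((8000, 2))
        post = np.c_[np.full(8000, 10.0), np.zeros(8000)]
        d = sample_delay(pre, post, 2.0, rng, cfg)
        assert d.std() == pytest.approx(0.3 * 6.5, rel=0.05)


@pytest.fixture(scope="module")
def preload():
    return preload_attractors(ExperimentConfig(), n_items=16)


class TestPreload:
    def test_weight_ordering_matches_attractor_structure(self, preload):
        """Within-HC same-pattern weights exceed cross-HC same-pattern
        weights, which are positive; competing patterns are coupled with
        negative (disynaptic-inhibition) weights."""
        wa = {k: v[0] for k, v in preload.weights.items()}
        assert wa["same_mc"] > wa["same_pattern"] > 0
        assert wa["diff_pattern"] < 0
        assert abs(wa["silent"]) < 1e-6

    def test_population_epsp_matches_target(self, preload):
        assert preload.mean_epsp_within_hc == pytest.approx(0.72, abs=0.01)

    def test_simulated_epsp_agrees_with_closed_form(self, preload):
        """Delivering the preloaded within-HC weight onto a resting
        neuron reproduces the closed-form EPSP within 5%."""
        from epimem.neuron import SingleNeuronSim
        from epimem.network import first_spike_release_gain
        gain = first_spike_release_gain(0.2)
        wa, wn = preload.weights["same_mc"]
        sim = SingleNeuronSim()
        out = sim.run(300.0, conductance_events=[
            (10.0, "ampa", gain * wa), (10.0, "nmda", gain * wn)])
        peak = (out["V_m"] - out["V_m"][0]).max()
        assert peak == pytest.approx(preload.mean_epsp_within_hc, rel=0.05)

    def test_preload_is_deterministic(self):
        a = preload_attractors(ExperimentConfig(), n_items=16)
        b = preload_attractors(ExperimentConfig(), n_items=16)
        assert a.weights == b.weights and a.t_gap == b.t_gap


def test_overlapping_patterns_rejected(tiny_config):
    pats = default_patterns(tiny_config.layout, 4, 2)
    pats.append(MemoryPattern(99, 0, pats[0].mc_in_hc))
    with pytest.raises(BuildError):
        build_network(tiny_config, seed=1, patterns=pats)


def test_frozen_weights_assigned_to_within_classes(small_model):
    within = ((small_model.conn_class == WITHIN_PP)
              | (small_model.conn_class == WITHIN_PPL))
    assert small_model.frozen[within].all()
    pre = np.repeat(np.arange(small_model.n_neurons),
                    np.diff(small_model.indptr))
    same = within & (small_model.pattern_id[pre] >= 0) & (
        small_model.pattern_id[pre]
        == small_model.pattern_id[small_model.post])
    assert small_model.w_ampa[same].mean() > 0
    diff = within & (small_model.pattern_id[pre] >= 0) & (
        small_model.pattern_id[small_model.post] >= 0) & (
        small_model.pattern_id[pre]
        != small_model.pattern_id[small_model.post])
    assert small_model.w_ampa[diff].mean() < 0


class TestAblation:
    def test_negative_associative_weights_severed(self, tiny_config):
        m = build_network(tiny_config, seed=11, n_items=4, n_contexts=2)
        assoc = m.conn_class == ASSOC
        m.w_ampa[assoc] = np.linspace(-1, 1, assoc.sum())
        pos_before = m.w_ampa[assoc & (m.w_ampa > 0)].copy()
        ablate(m, "associative_disynaptic_inhibition")
        assert (m.w_ampa[assoc] >= 0).all()
        np.testing.assert_array_equal(
            m.w_ampa[assoc & (m.w_ampa > 0)], pos_before)
        assert "associative_disynaptic_inhibition" in m.ablated

    def test_unknown_key_rejected(self, small_model):
        with pytest.raises(ValueError):
            ablate(small_model, "nope")
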