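"""LIF/synaptic integration: closed forms, impulse bookkeeping, LFP."""

import numpy as np
import pytest

from spikeweave.dynamics import (
    CurrentsTrace,
    NeuronParams,
    Simulator,
    SynapseParams,
    attenuation,
    compute_lfp,
    integrate,
)
from spikeweave.encoding import SpikeTrain, poisson_spikes
from spikeweave.topology import (
    AMPA,
    Connectivity,
    build_connectivity,
    build_population,
    wire_external,
)


def make_conn(pre, post, kind, weight, r):
    return Connectivity(
        pre=np.asarray(pre, dtype=int),
        post=np.asarray(post, dtype=int),
        kind=np.asarray(kind, dtype=np.int8),
        weight=np.asarray(weight, dtype=float),
        r=np.asarray(r, dtype=float),
    )


class TestFreeDecay:
    def test_membrane_decays_with_tau_m(self, empty_conn):
        pop = build_population(n=2, frac_exc=0.5, grid=(1, 2))
        sim = Simulator(pop, empty_conn)
        sim.set_v(np.array([10.0, 10.0]))
        sim.run(20.0)
        taus = np.where(pop.is_excitatory, 20.0, 10.0)
        expected = 10.0 * np.exp(-20.0 / taus)
        np.testing.assert_allclose(sim.v, expected, rtol=1e-6)

    def test_synaptic_states_decay_with_their_taus(self, empty_conn):
        pop = build_population(n=1, frac_exc=1.0, grid=(1, 1))
        sim = Simulator(pop, empty_conn)
        sim.Y[2, 0] = 5.0  # x_A
        sim.Y[4, 0] = 5.0  # x_G
        sim.run(1.0)
        assert sim.Y[2, 0] == pytest.approx(5 * np.exp(-1 / 0.4), rel=1e-9)
        assert sim.Y[4, 0] == pytest.approx(5 * np.exp(-1 / 0.25), rel=1e-9)


class TestConstantDrive:
    def test_interspike_interval_closed_form(self, empty_conn):
        pop = build_population(n=1, frac_exc=1.0, grid=(1, 1))
        sim = Simulator(pop, empty_conn, dt=0.05)
        drive = 25.0
        res = sim.run(400.0, i_const=np.array([drive]))
        isi = np.diff(res.spikes.spikes[0])
        expected = 2.0 + 20.0 * np.log(drive / (drive - 18.0))
        assert np.all(np.abs(isi - expected) <= 2 * 0.05 + 1e-12)

    def test_subthreshold_drive_never_fires(self, empty_conn):
        pop = build_population(n=1, frac_exc=1.0, grid=(1, 1))
        sim = Simulator(pop, empty_conn)
        res = sim.run(300.0, i_const=np.array([17.0]))
        assert res.spikes.n_spikes == 0
        assert sim.v[0] == pytest.approx(17.0, rel=1e-6)


class TestImpulseDelivery:
    def test_external_impulse_latency_and_magnitude(self):
        pop = build_population(n=1, frac_exc=1.0, grid=(1, 1))
        conn = wire_external(pop, j_ext=5.0)
        ext = SpikeTrain(spikes={0: np.array([0.0])}, duration=2.0)
        before = Simulator(pop, conn)
        before.run(1.0, external=ext)
        assert before.Y[2, 0] == 0.0  # nothing before the 1 ms latency
        after = Simulator(pop, conn)
        after.run(1.05, external=ext)
        # jump tau_m * J = 100 at t = 1.0, then one step of decay
        assert after.Y[2, 0] == pytest.approx(100 * np.exp(-0.05 / 0.4), rel=1e-9)

    def test_recurrent_impulse_attenuated_by_distance(self):
        pop = build_population(n=2, frac_exc=1.0, grid=(1, 2))
        r = 7.0
        conn = make_conn([0], [1], [AMPA], [1.5], [r])
        syn = SynapseParams(D=10.0)
        sim = Simulator(pop, conn, syn=syn)
        forced = SpikeTrain(spikes={0: np.array([0.05])}, duration=2.0)
        # delivery happens at 0.05 + 1.0 = 1.05, the start of the next step
        sim.run(1.10, forced=forced)
        expected = 20.0 * np.exp(-r / 10.0) * 1.5 * np.exp(-0.05 / 0.4)
        assert sim.Y[2, 1] == pytest.approx(expected, rel=1e-9)

    def test_impulse_bookkeeping_audit(self):
        # conservation: reported injected drive equals the sum over delivered
        # events of tau_m * e^(-r/D) * J, computed independently from spikes
        pop = build_population(n=40, frac_exc=0.8, grid=(5, 8))
        conn = build_connectivity(pop, p=0.3, weight_sd=1.0, seed=3)
        conn = conn.extend(wire_external(pop, j_ext=2.0))
        syn = SynapseParams(D=10.0)
        sim = Simulator(pop, conn, syn=syn)
        ext = poisson_spikes(np.full(180, 800.0), 1.0, 40, seed=8)
        res = sim.run(200.0, external=ext)

        tau_m = np.where(pop.is_excitatory, 20.0, 10.0)
        rec = conn.kind != 2
        gains = tau_m[conn.post[rec]] * np.exp(-conn.r[rec] / 10.0) * conn.weight[rec]
        expected_A = expected_G = 0.0
        for nid, times in res.spikes.spikes.items():
            out = np.nonzero(conn.pre[rec] == nid)[0]
            g = gains[out]
            gaba = conn.kind[rec][out] == 1
            expected_A += times.size * g[~gaba].sum()
            expected_G += times.size * g[gaba].sum()
        # external gain is tau_m(post) * J per channel
        for ch, times in ext.spikes.items():
            expected_A += times.size * tau_m[ch] * 2.0
        assert res.injected_ampa == pytest.approx(expected_A, rel=1e-9)
        assert res.injected_gaba == pytest.approx(expected_G, rel=1e-9)


class TestRefractoriness:
    def test_no_spikes_closer_than_tau_rp(self, empty_conn):
        pop = build_population(n=10, frac_exc=0.8, grid=(2, 5))
        sim = Simulator(pop, empty_conn)
        res = sim.run(500.0, i_const=np.full(10, 40.0))
        for nid, t in res.spikes.spikes.items():
            tau_rp = 2.0 if pop.is_excitatory[nid] else 1.0
            assert np.all(np.diff(t) >= tau_rp - 1e-9)

    def test_membrane_clamped_during_refractory(self, empty_conn):
        pop = build_population(n=1, frac_exc=1.0, grid=(1, 1))
        sim = Simulator(pop, empty_conn)
        res = sim.run(30.0, i_const=np.array([30.0]))
        first = res.spikes.spikes[0][0]
        sim2 = Simulator(pop, empty_conn)
        sim2.run(first + 1.0, i_const=np.array([30.0]))
        assert sim2.v[0] == 0.0  # v_res while refractory


class TestStepSizeRobustness:
    def test_halving_dt_preserves_spike_times(self):
        pop = build_population(n=20, frac_exc=0.8, grid=(4, 5))
        conn = build_connectivity(pop, p=0.2, weight_sd=1.0, seed=5)
        conn = conn.extend(wire_external(pop, j_ext=2.0))
        # grid-aligned external times so both step sizes see identical input
        times = np.arange(0.4, 150.0, 0.8)
        ext = SpikeTrain(
            spikes={ch: times.copy() for ch in range(20)}, duration=150.0
        )
        trains = {}
        for dt in (0.05, 0.025):
            sim = Simulator(pop, conn, syn=SynapseParams(D=10.0), dt=dt)
            trains[dt] = sim.run(150.0, external=ext).spikes
        assert trains[0.05].counts() == trains[0.025].counts()
        for nid in trains[0.05].spikes:
            d = np.abs(trains[0.05].spikes[nid] - trains[0.025].spikes[nid])
            assert d.max() < 0.1


class TestValidation:
    def test_rejects_bad_dt_and_duration(self, empty_conn):
        pop = build_population(n=1, frac_exc=1.0, grid=(1, 1))
        with pytest.raises(ValueError):
            Simulator(pop, empty_conn, dt=-0.05)
        sim = Simulator(pop, empty_conn)
        with pytest.raises(ValueError):
            sim.run(0.0)

    def test_nonfinite_state_aborts(self, empty_conn):
        pop = build_population(n=1, frac_exc=1.0, grid=(1, 1))
        sim = Simulator(pop, empty_conn)
        with pytest.raises(FloatingPointError):
            sim.run(10.0, i_const=np.array([np.nan]))

    def test_integrate_wrapper_contract(self, empty_conn):
        pop = build_population(n=2, frac_exc=0.5, grid=(1, 2))
        with pytest.raises(ValueError):
            integrate(pop, empty_conn, t0=10.0, t1=5.0)
        sim, spikes, trace = integrate(pop, empty_conn, t0=0.0, t1=10.0)
        assert trace is not None and trace.times.size > 0
        assert spikes.n_spikes == 0


class TestAttenuation:
    def test_limits(self):
        assert attenuation(0.0, 5.0) == pytest.approx(1.0)
        assert attenuation(5.0, 5.0) == pytest.approx(np.exp(-1), abs=1e-4)

    def test_monotone_decreasing(self):
        r = np.linspace(0, 50, 200)
        vals = attenuation(r, 7.0)
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals <= 1))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            attenuation(-1.0, 5.0)


class TestLFP:
    def _trace(self, i_a, i_g):
        i_a = np.asarray(i_a, dtype=float)
        return CurrentsTrace(
            times=np.arange(i_a.shape[1], dtype=float),
            i_ampa=i_a,
            i_gaba=np.asarray(i_g, dtype=float),
            neuron_ids=np.arange(i_a.shape[0]),
        )

    def test_silent_network_zero_lfp(self):
        trace = self._trace(np.zeros((3, 5)), np.zeros((3, 5)))
        _, lfp = compute_lfp(trace, [0, 1, 2])
        assert np.all(lfp == 0)

    def test_absolute_value_definition(self):
        trace = self._trace([[2.0]], [[-1.0]])
        _, lfp = compute_lfp(trace, [0])
        assert lfp[0] == pytest.approx(3.0)

    def test_disjoint_subset_additivity(self, rng):
        trace = self._trace(rng.normal(size=(6, 9)), rng.normal(size=(6, 9)))
        _, full = compute_lfp(trace, np.arange(6))
        _, a = compute_lfp(trace, [0, 1, 2])
        _, b = compute_lfp(trace, [3, 4, 5])
        np.testing.assert_allclose(full, a + b, rtol=1e-12)

    def test_empty_subset_rejected(self):
        trace = self._trace(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            compute_lfp(trace, [])

    def test_tsv_export(self, tmp_path):
        trace = self._trace([[1.0, 2.0]], [[0.5, -0.5]])
        path = tmp_path / "lfp.tsv"
        trace.to_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "time_ms\tvalue"
        assert float(lines[1].split("\t")[1]) == pytest.approx(1.5)
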