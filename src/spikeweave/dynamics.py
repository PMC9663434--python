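"""LIF membrane and AMPA/GABA synaptic-current dynamics.

Each neuron k integrates

    tau_m dv/dt   = -v + I_A - I_G (+ optional constant drive)
    tau_dA dI_A/dt = -I_A + x_A        tau_dG dI_G/dt = -I_G + x_G
    tau_rA dx_A/dt = -x_A + impulses   tau_rG dx_G/dt = -x_G + impulses

Presynaptic spikes arrive after a latency ``tau_L`` and kick the auxiliary
variable of the matching channel by ``tau_m * exp(-r/D) * J`` (no distance
attenuation for the external drive).  Crossing ``v_thr`` emits a spike,
resets v to ``v_res`` and clamps it for the refractory period; synaptic
states keep evolving while v is clamped.

Between events the subsystem is linear and time-invariant, so each step is
advanced with the exact matrix-exponential propagator (one 6x6 ``expm`` per
neuron type at setup); impulses are exact state jumps at event times rounded
up to the next grid point.  This keeps the free membrane decay exact to
machine precision at any dt while preserving grid-aligned event handling.

Optionally the simulator applies spatial STDP online: every neuron carries
exponentially decaying pre/post spike traces, and each spike updates the
weights of its incoming (LTP branch) and outgoing (LTD branch) plastic
synapses, which reproduces the all-pairs double-sum rule exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "CurrentsTrace",
    "Simulator",
    "RunResult",
    "attenuation",
    "compute_lfp",
    "integrate",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF constants: tau_m/tau_rp differ between pyramidal cells and
    interneurons (20/2 vs 10/1 ms); threshold 18 mV, reset 0 mV, latency 1 ms."""

    tau_m: float = 20.0
    v_thr: float = 18.0
    v_res: float = 0.0
    tau_rp: float = 2.0
    tau_L: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau_rp, self.tau_L) <= 0:
            raise ValueError("time constants must be positive")
        if self.v_res < 0 or self.v_thr <= self.v_res:
            raise ValueError("need v_thr > v_res >= 0")

    @classmethod
    def excitatory(cls) -> "NeuronParams":
        return cls(tau_m=20.0, tau_rp=2.0)

    @classmethod
    def inhibitory(cls) -> "NeuronParams":
        return cls(tau_m=10.0, tau_rp=1.0)


@dataclass(frozen=True)
class SynapseParams:
    """AMPA/GABA kinetics and the coupling distance scale D (grid units)."""

    tau_dA: float = 2.0
    tau_rA: float = 0.4
    tau_dG: float = 5.0
    tau_rG: float = 0.25
    D: float = 10.0

    def __post_init__(self) -> None:
        if min(self.tau_dA, self.tau_rA, self.tau_dG, self.tau_rG, self.D) <= 0:
            raise ValueError("all synaptic constants must be positive")


def attenuation(r, D: float):
    """Distance attenuation ``exp(-r/D)`` of synaptic coupling."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    out = np.exp(-r / D)
    return out if out.ndim else float(out)


@dataclass
class CurrentsTrace:
    """Recorded AMPA/GABA currents: arrays (n_neurons, n_samples)."""

    times: np.ndarray
    i_ampa: np.ndarray
    i_gaba: np.ndarray
    neuron_ids: np.ndarray

    def to_tsv(self, path, value: str = "lfp") -> None:
        series = (
            np.abs(self.i_ampa) + np.abs(self.i_gaba)
        ).sum(axis=0) if value == "lfp" else None
        if series is None:
            raise ValueError("only the 'lfp' series is exported as TSV")
        with open(path, "w") as fh:
            fh.write("time_ms\tvalue\n")
            for t, v in zip(self.times, series):
                fh.write(f"{t:.6f}\t{v:.9g}\n")


def compute_lfp(
    trace: CurrentsTrace,
    subset: np.ndarray,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LFP(t) = sum over the subset of |I_A| + |I_G|.

    ``subset`` holds neuron ids present in the trace.  Returns (times, lfp).
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("LFP subset must be non-empty")
    pos = {int(nid): k for k, nid in enumerate(trace.neuron_ids)}
    try:
        rows = np.array([pos[int(s)] for s in subset])
    except KeyError as exc:
        raise ValueError(f"neuron {exc} not present in trace") from exc
    mask = np.ones(trace.times.size, dtype=bool)
    if window is not None:
        mask = (trace.times >= window[0]) & (trace.times < window[1])
    lfp = (
        np.abs(trace.i_ampa[rows][:, mask])
        + np.abs(trace.i_gaba[rows][:, mask])
    ).sum(axis=0)
    return trace.times[mask], lfp


@dataclass
class RunResult:
    spikes: "object"  # SpikeTrain; late import avoids a module cycle
    trace: CurrentsTrace | None
    injected_ampa: float
    injected_gaba: float


def _propagator(np_: NeuronParams, sp: SynapseParams, dt: float) -> np.ndarray:
    """Exact 6x6 step propagator for (v, I_A, x_A, I_G, x_G, const drive)."""
    A = np.zeros((6, 6))
    A[0, 0] = -1.0 / np_.tau_m
    A[0, 1] = 1.0 / np_.tau_m
    A[0, 3] = -1.0 / np_.tau_m
    A[0, 5] = 1.0 / np_.tau_m
    A[1, 1] = -1.0 / sp.tau_dA
    A[1, 2] = 1.0 / sp.tau_dA
    A[2, 2] = -1.0 / sp.tau_rA
    A[3, 3] = -1.0 / sp.tau_dG
    A[3, 4] = 1.0 / sp.tau_dG
    A[4, 4] = -1.0 / sp.tau_rG
    return expm(A * dt)


class Simulator:
    """Event-driven grid integrator over a Population and Connectivity.

    State persists across :meth:`run` calls; :meth:`reset` zeroes it.  When
    ``plasticity`` params are given, non-EXT weights are updated online and
    the mutated weights live in ``conn.weight``.
    """

    def __init__(
        self,
        pop,
        conn,
        syn: SynapseParams | None = None,
        dt: float = 0.05,
        plasticity=None,
    ) -> None:
        from .topology import AMPA, GABA, EXT  # late: topology imports us

        if dt <= 0:
            raise ValueError("dt must be positive")
        self.pop = pop
        self.conn = conn
        self.syn = syn or SynapseParams()
        self.dt = float(dt)
        self.plasticity = plasticity
        n = pop.n

        # neuron-type grouping: excitatory-like (incl. outputs) vs inhibitory
        self.tau_m = np.where(
            pop.is_excitatory, pop.exc_params.tau_m, pop.inh_params.tau_m
        )
        self.tau_rp = np.where(
            pop.is_excitatory, pop.exc_params.tau_rp, pop.inh_params.tau_rp
        )
        self.v_thr = np.where(
            pop.is_excitatory, pop.exc_params.v_thr, pop.inh_params.v_thr
        )
        self.v_res = np.where(
            pop.is_excitatory, pop.exc_params.v_res, pop.inh_params.v_res
        )
        tau_L_e, tau_L_i = pop.exc_params.tau_L, pop.inh_params.tau_L
        if tau_L_e != tau_L_i:
            raise ValueError("a single synaptic latency is assumed")
        self.delay_steps = int(np.ceil(tau_L_e / dt - 1e-12))

        # recurrent synapse tables
        rec = conn.kind != EXT
        self._rs_pre = conn.pre[rec]
        self._rs_post = conn.post[rec]
        self._rs_is_gaba = conn.kind[rec] == GABA
        self._rs_gain = self.tau_m[self._rs_post] * np.exp(
            -conn.r[rec] / self.syn.D
        )
        self._rec_index = np.nonzero(rec)[0]  # into conn.weight
        # external synapse tables (pre = channel id)
        ext = conn.kind == EXT
        ext_post = conn.post[ext]
        ext_gain = self.tau_m[ext_post] * conn.weight[ext]
        self._ext_by_channel_post: dict[int, np.ndarray] = {}
        self._ext_by_channel_gain: dict[int, np.ndarray] = {}
        for ch in np.unique(conn.pre[ext]):
            m = conn.pre[ext] == ch
            self._ext_by_channel_post[int(ch)] = ext_post[m]
            self._ext_by_channel_gain[int(ch)] = ext_gain[m]

        if plasticity is not None:
            from .plasticity import synapse_rule_arrays

            amp_ltp, amp_ltd, spatial, plastic = synapse_rule_arrays(
                conn, pop.is_excitatory, plasticity
            )
            # restrict to the recurrent block, aligned with _rs_* arrays
            self._pl_ltp = (amp_ltp * spatial)[rec]
            self._pl_ltd = (amp_ltd * spatial)[rec]
            self._tr_decay_plus = np.exp(-dt / plasticity.tau_plus)
            self._tr_decay_minus = np.exp(-dt / plasticity.tau_minus)
        else:
            self._pl_ltp = np.zeros(0)
            self._pl_ltd = np.zeros(0)
            self._tr_decay_plus = 1.0
            self._tr_decay_minus = 1.0

        # flat tables for the compiled kernel
        self._group_of = np.where(pop.is_excitatory, 0, 1).astype(np.int8)
        self._E_stack = np.stack(
            [
                _propagator(pop.exc_params, self.syn, dt),
                _propagator(pop.inh_params, self.syn, dt),
            ]
        )
        self._pre_indptr, self._pre_syn = self._csr(self._rs_pre, n)
        self._post_indptr, self._post_syn = self._csr(self._rs_post, n)

        self.reset()

    @staticmethod
    def _csr(keys: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(keys, kind="stable").astype(np.int64)
        bounds = np.searchsorted(keys[order], np.arange(n + 1)).astype(np.int64)
        return bounds, order

    # ------------------------------------------------------------------
    def reset(self) -> None:
        n = self.pop.n
        self.Y = np.zeros((5, n))  # rows: v, I_A, x_A, I_G, x_G
        self.refractory_until = np.full(n, -np.inf)
        self.t = 0.0
        L = self.delay_steps + 2
        self._ring_A = np.zeros((L, n))
        self._ring_G = np.zeros((L, n))
        self.tr_plus = np.zeros(n)
        self.tr_minus = np.zeros(n)
        self._steps_done = 0

    @property
    def v(self) -> np.ndarray:
        return self.Y[0]

    def set_v(self, v0: np.ndarray) -> None:
        self.Y[0] = np.asarray(v0, dtype=float)

    def _weights_rec(self) -> np.ndarray:
        return self.conn.weight[self._rec_index]

    # ------------------------------------------------------------------
    def run(
        self,
        duration: float,
        external=None,
        i_const=None,
        record_currents: bool = False,
        record_stride: int = 20,
        plastic: bool = True,
        forced=None,
    ) -> RunResult:
        """Advance the network by ``duration`` ms.

        ``external`` is a SpikeTrain of input-channel spike times relative to
        the start of this run; each spike is delivered after the synaptic
        latency, rounded up to the grid.  ``i_const`` adds a constant
        per-neuron drive to the membrane equation (diagnostics/tests).
        ``forced`` is a SpikeTrain of spike times imposed on neurons
        regardless of threshold (used by controlled plasticity checks).
        """
        from ._kernel import run_steps
        from .encoding import SpikeTrain

        if duration <= 0:
            raise ValueError("duration must be positive")
        dt = self.dt
        n_steps = int(np.round(duration / dt))
        n = self.pop.n
        learn = self.plasticity is not None and plastic

        if i_const is None:
            drive = np.zeros(n)
            has_drive = False
        else:
            drive = np.asarray(i_const, dtype=float)
            has_drive = True

        # pre-bin external deliveries by step
        if external is not None and external.spikes:
            steps_l = []
            posts_l = []
            gains_l = []
            tau_L = self.pop.exc_params.tau_L
            for ch, times in external.spikes.items():
                posts = self._ext_by_channel_post.get(int(ch))
                if posts is None:
                    continue
                gains = self._ext_by_channel_gain[int(ch)]
                st = np.ceil((times + tau_L) / dt - 1e-9).astype(np.int64)
                ok = (st >= 0) & (st < n_steps)
                st = st[ok]
                steps_l.append(np.repeat(st, posts.size))
                posts_l.append(np.tile(posts, st.size))
                gains_l.append(np.tile(gains, st.size))
            if steps_l:
                ext_step = np.concatenate(steps_l)
                order = np.argsort(ext_step, kind="stable")
                ext_step = ext_step[order]
                ext_post = np.concatenate(posts_l)[order]
                ext_gain = np.concatenate(gains_l)[order]
            else:
                ext_step = np.zeros(0, dtype=np.int64)
                ext_post = np.zeros(0, dtype=np.int64)
                ext_gain = np.zeros(0)
        else:
            ext_step = np.zeros(0, dtype=np.int64)
            ext_post = np.zeros(0, dtype=np.int64)
            ext_gain = np.zeros(0)
        ext_indptr = np.searchsorted(
            ext_step, np.arange(n_steps + 1)
        ).astype(np.int64)

        # pre-bin forced spikes by step (times on grid ends: step = t/dt - 1)
        if forced is not None and forced.spikes:
            fs_l = []
            fi_l = []
            for nid, times in forced.spikes.items():
                st = np.round(np.asarray(times) / dt).astype(np.int64) - 1
                ok = (st >= 0) & (st < n_steps)
                fs_l.append(st[ok])
                fi_l.append(np.full(int(ok.sum()), int(nid), dtype=np.int64))
            f_step = np.concatenate(fs_l)
            order = np.argsort(f_step, kind="stable")
            f_step = f_step[order]
            forced_ids = np.concatenate(fi_l)[order]
        else:
            f_step = np.zeros(0, dtype=np.int64)
            forced_ids = np.zeros(0, dtype=np.int64)
        forced_indptr = np.searchsorted(
            f_step, np.arange(n_steps + 1)
        ).astype(np.int64)

        rec_every = max(1, int(record_stride))
        n_rec = n_steps // rec_every + 1 if record_currents else 1
        rec_t = np.zeros(n_rec)
        rec_A = np.zeros((n if record_currents else 1, n_rec))
        rec_G = np.zeros((n if record_currents else 1, n_rec))

        t_start = self.t
        ring_start = self._steps_done % self._ring_A.shape[0]
        cap = max(10_000, n * 8, ext_step.size + f_step.size + 1024)

        # snapshot so an undersized spike buffer can be retried exactly
        snap = (
            self.Y.copy(),
            self.refractory_until.copy(),
            self._ring_A.copy(),
            self._ring_G.copy(),
            self.tr_plus.copy(),
            self.tr_minus.copy(),
            self.conn.weight.copy(),
        )
        while True:
            spike_steps = np.empty(cap, dtype=np.int64)
            spike_ids = np.empty(cap, dtype=np.int64)
            status, n_spikes, rec_k, inj_A, inj_G = run_steps(
                self.Y,
                self.refractory_until,
                self._group_of,
                self._E_stack,
                self.v_thr,
                self.v_res,
                self.tau_rp,
                drive,
                has_drive,
                self._ring_A,
                self._ring_G,
                ring_start,
                n_steps,
                dt,
                t_start,
                self.delay_steps,
                self._pre_indptr,
                self._pre_syn,
                self._rs_post,
                self._rs_gain,
                self._rs_is_gaba,
                self._rec_index,
                self.conn.weight,
                ext_indptr,
                ext_post,
                ext_gain,
                forced_indptr,
                forced_ids,
                learn,
                self._post_indptr,
                self._post_syn,
                self._rs_pre,
                self._pl_ltp,
                self._pl_ltd,
                self.plasticity.w_min if learn else 0.0,
                self.plasticity.w_max if learn else 0.0,
                self.tr_plus,
                self.tr_minus,
                self._tr_decay_plus if learn else 1.0,
                self._tr_decay_minus if learn else 1.0,
                bool(record_currents),
                rec_every,
                rec_t,
                rec_A,
                rec_G,
                spike_steps,
                spike_ids,
            )
            if status == 0:
                break
            if status == -2:
                raise FloatingPointError(
                    "non-finite network state during integration"
                )
            # spike buffer overflow: restore state and retry with more room
            (
                self.Y,
                self.refractory_until,
                self._ring_A,
                self._ring_G,
                self.tr_plus,
                self.tr_minus,
            ) = (a.copy() for a in snap[:6])
            self.conn.weight[:] = snap[6]
            cap *= 4

        if not np.all(np.isfinite(self.Y)):
            raise FloatingPointError("non-finite network state at end of run")
        self.t = t_start + n_steps * dt
        self._steps_done += n_steps

        ids = spike_ids[:n_spikes]
        times = (spike_steps[:n_spikes] + 1) * dt
        spikes: dict[int, np.ndarray] = {}
        for nid in np.unique(ids):
            spikes[int(nid)] = times[ids == nid]
        train = SpikeTrain(spikes=spikes, duration=n_steps * dt)
        trace = None
        if record_currents:
            trace = CurrentsTrace(
                times=rec_t[:rec_k],
                i_ampa=rec_A[:, :rec_k],
                i_gaba=rec_G[:, :rec_k],
                neuron_ids=np.arange(n),
            )
        return RunResult(
            spikes=train,
            trace=trace,
            injected_ampa=inj_A,
            injected_gaba=inj_G,
        )

def integrate(
    pop,
    conn,
    syn: SynapseParams | None = None,
    external=None,
    t0: float = 0.0,
    t1: float = 100.0,
    dt: float = 0.05,
    plasticity=None,
    record_currents: bool = True,
    **kwargs,
):
    """One-shot convenience wrapper: build a Simulator and run [t0, t1).

    Returns ``(simulator, spike_train, currents_trace)``; the simulator holds
    the final state and (possibly plasticity-updated) weights.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    sim = Simulator(pop, conn, syn=syn, dt=dt, plasticity=plasticity)
    sim.t = t0
    res = sim.run(
        t1 - t0,
        external=external,
        record_currents=record_currents,
        **kwargs,
    )
    return sim, res.spikes, res.trace
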