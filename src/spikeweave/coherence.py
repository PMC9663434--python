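"""Phase synchrony and the coherence-based intertwined-pattern recognizer.

Each neuron's spike train defines an instantaneous phase: at reference time t
inside the inter-spike interval ``[t_k, t_k+1)`` the phase is
``(t - t_k) / (t_k+1 - t_k)`` in ``[0, 1)``.  A population phase vector is
summarised by the order parameter ``R = |mean exp(2*pi*i*phase)|``: R = 1 for
complete synchrony, R = 0 for uniformly spread phases, and identically
``R^2 = 1 - var(z)`` with ``z = exp(2*pi*i*phase)``.

Following the communication-through-coherence idea, a hub network (untrained,
same architecture) is driven by the combined "informative signal" of a
superimposed input; its local field potential is re-encoded as a Poisson rate
that drives every trained platform network.  Per platform, R is computed over
a fixed set of shared neuron indices pooled across hub and platform; a
platform whose R exceeds the decision threshold (0.8) is declared a member,
and its class readout (maximum output-neuron rate) names the component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import compute_lfp
from .encoding import EncodedSignal, SpikeTrain, poisson_spikes, signal_to_rate

__all__ = [
    "PhaseVector",
    "SyncResult",
    "IntertwinedSystem",
    "IntertwinedDecision",
    "spike_phases",
    "sync_measure",
    "windowed_sync",
    "recognize_intertwined",
    "count_combinations",
]


@dataclass
class PhaseVector:
    """Per-neuron phase samples at reference times; NaN where undefined
    (a neuron needs an inter-spike interval bracketing the reference time)."""

    phases: np.ndarray  # (n_neurons, n_ref) in [0, 1) or NaN
    ref_times: np.ndarray
    neuron_ids: np.ndarray


@dataclass
class SyncResult:
    """Order parameter over a phase set; ``n`` is the sample count used."""

    R: float
    n: int
    window: tuple[float, float] | None = None


def spike_phases(
    train: SpikeTrain, ref_times: np.ndarray, neuron_ids=None
) -> PhaseVector:
    """Fractional inter-spike-interval phases at the reference times."""
    if not train.spikes:
        raise ValueError("cannot compute phases of an empty spike train")
    ref = np.atleast_1d(np.asarray(ref_times, dtype=float))
    ids = (
        np.asarray(sorted(train.spikes), dtype=int)
        if neuron_ids is None
        else np.asarray(neuron_ids, dtype=int)
    )
    phases = np.full((ids.size, ref.size), np.nan)
    for row, nid in enumerate(ids):
        t = train.spikes.get(int(nid))
        if t is None or t.size < 2:
            continue
        k = np.searchsorted(t, ref, side="right") - 1
        ok = (k >= 0) & (k < t.size - 1)
        kk = np.clip(k, 0, t.size - 2)
        ph = (ref - t[kk]) / (t[kk + 1] - t[kk])
        phases[row, ok] = ph[ok]
    return PhaseVector(phases=phases, ref_times=ref, neuron_ids=ids)


def sync_measure(phases: np.ndarray) -> SyncResult:
    """Order parameter of a single 1-D phase vector (NaNs ignored)."""
    ph = np.asarray(phases, dtype=float).ravel()
    ph = ph[np.isfinite(ph)]
    if ph.size < 2:
        raise ValueError("need at least two phase samples")
    z = np.exp(2j * np.pi * ph)
    return SyncResult(R=float(np.abs(z.mean())), n=int(ph.size))


def windowed_sync(
    pv: PhaseVector, window: tuple[float, float] | None = None
) -> SyncResult:
    """Per-reference-time order parameters averaged over the window.

    Reference times with fewer than two defined phases are skipped.
    """
    mask = np.ones(pv.ref_times.size, dtype=bool)
    if window is not None:
        mask = (pv.ref_times >= window[0]) & (pv.ref_times < window[1])
    rs = []
    ns = []
    for col in np.nonzero(mask)[0]:
        ph = pv.phases[:, col]
        ph = ph[np.isfinite(ph)]
        if ph.size >= 2:
            rs.append(np.abs(np.exp(2j * np.pi * ph).mean()))
            ns.append(ph.size)
    if not rs:
        return SyncResult(R=0.0, n=0, window=window)
    return SyncResult(R=float(np.mean(rs)), n=int(np.mean(ns)), window=window)


def pooled_sync(
    pvs: list[PhaseVector], window: tuple[float, float] | None = None
) -> SyncResult:
    """Order parameter over phases pooled across populations per ref time."""
    stacked = PhaseVector(
        phases=np.vstack([p.phases for p in pvs]),
        ref_times=pvs[0].ref_times,
        neuron_ids=np.concatenate([p.neuron_ids for p in pvs]),
    )
    return windowed_sync(stacked, window=window)


def count_combinations(set_sizes: list[int]) -> int:
    """Number of intertwined patterns from one pick per source set."""
    if not set_sizes or any(s < 1 for s in set_sizes):
        raise ValueError("set sizes must be positive integers")
    out = 1
    for s in set_sizes:
        out *= int(s)
    return out


@dataclass
class IntertwinedSystem:
    """A hub (untrained) network plus trained platform models.

    ``shared_ids`` is one fixed index set of layer neurons, used on both the
    hub and every platform when pooling phases (all networks share the same
    layer size).  ``lfp_gain`` converts the hub LFP into the platform drive
    rate: ``rate = lfp_gain * LFP / n_hub`` (spikes/s).
    """

    hub_pop: object
    hub_conn: object
    platforms: list  # TrainedModel
    shared_ids: np.ndarray
    threshold: float = 0.8
    lfp_gain: float = 1.0
    ref_dt: float = 5.0
    transient_ms: float = 100.0
    syn: object = None
    dt: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        self.shared_ids = np.asarray(self.shared_ids, dtype=int)


@dataclass
class IntertwinedDecision:
    """Per-platform synchrony and the decoded member components."""

    R: dict[int, float]
    members: list[int]
    classes: dict[int, object]
    hub_rate_mean: float = 0.0
    meta: dict = field(default_factory=dict)


def recognize_intertwined(
    system: IntertwinedSystem,
    signal: EncodedSignal,
    duration: float,
    seed: int,
    coding=None,
) -> IntertwinedDecision:
    """Decompose a (possibly superimposed) signal into source components.

    Drives the hub with Poisson spikes of the signal, re-encodes the hub LFP
    as a Poisson rate into each platform, computes the pooled order parameter
    over the shared neurons for each (hub, platform) pair, thresholds it for
    membership, and decodes each member's class by maximum output rate.
    """
    from .dynamics import Simulator
    from .encoding import CodingParams
    from .training import presentation_rates

    coding = coding or CodingParams()
    rng_seed = np.random.default_rng(seed)
    for m in system.platforms:
        if m.class_of_output is None:
            raise ValueError("all platforms must be trained and labeled")

    # 1) hub driven by the raw signal
    _, rates = signal_to_rate(signal, 0.0, duration, coding)
    ext = poisson_spikes(
        rates,
        coding.dt,
        system.hub_pop.n_grid,
        seed=int(rng_seed.integers(2**31)),
    )
    hub_sim = Simulator(
        system.hub_pop, system.hub_conn, syn=system.syn, dt=system.dt
    )
    hub_res = hub_sim.run(
        duration,
        external=ext,
        record_currents=True,
        record_stride=max(1, int(round(coding.dt / system.dt))),
    )

    # 2) hub LFP -> platform drive rate (whole-population readout)
    lfp_t, lfp = compute_lfp(
        hub_res.trace, np.arange(system.hub_pop.n_grid)
    )
    drive_rate = system.lfp_gain * lfp / system.hub_pop.n_grid

    window = (system.transient_ms, duration)
    ref_times = np.arange(window[0], window[1], system.ref_dt)
    if not hub_res.spikes.spikes:
        # silent hub: nothing to synchronize with
        return IntertwinedDecision(
            R={k: 0.0 for k in range(len(system.platforms))},
            members=[],
            classes={},
            hub_rate_mean=float(drive_rate.mean()),
            meta={"duration": duration, "seed": seed},
        )
    hub_pv = spike_phases(
        hub_res.spikes, ref_times, neuron_ids=system.shared_ids
    )

    # 3) drive each platform and measure pooled coherence
    R: dict[int, float] = {}
    members: list[int] = []
    classes: dict[int, object] = {}
    for k, model in enumerate(system.platforms):
        pext = poisson_spikes(
            drive_rate,
            coding.dt,
            model.pop.n_grid,
            seed=int(rng_seed.integers(2**31)),
        )
        sim = Simulator(model.pop, model.conn, syn=model.syn, dt=system.dt)
        res = sim.run(duration, external=pext, plastic=False)
        if not res.spikes.spikes:
            R[k] = 0.0  # silent platform: no coherent interaction
            continue
        plat_pv = spike_phases(
            res.spikes, ref_times, neuron_ids=system.shared_ids
        )
        sync = pooled_sync([hub_pv, plat_pv], window=window)
        R[k] = sync.R
        if sync.R > system.threshold:
            members.append(k)
            out_rates = presentation_rates(
                res.spikes, model.pop, window=window
            )
            best = int(np.argmax(out_rates))
            classes[k] = model.class_of_output[best]
    return IntertwinedDecision(
        R=R,
        members=members,
        classes=classes,
        hub_rate_mean=float(drive_rate.mean()),
        meta={"duration": duration, "seed": seed},
    )
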