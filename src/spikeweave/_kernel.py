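"""Compiled inner loop of the network integrator.

The Python-level :class:`~spikeweave.dynamics.Simulator` assembles flat
arrays (state, propagators, CSR synapse tables, pre-binned external events)
and hands them to :func:`run_steps`, which advances the network step by step:
deliver queued impulses, propagate the linear subsystem with the per-type
exact propagator, clamp refractory membranes, detect threshold crossings,
apply online spatial-STDP updates, and enqueue outgoing deliveries.

Semantics are defined entirely by the caller; this module is pure mechanism.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_steps(
    Y,                 # (5, n) state: v, I_A, x_A, I_G, x_G
    refractory_until,  # (n,)
    group_of,          # (n,) int8 index into E
    E,                 # (n_groups, 6, 6) propagators
    v_thr, v_res, tau_rp,   # (n,)
    drive,             # (n,) constant membrane drive
    has_drive,         # bool
    ring_A, ring_G,    # (L, n) delivery queues
    ring_start,        # int: slot of step 0
    n_steps, dt, t_start, delay_steps,
    # recurrent synapses (CSR by presynaptic neuron)
    pre_indptr, pre_syn,     # synapse ids sorted by pre
    rs_post, rs_gain, rs_is_gaba, rs_weight_idx,
    weights,           # full weight array (mutated by plasticity)
    # external events pre-binned by step
    ext_indptr, ext_post, ext_gain,
    # forced spikes pre-binned by step
    forced_indptr, forced_ids,
    # plasticity tables (empty arrays when disabled)
    learn,
    post_indptr, post_syn,
    rs_pre,
    pl_ltp, pl_ltd, w_min, w_max,
    tr_plus, tr_minus, decay_plus, decay_minus,
    # recording
    record, rec_every, rec_t, rec_A, rec_G,
    # outputs
    spike_steps, spike_ids,
):
    n = Y.shape[1]
    L = ring_A.shape[0]
    n_spikes = 0
    rec_k = 0
    injected_A = 0.0
    injected_G = 0.0
    cap = spike_steps.shape[0]

    for s in range(n_steps):
        slot = (ring_start + s) % L
        for i in range(n):
            Y[2, i] += ring_A[slot, i]
            Y[4, i] += ring_G[slot, i]
            ring_A[slot, i] = 0.0
            ring_G[slot, i] = 0.0
        for e in range(ext_indptr[s], ext_indptr[s + 1]):
            Y[2, ext_post[e]] += ext_gain[e]
            injected_A += ext_gain[e]

        if record and s % rec_every == 0:
            rec_t[rec_k] = t_start + s * dt
            for i in range(n):
                rec_A[i, rec_k] = Y[1, i]
                rec_G[i, rec_k] = Y[3, i]
            rec_k += 1

        # exact propagation, per neuron through its group matrix
        for i in range(n):
            g = group_of[i]
            y0 = Y[0, i]
            y1 = Y[1, i]
            y2 = Y[2, i]
            y3 = Y[3, i]
            y4 = Y[4, i]
            d = drive[i] if has_drive else 0.0
            Y[0, i] = (
                E[g, 0, 0] * y0 + E[g, 0, 1] * y1 + E[g, 0, 2] * y2
                + E[g, 0, 3] * y3 + E[g, 0, 4] * y4 + E[g, 0, 5] * d
            )
            Y[1, i] = E[g, 1, 1] * y1 + E[g, 1, 2] * y2
            Y[2, i] = E[g, 2, 2] * y2
            Y[3, i] = E[g, 3, 3] * y3 + E[g, 3, 4] * y4
            Y[4, i] = E[g, 4, 4] * y4

        t_new = t_start + (s + 1) * dt

        # advance the STDP traces to t_new before any update reads them
        if learn:
            for i in range(n):
                tr_plus[i] *= decay_plus
                tr_minus[i] *= decay_minus

        # threshold / refractory / forced spikes
        n_new = 0
        for i in range(n):
            if t_new < refractory_until[i] - 1e-9:
                Y[0, i] = v_res[i]
            elif Y[0, i] >= v_thr[i]:
                if n_spikes + n_new >= cap:
                    return -1, n_spikes, rec_k, injected_A, injected_G
                spike_ids[n_spikes + n_new] = i
                spike_steps[n_spikes + n_new] = s
                n_new += 1
        for e in range(forced_indptr[s], forced_indptr[s + 1]):
            i = forced_ids[e]
            dup = False
            for k in range(n_spikes, n_spikes + n_new):
                if spike_ids[k] == i:
                    dup = True
                    break
            if not dup:
                if n_spikes + n_new >= cap:
                    return -1, n_spikes, rec_k, injected_A, injected_G
                spike_ids[n_spikes + n_new] = i
                spike_steps[n_spikes + n_new] = s
                n_new += 1

        if n_new > 0:
            tgt = (ring_start + s + 1 + delay_steps) % L
            for k in range(n_spikes, n_spikes + n_new):
                i = spike_ids[k]
                Y[0, i] = v_res[i]
                refractory_until[i] = t_new + tau_rp[i]

            if learn:
                # LTP on incoming synapses of each spiking neuron
                for k in range(n_spikes, n_spikes + n_new):
                    i = spike_ids[k]
                    for q in range(post_indptr[i], post_indptr[i + 1]):
                        sy = post_syn[q]
                        wi = rs_weight_idx[sy]
                        w = weights[wi] + pl_ltp[sy] * tr_plus[rs_pre[sy]]
                        if w < w_min:
                            w = w_min
                        elif w > w_max:
                            w = w_max
                        weights[wi] = w
                # LTD on outgoing synapses
                for k in range(n_spikes, n_spikes + n_new):
                    i = spike_ids[k]
                    for q in range(pre_indptr[i], pre_indptr[i + 1]):
                        sy = pre_syn[q]
                        wi = rs_weight_idx[sy]
                        w = weights[wi] + pl_ltd[sy] * tr_minus[rs_post[sy]]
                        if w < w_min:
                            w = w_min
                        elif w > w_max:
                            w = w_max
                        weights[wi] = w

            # enqueue deliveries with the (possibly just-updated) weights
            for k in range(n_spikes, n_spikes + n_new):
                i = spike_ids[k]
                for q in range(pre_indptr[i], pre_indptr[i + 1]):
                    sy = pre_syn[q]
                    c = rs_gain[sy] * weights[rs_weight_idx[sy]]
                    if rs_is_gaba[sy]:
                        ring_G[tgt, rs_post[sy]] += c
                        injected_G += c
                    else:
                        ring_A[tgt, rs_post[sy]] += c
                        injected_A += c
            n_spikes += n_new

        if learn and n_new > 0:
            for k in range(n_spikes - n_new, n_spikes):
                tr_plus[spike_ids[k]] += 1.0
                tr_minus[spike_ids[k]] += 1.0

        if s % 2000 == 1999:
            ok = True
            for i in range(n):
                if not (
                    np.isfinite(Y[0, i])
                    and np.isfinite(Y[2, i])
                    and np.isfinite(Y[4, i])
                ):
                    ok = False
                    break
            if not ok:
                return -2, n_spikes, rec_k, injected_A, injected_G

    return 0, n_spikes, rec_k, injected_A, injected_G
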