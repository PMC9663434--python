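"""Spatial spike-timing-dependent plasticity.

The pair-based STDP window is multiplied by a spatial factor ``exp(r/Ds)``
that *amplifies* updates for distant neuron pairs (deliberately opposite to
the ``exp(-r/D)`` coupling attenuation: distant pairs couple weakly but learn
fast).  Four cell-type-specific rules apply, all with the same exponential
time course (time constants 10 ms):

1. pyramidal -> pyramidal: post-after-pre increases the AMPA weight by
   ``exp(r/Ds) * 0.06 * exp(-x/tau+)``;
2. interneuron -> pyramidal: post-after-pre *decreases* the GABA weight by
   ``exp(r/Ds) * 0.05 * exp(-x/tau+)`` (less inhibition = potentiation);
3. pyramidal -> interneuron: as rule 1 scaled by 0.4;
4. interneuron -> interneuron: as rule 2 scaled by 0.4.

Pre-before-post reverses the sign of every rule (LTD mirror).  Weights are
stored as nonnegative magnitudes and clipped to ``[w_min, w_max]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import SpikeTrain

RULES = ("pyr->pyr", "int->pyr", "pyr->int", "int->int")

__all__ = [
    "PlasticityParams",
    "RULES",
    "stdp_window",
    "accumulate_pair_updates",
    "apply_deltas",
    "synapse_rule_arrays",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Amplitudes, time constants and spatial scale of spatial STDP.

    ``a_plus`` (0.06) and ``g_amp`` (0.05) are the pyramidal-source and
    interneuron-source amplitudes at zero lag and unit spatial factor;
    ``int_scale`` (0.4) scales the interneuron-target rules.  The LTD
    amplitudes ``a_minus``/``g_minus`` default to their LTP counterparts
    (symmetric window); stable learning usually wants them larger.  ``ds`` is the spatial scale of
    the learning kernel; weights are clipped to ``[w_min, w_max]``.
    """

    a_plus: float = 0.06
    a_minus: float = 0.06
    g_amp: float = 0.05
    g_minus: float = 0.05
    int_scale: float = 0.4
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    ds: float = 10.0
    w_min: float = 0.0
    w_max: float = 5.0
    pairing_scheme: str = "all_pairs"  # "all_pairs" | "nearest"

    def __post_init__(self) -> None:
        for name in ("a_plus", "a_minus", "g_amp", "g_minus", "int_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (self.tau_plus > 0 and self.tau_minus > 0 and self.ds > 0):
            raise ValueError("tau_plus, tau_minus and ds must be positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")
        if self.pairing_scheme not in ("all_pairs", "nearest"):
            raise ValueError("pairing_scheme must be 'all_pairs' or 'nearest'")

    def null(self) -> "PlasticityParams":
        """A copy with all amplitudes zeroed (learning disabled)."""
        return PlasticityParams(
            a_plus=0.0, a_minus=0.0, g_amp=0.0, g_minus=0.0,
            int_scale=self.int_scale, tau_plus=self.tau_plus,
            tau_minus=self.tau_minus, ds=self.ds,
            w_min=self.w_min, w_max=self.w_max,
            pairing_scheme=self.pairing_scheme,
        )


def _rule_amplitudes(params: PlasticityParams, rule: str) -> tuple[float, float]:
    """Signed (LTP, LTD) amplitudes of the weight-magnitude change."""
    if rule == "pyr->pyr":
        return params.a_plus, -params.a_minus
    if rule == "int->pyr":
        return -params.g_amp, params.g_minus
    if rule == "pyr->int":
        return params.a_plus * params.int_scale, -params.a_minus * params.int_scale
    if rule == "int->int":
        return -params.g_amp * params.int_scale, params.g_minus * params.int_scale
    raise ValueError(f"unknown plasticity rule {rule!r}; expected one of {RULES}")


def stdp_window(x, r, params: PlasticityParams, rule: str):
    """Signed weight change for a single pre/post pair at lag ``x`` (ms).

    ``x = t_post - t_pre``; ``r`` is the pre/post grid distance.  Positive lag
    follows the LTP branch of the rule, negative lag the mirrored LTD branch;
    a pair at exactly zero lag contributes nothing (tie convention that makes
    online and batch accumulation agree).
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("lag must be finite")
    if np.any(np.asarray(r) < 0):
        raise ValueError("distance must be nonnegative")
    amp_ltp, amp_ltd = _rule_amplitudes(params, rule)
    spatial = np.exp(np.asarray(r, dtype=float) / params.ds)
    out = np.where(
        x > 0,
        amp_ltp * np.exp(-x / params.tau_plus),
        amp_ltd * np.exp(np.minimum(x, 0.0) / params.tau_minus),
    ) * spatial
    out = np.where(x == 0, 0.0, out)
    return out if out.ndim else float(out)


def synapse_rule_arrays(conn, is_excitatory: np.ndarray, params: PlasticityParams):
    """Per-synapse signed LTP/LTD amplitudes and spatial gains.

    Output (classifying) neurons count as pyramidal targets.  EXT synapses
    (the input weights) are frozen and excluded via the returned mask.
    """
    from .topology import EXT  # local import to avoid a cycle

    plastic = conn.kind != EXT
    pre_exc = is_excitatory[np.clip(conn.pre, 0, is_excitatory.size - 1)]
    post_exc = is_excitatory[conn.post]
    amp_ltp = np.zeros(conn.n_synapses)
    amp_ltd = np.zeros(conn.n_synapses)
    for rule, mask in (
        ("pyr->pyr", pre_exc & post_exc),
        ("int->pyr", ~pre_exc & post_exc),
        ("pyr->int", pre_exc & ~post_exc),
        ("int->int", ~pre_exc & ~post_exc),
    ):
        ltp, ltd = _rule_amplitudes(params, rule)
        amp_ltp[mask] = ltp
        amp_ltd[mask] = ltd
    amp_ltp[~plastic] = 0.0
    amp_ltd[~plastic] = 0.0
    spatial = np.exp(conn.r / params.ds)
    return amp_ltp, amp_ltd, spatial, plastic


def accumulate_pair_updates(
    spikes: SpikeTrain,
    conn,
    is_excitatory: np.ndarray,
    params: PlasticityParams,
) -> np.ndarray:
    """Batch double sum of the window over all pre/post spike pairs.

    Returns the per-synapse weight delta (before clipping).  With the
    ``nearest`` pairing scheme only each post spike's nearest earlier pre
    spike (and each pre spike's nearest earlier post spike) contribute.
    """
    amp_ltp, amp_ltd, spatial, plastic = synapse_rule_arrays(
        conn, is_excitatory, params
    )
    deltas = np.zeros(conn.n_synapses)
    for s in np.nonzero(plastic)[0]:
        t_pre = spikes.spikes.get(int(conn.pre[s]))
        t_post = spikes.spikes.get(int(conn.post[s]))
        if t_pre is None or t_post is None:
            continue
        lags = t_post[:, None] - t_pre[None, :]  # post - pre
        pos = lags > 0
        neg = lags < 0
        if params.pairing_scheme == "nearest":
            pos &= lags == np.where(pos, lags, np.inf).min(
                axis=1, keepdims=True
            )
            neg &= lags == np.where(neg, lags, -np.inf).max(
                axis=0, keepdims=True
            )
        d = amp_ltp[s] * np.exp(-lags[pos] / params.tau_plus).sum()
        d += amp_ltd[s] * np.exp(lags[neg] / params.tau_minus).sum()
        deltas[s] = d * spatial[s]
    return deltas


def apply_deltas(conn, deltas: np.ndarray, params: PlasticityParams) -> None:
    """Apply accumulated deltas to the stored weights, clipped in place."""
    np.clip(conn.weight + deltas, params.w_min, params.w_max, out=conn.weight)
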