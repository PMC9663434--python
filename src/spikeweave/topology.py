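"""Spatially embedded E/I populations and sparse synaptic wiring.

The recognition layer is a rectangular grid of LIF neurons, 80% excitatory
(pyramidal) and 20% inhibitory (interneurons), wired by independent Bernoulli
draws at connection probability 0.2 per directed non-self pair.  Synaptic
efficacy falls off with Euclidean grid distance as ``exp(-r/D)`` inside the
dynamics; the wiring stores the raw distance.  Classifying output neurons sit
off the grid and receive full connections from every layer neuron.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import NeuronParams

AMPA, GABA, EXT = 0, 1, 2
KIND_NAMES = {AMPA: "AMPA", GABA: "GABA", EXT: "EXT"}

__all__ = [
    "AMPA",
    "GABA",
    "EXT",
    "Population",
    "Connectivity",
    "build_population",
    "build_connectivity",
    "wire_external",
    "wire_output_layer",
    "grid_distance",
]


@dataclass
class Population:
    """Neurons with grid positions and E/I type labels.

    Indices ``[0, n_grid)`` are layer neurons with (row, col) positions;
    indices ``[n_grid, n)`` are off-grid output (classifying) neurons, which
    use excitatory membrane parameters.
    """

    is_excitatory: np.ndarray  # bool, (n,); output neurons count as excitatory
    positions: np.ndarray  # float, (n, 2); NaN rows for off-grid neurons
    grid: tuple[int, int]
    n_grid: int
    exc_params: NeuronParams = field(default_factory=NeuronParams.excitatory)
    inh_params: NeuronParams = field(default_factory=NeuronParams.inhibitory)

    @property
    def n(self) -> int:
        return self.is_excitatory.size

    @property
    def n_outputs(self) -> int:
        return self.n - self.n_grid

    @property
    def n_excitatory(self) -> int:
        return int(self.is_excitatory[: self.n_grid].sum())

    @property
    def n_inhibitory(self) -> int:
        return self.n_grid - self.n_excitatory

    def with_outputs(self, n_outputs: int) -> "Population":
        """Append off-grid output neurons (excitatory parameters)."""
        exc = np.concatenate(
            [self.is_excitatory, np.ones(n_outputs, dtype=bool)]
        )
        pos = np.vstack(
            [self.positions, np.full((n_outputs, 2), np.nan)]
        )
        return replace(self, is_excitatory=exc, positions=pos)


@dataclass
class Connectivity:
    """Directed synapses as parallel columnar arrays.

    ``kind`` is AMPA (0) for excitatory presynaptic neurons, GABA (1) for
    inhibitory ones, and EXT (2) for the external Poisson drive (for EXT the
    ``pre`` index names the input channel).  ``weight`` is a nonnegative
    magnitude — the sign of the synaptic effect is carried by the kind.
    ``r`` is the Euclidean grid distance between pre and post.
    """

    pre: np.ndarray
    post: np.ndarray
    kind: np.ndarray
    weight: np.ndarray
    r: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.kind = np.asarray(self.kind, dtype=np.int8)
        self.weight = np.asarray(self.weight, dtype=float)
        self.r = np.asarray(self.r, dtype=float)

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    def counts_per_kind(self) -> dict[str, int]:
        return {
            name: int((self.kind == code).sum())
            for code, name in KIND_NAMES.items()
        }

    def extend(self, other: "Connectivity") -> "Connectivity":
        return Connectivity(
            pre=np.concatenate([self.pre, other.pre]),
            post=np.concatenate([self.post, other.post]),
            kind=np.concatenate([self.kind, other.kind]),
            weight=np.concatenate([self.weight, other.weight]),
            r=np.concatenate([self.r, other.r]),
            meta={**self.meta, **other.meta},
        )

    def digest(self) -> str:
        h = hashlib.sha256()
        for a in (self.pre, self.post, self.kind, self.weight, self.r):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()

    # --- columnar container round trip --------------------------------
    def save(self, path) -> None:
        np.savez_compressed(
            path,
            pre=self.pre,
            post=self.post,
            kind=self.kind,
            weight=self.weight,
            r=self.r,
            meta=np.frombuffer(
                json.dumps(self.meta).encode(), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path) -> "Connectivity":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode()) if "meta" in z else {}
            return cls(
                pre=z["pre"],
                post=z["post"],
                kind=z["kind"],
                weight=z["weight"],
                r=z["r"],
                meta=meta,
            )


def grid_distance(a, b) -> float:
    """Euclidean distance between two (row, col) grid positions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.hypot(*(a - b)))


def build_population(
    n: int = 5000,
    frac_exc: float = 0.8,
    grid: tuple[int, int] = (100, 50),
    seed: int | None = None,
    exc_params: NeuronParams | None = None,
    inh_params: NeuronParams | None = None,
) -> Population:
    """Place ``n`` neurons on a rectangular grid with an exact E/I split.

    ``round(n * frac_exc)`` neurons are excitatory.  Placement is row-major
    over the first ``n`` grid cells and the E/I labels are interleaved
    (every fifth neuron inhibitory at the default 80/20 split), so the layout
    is deterministic; ``seed`` is accepted for interface symmetry.
    """
    rows, cols = grid
    if n > rows * cols:
        raise ValueError(f"population of {n} exceeds grid capacity {rows * cols}")
    if not 0.0 <= frac_exc <= 1.0:
        raise ValueError("frac_exc must be within [0, 1]")
    n_exc = int(round(n * frac_exc))
    cells = np.arange(n)
    positions = np.column_stack([cells // cols, cells % cols]).astype(float)
    is_exc = np.ones(n, dtype=bool)
    n_inh = n - n_exc
    if n_inh > 0:
        # spread inhibitory labels evenly through the row-major order
        inh_idx = np.floor(
            (np.arange(n_inh) + 0.5) * n / n_inh
        ).astype(int)
        inh_idx = np.clip(inh_idx, 0, n - 1)
        # guard against collisions from rounding at tiny n
        inh_idx = np.unique(inh_idx)
        extra = np.setdiff1d(np.arange(n), inh_idx)
        inh_idx = np.concatenate([inh_idx, extra[: n_inh - inh_idx.size]])
        is_exc[inh_idx] = False
    return Population(
        is_excitatory=is_exc,
        positions=positions,
        grid=grid,
        n_grid=n,
        exc_params=exc_params or NeuronParams.excitatory(),
        inh_params=inh_params or NeuronParams.inhibitory(),
    )


def _truncated_gaussian_weights(rng, size: int, sd: float) -> np.ndarray:
    """Gaussian(0, sd) draws stored as magnitudes, negatives truncated to 0.

    The synapse kind carries the sign of the effect, so weights are
    nonnegative magnitudes.
    """
    return np.maximum(rng.normal(0.0, sd, size), 0.0)


def build_connectivity(
    pop: Population,
    p: float = 0.2,
    weight_sd: float = 0.2,
    seed: int = 0,
) -> Connectivity:
    """Bernoulli(p) wiring over ordered non-self pairs of layer neurons.

    Initial weights are Gaussian(0, ``weight_sd``) magnitudes (negative draws
    truncated at zero); ``kind`` follows the presynaptic type (Dale's rule).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("connection probability must be in (0, 1]")
    n = pop.n_grid
    rng = np.random.default_rng(seed)
    pres: list[np.ndarray] = []
    posts: list[np.ndarray] = []
    for i in range(n):
        mask = rng.random(n) < p
        mask[i] = False
        tgt = np.nonzero(mask)[0]
        if tgt.size:
            pres.append(np.full(tgt.size, i, dtype=np.int64))
            posts.append(tgt.astype(np.int64))
    pre = np.concatenate(pres) if pres else np.empty(0, dtype=np.int64)
    post = np.concatenate(posts) if posts else np.empty(0, dtype=np.int64)
    kind = np.where(pop.is_excitatory[pre], AMPA, GABA).astype(np.int8)
    d = pop.positions[pre] - pop.positions[post]
    r = np.hypot(d[:, 0], d[:, 1])
    weight = _truncated_gaussian_weights(rng, pre.size, weight_sd)
    return Connectivity(
        pre=pre,
        post=post,
        kind=kind,
        weight=weight,
        r=r,
        meta={"n": n, "p": p, "grid": list(pop.grid), "seed": seed},
    )


def wire_external(pop: Population, j_ext: float = 5.0) -> Connectivity:
    """One untrained external Poisson channel per layer neuron (r = 0)."""
    n = pop.n_grid
    idx = np.arange(n, dtype=np.int64)
    return Connectivity(
        pre=idx,
        post=idx,
        kind=np.full(n, EXT, dtype=np.int8),
        weight=np.full(n, float(j_ext)),
        r=np.zeros(n),
        meta={"j_ext": j_ext},
    )


def wire_output_layer(
    pop: Population,
    n_classes: int,
    weight_sd: float = 0.2,
    gaba_weight_sd: float | None = None,
    balance: float | None = None,
    seed: int = 0,
) -> tuple[Population, Connectivity]:
    """Fully connect every layer neuron to ``n_classes`` output neurons.

    Output neurons have no grid position; output synapses use r = 0 (no
    distance attenuation).  AMPA from pyramidal neurons, GABA from
    interneurons, initial Gaussian-magnitude weights as in the layer wiring.

    ``gaba_weight_sd`` sets the interneuron-pathway scale separately; with
    the 80/20 E/I split, a larger inhibitory scale balances the mean
    excitatory and inhibitory charge at each output neuron so the readout
    responds to population activity *contrasts* rather than to the common
    drive level (default: same as ``weight_sd``).
    """
    if n_classes < 2:
        raise ValueError("need at least two output classes")
    pop2 = pop.with_outputs(n_classes)
    n = pop.n_grid
    rng = np.random.default_rng(seed)
    pre = np.tile(np.arange(n, dtype=np.int64), n_classes)
    post = np.repeat(np.arange(n, n + n_classes, dtype=np.int64), n)
    kind = np.where(pop.is_excitatory[pre], AMPA, GABA).astype(np.int8)
    weight = _truncated_gaussian_weights(rng, pre.size, weight_sd)
    if gaba_weight_sd is not None:
        gaba = kind == GABA
        weight[gaba] = _truncated_gaussian_weights(
            rng, int(gaba.sum()), gaba_weight_sd
        )
    if balance is not None:
        # Per-output synaptic scaling: scale the inhibitory weights so the
        # summed inhibitory charge matches the summed excitatory charge and
        # each classifying neuron reads activity *contrasts* rather than the
        # common population drive.  ``balance`` is the relative charge of one
        # inhibitory spike (rise-time ratio tau_rG/tau_rA times the typical
        # interneuron/pyramidal rate ratio of the layer).
        for o in range(n_classes):
            rows = slice(o * n, (o + 1) * n)
            w = weight[rows]
            k = kind[rows]
            exc_sum = w[k == AMPA].sum()
            inh_sum = w[k == GABA].sum() * balance
            if inh_sum > 0:
                w[k == GABA] *= exc_sum / inh_sum
            weight[rows] = w
    conn = Connectivity(
        pre=pre,
        post=post,
        kind=kind,
        weight=weight,
        r=np.zeros(pre.size),
        meta={"n_classes": n_classes},
    )
    return pop2, conn
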