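"""Sinusoidal image encoding and inhomogeneous Poisson spike generation.

An image is mapped to a single scalar "informative signal": one sinusoid per
pixel, with the column index setting the frequency (``j * f_max / M``), the row
index setting the phase (``i * 360 / N`` degrees, indices 1-based so the
extremes ``f_max`` and 360 degrees are attained), and the amplitude equal to
pixel brightness plus a nonnegative constant that preserves black-pixel
information.  Signals from several images add component-wise, which is what
makes superimposed ("intertwined") patterns linearly decomposable in frequency
space when the source images have different column counts.

The scalar signal drives the network as the time-varying rate of independent
Poisson spike trains, one channel per target neuron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CodingParams",
    "EncodedSignal",
    "SpikeTrain",
    "encode_image",
    "evaluate_signal",
    "combine_signals",
    "signal_to_rate",
    "poisson_spikes",
    "recover_quadrature",
]


@dataclass(frozen=True)
class CodingParams:
    """Parameters of the image -> signal -> spike-rate pipeline.

    Parameters
    ----------
    f_max
        Maximal sinusoid frequency in Hz; the column lattice is
        ``j * f_max / M`` for ``j = 1..M``.
    brightness_constant
        Nonnegative offset added to every pixel brightness so that black
        pixels still contribute a sinusoid.
    dt
        Sample step of the rate series, in ms.
    rate_scale
        Spikes/s of external drive per unit of (rectified) signal amplitude.
        The amplitude-to-rate gain is not a property of the encoding itself
        and is exposed as plain plumbing.
    """

    f_max: float = 100.0
    brightness_constant: float = 1.0
    dt: float = 1.0
    rate_scale: float = 1.0
    rectify: str = "relu"  # "relu" | "abs"

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise ValueError("f_max must be positive")
        if self.brightness_constant < 0:
            raise ValueError("brightness_constant must be nonnegative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.rate_scale > 0:
            raise ValueError("rate_scale must be positive")
        if self.rectify not in ("relu", "abs"):
            raise ValueError("rectify must be 'relu' or 'abs'")


@dataclass
class EncodedSignal:
    """A set of sinusoidal components ``a * sin(2*pi*F*t + phi)``.

    ``amplitudes`` are in brightness units, ``frequencies`` in Hz and
    ``phases`` in degrees.  ``source_shape`` records the (rows, cols) of the
    originating image; for combined signals it is the list of all source
    shapes.
    """

    amplitudes: np.ndarray
    frequencies: np.ndarray
    phases: np.ndarray
    source_shape: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if not (
            self.amplitudes.shape == self.frequencies.shape == self.phases.shape
        ):
            raise ValueError("component arrays must share one shape")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def n_components(self) -> int:
        return self.amplitudes.size

    def evaluate(self, times_ms: np.ndarray) -> np.ndarray:
        """Evaluate the scalar signal on a grid of times (ms)."""
        return evaluate_signal(self, times_ms)

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "components": [
                    [float(a), float(f), float(p)]
                    for a, f, p in zip(
                        self.amplitudes, self.frequencies, self.phases
                    )
                ],
                "source_shape": [list(s) for s in self.source_shape],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EncodedSignal":
        obj = json.loads(text)
        comps = np.asarray(obj["components"], dtype=float).reshape(-1, 3)
        return cls(
            amplitudes=comps[:, 0],
            frequencies=comps[:, 1],
            phases=comps[:, 2],
            source_shape=[tuple(s) for s in obj["source_shape"]],
        )


@dataclass
class SpikeTrain:
    """Per-channel sorted spike times (ms); the exchange format of the stack.

    ``spikes`` maps 0-based integer channel/neuron ids to strictly increasing
    arrays of spike times within ``[0, duration]``.
    """

    spikes: dict[int, np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for nid, times in self.spikes.items():
            t = np.asarray(times, dtype=float)
            if t.size == 0:
                continue
            if np.any(~np.isfinite(t)):
                raise ValueError("spike times must be finite")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times of channel {nid} not strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike times outside [0, duration]")
            clean[int(nid)] = t
        self.spikes = clean

    @property
    def n_spikes(self) -> int:
        return sum(t.size for t in self.spikes.values())

    def counts(self) -> dict[int, int]:
        return {nid: int(t.size) for nid, t in self.spikes.items()}

    # --- TSV round trip ------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("neuron_id\ttime_ms\n")
            for nid in sorted(self.spikes):
                for t in self.spikes[nid]:
                    fh.write(f"{nid}\t{t:.6f}\n")

    @classmethod
    def from_tsv(cls, path, duration: float | None = None) -> "SpikeTrain":
        ids: list[int] = []
        times: list[float] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("neuron_id"):
                raise ValueError("expected a 'neuron_id\\ttime_ms' header")
            for line in fh:
                if not line.strip():
                    continue
                a, b = line.split("\t")
                ids.append(int(a))
                times.append(float(b))
        ids_arr = np.asarray(ids, dtype=int)
        t_arr = np.asarray(times, dtype=float)
        if duration is None:
            duration = float(t_arr.max()) if t_arr.size else 0.0
        spikes = {
            int(nid): t_arr[ids_arr == nid] for nid in np.unique(ids_arr)
        }
        return cls(spikes=spikes, duration=duration)


def encode_image(image: np.ndarray, params: CodingParams) -> EncodedSignal:
    """Encode a nonnegative 2-D brightness grid as a sum of sinusoids.

    Pixel (i, j) (1-based) becomes the component
    ``(brightness_ij + c) * sin(2*pi * j*f_max/M * t + i*360/N)``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must be a 2-D grid with at least one pixel")
    if np.any(~np.isfinite(img)):
        raise ValueError("image brightness must be finite")
    if np.any(img < 0):
        raise ValueError("image brightness must be nonnegative")
    n, m = img.shape
    i = np.arange(1, n + 1, dtype=float)[:, None]  # rows -> phase
    j = np.arange(1, m + 1, dtype=float)[None, :]  # cols -> frequency
    freqs = np.broadcast_to(j * params.f_max / m, img.shape)
    phases = np.broadcast_to(i * 360.0 / n, img.shape)
    amps = img + params.brightness_constant
    return EncodedSignal(
        amplitudes=amps.ravel(),
        frequencies=freqs.copy().ravel(),
        phases=phases.copy().ravel(),
        source_shape=[(n, m)],
    )


def evaluate_signal(sig: EncodedSignal, times_ms: np.ndarray) -> np.ndarray:
    """Sum the sinusoids at the given times (ms -> internally seconds)."""
    t = np.atleast_1d(np.asarray(times_ms, dtype=float)) / 1000.0
    if sig.n_components == 0:
        return np.zeros(t.shape)
    # chunk over components to bound the (n_comp x n_t) temporaries
    out = np.zeros(t.shape)
    phase_rad = np.deg2rad(sig.phases)
    omega = 2.0 * np.pi * sig.frequencies
    step = max(1, int(4e6 // max(t.size, 1)))
    for k in range(0, sig.n_components, step):
        sl = slice(k, k + step)
        out += sig.amplitudes[sl] @ np.sin(
            np.outer(omega[sl], t) + phase_rad[sl][:, None]
        )
    return out


def combine_signals(sigs: list[EncodedSignal]) -> EncodedSignal:
    """Concatenate component sets; evaluates to the pointwise sum."""
    if not sigs:
        raise ValueError("need at least one signal to combine")
    shapes: list[tuple[int, int]] = []
    for s in sigs:
        shapes.extend(s.source_shape)
    return EncodedSignal(
        amplitudes=np.concatenate([s.amplitudes for s in sigs]),
        frequencies=np.concatenate([s.frequencies for s in sigs]),
        phases=np.concatenate([s.phases for s in sigs]),
        source_shape=shapes,
    )


def signal_to_rate(
    sig: EncodedSignal, t0: float, t1: float, params: CodingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate series (spikes/s) on the coding dt grid.

    Negative excursions of the sine sum are rectified (``relu``, default) or
    folded (``abs``); the result is ``rate_scale * rectified signal``.
    Returns (bin start times in ms, rates).
    """
    edges = np.arange(t0, t1, params.dt)
    centers = edges + params.dt / 2.0
    vals = evaluate_signal(sig, centers)
    if params.rectify == "relu":
        vals = np.maximum(vals, 0.0)
    else:
        vals = np.abs(vals)
    return edges, params.rate_scale * vals


def poisson_spikes(
    rate_series: np.ndarray,
    dt_ms: float,
    n_channels: int,
    seed: int,
    t0: float = 0.0,
) -> SpikeTrain:
    """Independent inhomogeneous Poisson realizations of a common rate.

    The rate (spikes/s) is piecewise constant on bins of width ``dt_ms``; per
    bin the spike count is Poisson with mean ``rate * dt`` and spike times are
    uniform within the bin, which realizes the inhomogeneous process exactly.
    """
    rates = np.asarray(rate_series, dtype=float)
    if np.any(~np.isfinite(rates)):
        raise ValueError("rates must be finite")
    rates = np.maximum(rates, 0.0)
    rng = np.random.default_rng(seed)
    lam = rates * dt_ms / 1000.0
    counts = rng.poisson(lam[None, :].repeat(n_channels, axis=0))
    duration = t0 + rates.size * dt_ms
    spikes: dict[int, np.ndarray] = {}
    bin_starts = t0 + np.arange(rates.size) * dt_ms
    for ch in range(n_channels):
        c = counts[ch]
        nz = np.nonzero(c)[0]
        if nz.size == 0:
            continue
        reps = c[nz]
        starts = np.repeat(bin_starts[nz], reps)
        t = starts + rng.random(reps.sum()) * dt_ms
        t.sort()
        # ties have probability zero but would violate the strictness contract
        keep = np.concatenate(([True], np.diff(t) > 0))
        spikes[ch] = t[keep]
    return SpikeTrain(spikes=spikes, duration=duration)


def recover_quadrature(sig: EncodedSignal) -> dict[float, tuple[float, float]]:
    """Per-frequency in-phase/quadrature pairs of the signal.

    Writing each component as
    ``a*sin(wt+phi) = a*cos(phi)*sin(wt) + a*sin(phi)*cos(wt)``,
    the signal is fully determined by, and exactly recoverable as, the pair
    ``(sum a*cos(phi), sum a*sin(phi))`` at each distinct frequency.  All
    row-pixels of a column share one frequency, so this is the mathematically
    recoverable content of the code (full pixel-level inversion is not
    possible for more than two rows).
    """
    out: dict[float, tuple[float, float]] = {}
    phase_rad = np.deg2rad(sig.phases)
    ci = sig.amplitudes * np.cos(phase_rad)
    cq = sig.amplitudes * np.sin(phase_rad)
    freqs = np.round(sig.frequencies, 9)
    for f in np.unique(freqs):
        mask = freqs == f
        out[float(f)] = (float(ci[mask].sum()), float(cq[mask].sum()))
    return out
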