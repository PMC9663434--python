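"""Deterministic synthetic image families for desk-scale experiments.

Real benchmark sets (handwritten glyphs, face photographs) live outside this
package's test path; these fixtures emulate the one property the intertwined
recognizer depends on — each "dataset" has its own image dimensions, hence
its own frequency/phase lattice under the sinusoidal encoding.  Glyph classes
are hand-coded binary masks (bars, cross, ring, checker, wedge, X); the
"faces" family uses smooth Gaussian-blob textures to mimic gray-level
structure.  Samples are prototypes plus seeded Gaussian pixel noise clipped
to [0, 1], with train/test splits disjoint by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import (
    CodingParams,
    EncodedSignal,
    combine_signals,
    encode_image,
    signal_to_rate,
)
from .training import LabeledImage

__all__ = [
    "FixtureSpec",
    "GLYPH_ORDER",
    "make_glyphs",
    "default_families",
    "make_intertwined_fixture",
    "write_pgm",
    "read_image",
    "write_fixture_dataset",
    "load_fixture_dataset",
]


def _hbar(shape, frac=0.5):
    img = np.zeros(shape)
    r = int(frac * (shape[0] - 1))
    img[max(r - 1, 0): r + 1, :] = 1.0
    return img


def _cross(shape):
    img = _hbar(shape)
    c = shape[1] // 2
    img[: shape[0] // 2, max(c - 1, 0): c + 1] = 1.0  # half-height stroke
    return np.clip(img, 0, 1)


def _ring(shape):
    img = np.zeros(shape)
    img[1:-1, 1] = img[1:-1, -2] = 1.0
    img[1, 1:-1] = img[-2, 1:-1] = 1.0
    return img


def _halfblock(shape, col_lo, col_hi):
    img = np.zeros(shape)
    c0 = int(col_lo * shape[1])
    c1 = max(int(col_hi * shape[1]), c0 + 1)
    img[: shape[0] // 2, c0:c1] = 1.0
    return img


def _wedge(shape):
    r = np.arange(shape[0])[:, None] / max(shape[0] - 1, 1)
    c = np.arange(shape[1])[None, :] / max(shape[1] - 1, 1)
    return (c <= r).astype(float)


def _xstroke(shape):
    img = np.zeros(shape)
    n, m = shape
    rows = np.arange(n)
    cols = np.clip((rows * (m - 1)) // max(n - 1, 1), 0, m - 1)
    img[rows, cols] = 1.0
    img[rows, m - 1 - cols] = 1.0
    return img


def _blob(shape, centers, width=0.22):
    rr = np.linspace(0, 1, shape[0])[:, None]
    cc = np.linspace(0, 1, shape[1])[None, :]
    img = np.zeros(shape)
    for (r0, c0) in centers:
        img += np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2)))
    return np.clip(img, 0, 1)


# NOTE: within a column the phases i*360/N span the full circle, so the code
# transmits exactly the first row-harmonic of each column (a quadrature pair
# per frequency); column-constant content — full-height bars, the brightness
# offset — and any higher row-harmonic cancel identically.  The prototypes
# are therefore built to have distinct per-column first-harmonic profiles.
GLYPH_ORDER = ("ltop", "rtop", "wedge", "x", "htop", "hbot", "ring", "cross")

_GLYPHS = {
    "ltop": lambda s: _halfblock(s, 0.0, 0.5),
    "rtop": lambda s: _halfblock(s, 0.5, 1.0),
    "wedge": _wedge,
    "x": _xstroke,
    "htop": lambda s: _hbar(s, 0.15),
    "hbot": lambda s: _hbar(s, 0.85),
    "ring": _ring,
    "cross": _cross,
}

_BLOB_CENTERS = [
    [(0.3, 0.2)],
    [(0.3, 0.8)],
    [(0.65, 0.35), (0.65, 0.65)],
    [(0.75, 0.15), (0.2, 0.55)],
    [(0.5, 0.2), (0.5, 0.8)],
    [(0.2, 0.2), (0.8, 0.8), (0.2, 0.8)],
]


@dataclass(frozen=True)
class FixtureSpec:
    """One synthetic "dataset": class count, shape, sampling and noise.

    With ``power_normalize`` (default) the prototypes are rescaled so every
    class produces the same mean rectified signal power under the encoding;
    classes then differ in waveform *shape* rather than overall drive level,
    which is the property the max-rate readout is meant to test.
    """

    family: str = "glyphs"
    n_classes: int = 4
    image_shape: tuple[int, int] = (16, 16)
    samples_per_class: int = 20
    pixel_noise_sd: float = 0.05
    test_fraction: float = 0.2
    seed: int = 0
    kind: str = "glyph"  # "glyph" | "texture"
    power_normalize: bool = True

    def __post_init__(self) -> None:
        if self.pixel_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        limit = len(GLYPH_ORDER) if self.kind == "glyph" else len(_BLOB_CENTERS)
        if self.n_classes > limit:
            raise ValueError(
                f"at most {limit} {self.kind} prototype classes are available"
            )
        if self.kind not in ("glyph", "texture"):
            raise ValueError("kind must be 'glyph' or 'texture'")


def _mean_rectified_power(img: np.ndarray) -> float:
    """Mean of max(0, signal) over one second; linear in brightness scale."""
    cp = CodingParams(f_max=40.0, dt=1.0, rate_scale=1.0)
    _, rates = signal_to_rate(encode_image(img, cp), 0.0, 1000.0, cp)
    return float(rates.mean())


def prototype(spec: FixtureSpec, class_index: int) -> np.ndarray:
    if spec.kind == "glyph":
        img = _GLYPHS[GLYPH_ORDER[class_index]](spec.image_shape)
    else:
        img = _blob(spec.image_shape, _BLOB_CENTERS[class_index])
    if spec.power_normalize:
        powers = []
        for c in range(spec.n_classes):
            if spec.kind == "glyph":
                p = _GLYPHS[GLYPH_ORDER[c]](spec.image_shape)
            else:
                p = _blob(spec.image_shape, _BLOB_CENTERS[c])
            powers.append(_mean_rectified_power(p))
        target = min(powers)
        if powers[class_index] > 0:
            img = img * (target / powers[class_index])
    return img


def make_glyphs(spec: FixtureSpec) -> list[LabeledImage]:
    """Labeled noisy samples for every class; byte-deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n_test = max(1, int(round(spec.samples_per_class * spec.test_fraction)))
    out: list[LabeledImage] = []
    for c in range(spec.n_classes):
        proto = prototype(spec, c)
        for k in range(spec.samples_per_class):
            noise = rng.normal(0.0, spec.pixel_noise_sd, proto.shape) \
                if spec.pixel_noise_sd > 0 else 0.0
            img = np.clip(proto + noise, 0.0, 1.0)
            out.append(
                LabeledImage(
                    image=img,
                    label=c,
                    sample_id=f"{spec.family}-{c}-{k:03d}",
                    family=spec.family,
                    split="test" if k >= spec.samples_per_class - n_test else "train",
                )
            )
    return out


def default_families() -> dict[str, FixtureSpec]:
    """Three families with pairwise distinct image dimensions."""
    return {
        "glyphs": FixtureSpec(
            family="glyphs", image_shape=(16, 16), kind="glyph", seed=11
        ),
        "textures": FixtureSpec(
            family="textures", image_shape=(12, 10), kind="glyph", seed=22
        ),
        "faces": FixtureSpec(
            family="faces", image_shape=(20, 15), kind="texture", seed=33
        ),
    }


def make_intertwined_fixture(
    picks: list[LabeledImage], coding: CodingParams
) -> tuple[EncodedSignal, list[dict]]:
    """Superimpose one image per family into a combined signal.

    Rejects picks whose image shapes coincide — identical dimensions would
    collapse the frequency lattices and destroy separability.  Returns the
    combined signal and the ground-truth component records for scoring.
    """
    if not picks:
        raise ValueError("need at least one pick")
    shapes = [tuple(p.image.shape) for p in picks]
    if len(set(shapes)) != len(shapes):
        raise ValueError("picked families must have pairwise distinct image shapes")
    sigs = [encode_image(p.image, coding) for p in picks]
    truth = [
        {"family": p.family, "label": p.label, "sample_id": p.sample_id}
        for p in picks
    ]
    return combine_signals(sigs), truth


# --- desk-scale study system -------------------------------------------
#
# The reference architecture (5000 neurons, ~5e6 synapses) is reachable via
# configuration; the desk system scales it to 300-neuron platforms.  With the
# layer in-degree cut ~16-fold, initial weights are scaled up so summed
# synaptic drive per neuron stays comparable, the output readout is
# charge-balanced (see wire_output_layer), and the STDP window is made
# depression-dominant (unprinted LTD amplitudes set to twice their LTP
# counterparts) because the symmetric default diverges under the causal
# pre-before-post correlations of a driven network.

def desk_coding() -> CodingParams:
    """Desk-scale coding: gamma-band ceiling, 1 ms rate bins."""
    return CodingParams(f_max=40.0, dt=1.0, rate_scale=800.0)


def desk_network(n_classes: int = 4, seed: int = 0, n: int = 300):
    """A 300-neuron recognition platform in the desk-scale regime."""
    from .dynamics import SynapseParams
    from .plasticity import PlasticityParams
    from .training import build_network

    rows = 20
    cols = int(np.ceil(n / rows))
    return build_network(
        n=n,
        n_classes=n_classes,
        grid=(rows, cols),
        p=0.2,
        j_ext=1.0,
        rec_weight_sd=2.0,
        out_weight_sd=3.0,
        out_balance=0.8,
        syn=SynapseParams(D=10.0),
        coding=desk_coding(),
        plasticity=PlasticityParams(
            a_minus=0.12, g_minus=0.10, ds=10.0, w_max=8.0
        ),
        seed=seed,
    )


def desk_schedule(seed: int = 0):
    """3 unsupervised epochs + labeling, 300 ms patterns, 100 ms blanks."""
    from .training import TrainingSchedule

    return TrainingSchedule(
        n_train_epochs=3, present_ms=300.0, blank_ms=100.0, seed=seed
    )


def desk_system(platforms, seed: int = 0, n: int = 300, n_shared: int = 150):
    """Hub + platforms wired as an intertwined-recognition system.

    The hub shares the platform architecture but is never trained; the
    shared-neuron count scales the reference 500 down with the layer size.
    """
    from .coherence import IntertwinedSystem
    from .dynamics import SynapseParams
    from .topology import build_connectivity, build_population, wire_external

    rows = 20
    cols = int(np.ceil(n / rows))
    hub_pop = build_population(n=n, grid=(rows, cols), seed=seed)
    hub_conn = build_connectivity(
        hub_pop, p=0.2, weight_sd=2.0, seed=seed + 101
    ).extend(wire_external(hub_pop, j_ext=1.0))
    rng = np.random.default_rng(seed + 202)
    shared = rng.choice(n, size=min(n_shared, n), replace=False)
    return IntertwinedSystem(
        hub_pop=hub_pop,
        hub_conn=hub_conn,
        platforms=list(platforms),
        shared_ids=shared,
        threshold=0.8,
        lfp_gain=60.0,
        ref_dt=5.0,
        transient_ms=100.0,
        syn=SynapseParams(D=10.0),
        dt=0.05,
    )


# --- disk round trip ----------------------------------------------------

def write_pgm(path, image: np.ndarray) -> None:
    """8-bit binary PGM of a [0, 1] brightness grid."""
    img = np.clip(np.asarray(image, dtype=float), 0, 1)
    data = (img * 255).round().astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(f"P5\n{img.shape[1]} {img.shape[0]}\n255\n".encode())
        fh.write(data.tobytes())


def read_image(path) -> np.ndarray:
    """Grayscale PGM/PNG as a [0, 1] float array."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("I"))
    peak = 65535.0 if arr.max() > 255 else 255.0
    return arr.astype(float) / peak


def write_fixture_dataset(directory, images: list[LabeledImage]) -> Path:
    """PGM files plus a (path, label, family, split) CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "label", "family", "split"])
        for it in images:
            fname = f"{it.sample_id}.pgm"
            write_pgm(directory / fname, it.image)
            writer.writerow([fname, it.label, it.family, it.split])
    return manifest


def load_fixture_dataset(manifest_path) -> list[LabeledImage]:
    manifest_path = Path(manifest_path)
    out: list[LabeledImage] = []
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            img = read_image(manifest_path.parent / row["image_path"])
            out.append(
                LabeledImage(
                    image=img,
                    label=int(row["label"]) if row["label"].isdigit() else row["label"],
                    sample_id=Path(row["image_path"]).stem,
                    family=row["family"],
                    split=row["split"],
                )
            )
    return out
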