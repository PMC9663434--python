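"""Unsupervised training loop, rate-based class assignment, evaluation.

A recognition network is trained by presenting encoded patterns as external
Poisson drive while spatial STDP runs online: three unsupervised epochs over
the (shuffled) training set with 100 ms silent blanks between patterns, then
one labeling epoch with frozen weights in which each classifying output
neuron is assigned the class for which its mean firing rate is maximal.
Classification of a test pattern is the class of the maximally firing output
neuron; ties break toward the lowest class index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Simulator, SynapseParams
from .encoding import CodingParams, encode_image, poisson_spikes, signal_to_rate
from .plasticity import PlasticityParams
from .topology import (
    Population,
    build_connectivity,
    build_population,
    wire_external,
    wire_output_layer,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSchedule",
    "LabeledImage",
    "RecognitionNetwork",
    "TrainedModel",
    "build_network",
    "presentation_rates",
    "train_unsupervised",
    "assign_classes",
    "labels_from_rates",
    "decide_class",
    "classify",
    "evaluate",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Epoch counts, presentation/blank durations (ms) and the run seed."""

    n_train_epochs: int = 3
    n_label_epochs: int = 1
    present_ms: float = 200.0
    blank_ms: float = 100.0
    transient_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.present_ms <= 0 or self.blank_ms <= 0:
            raise ValueError("durations must be positive")
        if self.n_train_epochs < 0 or self.n_label_epochs < 0:
            raise ValueError("epoch counts must be nonnegative")


@dataclass
class LabeledImage:
    """A brightness grid with its label, stable id and train/test split."""

    image: np.ndarray
    label: object
    sample_id: str
    family: str = ""
    split: str = "train"


@dataclass
class RecognitionNetwork:
    """A pattern-recognition platform: population, wiring and run settings."""

    pop: Population
    conn: object
    syn: SynapseParams
    coding: CodingParams
    plasticity: PlasticityParams
    dt: float = 0.05
    seed: int = 0
    _sim: Simulator | None = field(default=None, repr=False)

    def simulator(self, plastic: bool = True) -> Simulator:
        """A persistent simulator bound to this network's weights."""
        if self._sim is None:
            self._sim = Simulator(
                self.pop,
                self.conn,
                syn=self.syn,
                dt=self.dt,
                plasticity=self.plasticity,
            )
        return self._sim


@dataclass
class TrainedModel:
    """A frozen platform with its output-neuron -> class map."""

    pop: Population
    conn: object
    syn: SynapseParams
    coding: CodingParams
    dt: float
    class_of_output: dict[int, object]
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_network(
        cls, net: RecognitionNetwork, class_of_output, metadata=None
    ) -> "TrainedModel":
        return cls(
            pop=net.pop,
            conn=net.conn,
            syn=net.syn,
            coding=net.coding,
            dt=net.dt,
            class_of_output=dict(class_of_output),
            metadata=metadata or {},
        )

    def save(self, prefix) -> None:
        """Columnar container (<prefix>.npz) + JSON class map (<prefix>.json)."""
        import dataclasses
        import json
        from pathlib import Path

        prefix = Path(prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"),
            pre=self.conn.pre,
            post=self.conn.post,
            kind=self.conn.kind,
            weight=self.conn.weight,
            r=self.conn.r,
            is_excitatory=self.pop.is_excitatory,
            positions=self.pop.positions,
            n_grid=self.pop.n_grid,
            grid=np.asarray(self.pop.grid),
        )
        side = {
            "class_of_output": {str(k): v for k, v in self.class_of_output.items()},
            "syn": dataclasses.asdict(self.syn),
            "coding": dataclasses.asdict(self.coding),
            "dt": self.dt,
            "meta": {
                k: v
                for k, v in self.metadata.items()
                if isinstance(v, (str, int, float))
            },
        }
        prefix.with_suffix(".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def load(cls, prefix) -> "TrainedModel":
        import json
        from pathlib import Path

        from .topology import Connectivity

        prefix = Path(prefix)
        side = json.loads(prefix.with_suffix(".json").read_text())
        with np.load(prefix.with_suffix(".npz")) as z:
            pop = Population(
                is_excitatory=z["is_excitatory"],
                positions=z["positions"],
                grid=tuple(int(v) for v in z["grid"]),
                n_grid=int(z["n_grid"]),
            )
            conn = Connectivity(
                pre=z["pre"], post=z["post"], kind=z["kind"],
                weight=z["weight"], r=z["r"],
            )
        return cls(
            pop=pop,
            conn=conn,
            syn=SynapseParams(**side["syn"]),
            coding=CodingParams(**side["coding"]),
            dt=float(side["dt"]),
            class_of_output={int(k): v for k, v in side["class_of_output"].items()},
            metadata=side.get("meta", {}),
        )


def build_network(
    n: int = 5000,
    n_classes: int = 10,
    grid: tuple[int, int] = (100, 50),
    frac_exc: float = 0.8,
    p: float = 0.2,
    j_ext: float = 5.0,
    rec_weight_sd: float = 0.2,
    out_weight_sd: float = 0.2,
    out_gaba_weight_sd: float | None = None,
    out_balance: float | None = None,
    syn: SynapseParams | None = None,
    coding: CodingParams | None = None,
    plasticity: PlasticityParams | None = None,
    dt: float = 0.05,
    seed: int = 0,
) -> RecognitionNetwork:
    """Assemble layer + external drive + fully connected output layer.

    ``rec_weight_sd``/``out_weight_sd`` set the Gaussian-magnitude scale of
    the initial weights (0.2 at full scale); networks much smaller than the
    reference 5000-neuron layer need proportionally larger weights to keep
    the summed synaptic drive per neuron comparable.
    """
    pop = build_population(n=n, frac_exc=frac_exc, grid=grid, seed=seed)
    conn = build_connectivity(pop, p=p, weight_sd=rec_weight_sd, seed=seed)
    conn = conn.extend(wire_external(pop, j_ext=j_ext))
    pop, out_conn = wire_output_layer(
        pop,
        n_classes,
        weight_sd=out_weight_sd,
        gaba_weight_sd=out_gaba_weight_sd,
        balance=out_balance,
        seed=seed + 1,
    )
    conn = conn.extend(out_conn)
    return RecognitionNetwork(
        pop=pop,
        conn=conn,
        syn=syn or SynapseParams(),
        coding=coding or CodingParams(),
        plasticity=plasticity or PlasticityParams(),
        dt=dt,
        seed=seed,
    )


def presentation_rates(
    spikes, pop: Population, window: tuple[float, float]
) -> np.ndarray:
    """Mean firing rate (spikes/s) of each output neuron in the window."""
    t0, t1 = window
    rates = np.zeros(pop.n_outputs)
    for k, nid in enumerate(range(pop.n_grid, pop.n)):
        t = spikes.spikes.get(nid)
        if t is not None:
            rates[k] = ((t >= t0) & (t < t1)).sum() / ((t1 - t0) / 1000.0)
    return rates


def labels_from_rates(mean_rates: np.ndarray, classes: list) -> dict[int, object]:
    """Row-argmax labeling: each output gets its maximum-rate class.

    Ties (including all-silent outputs) break toward the lowest class index,
    with a warning for silent outputs.
    """
    out: dict[int, object] = {}
    for o in range(mean_rates.shape[0]):
        row = mean_rates[o]
        if row.max() == 0:
            logger.warning(
                "output neuron %d silent for all classes; assigned %r",
                o,
                classes[0],
            )
        out[o] = classes[int(np.argmax(row))]
    return out


def decide_class(rates: np.ndarray, class_of_output: dict[int, object]):
    """Class of the maximally firing output; rate ties -> lowest class."""
    best = rates.max()
    tied = np.nonzero(rates == best)[0]
    if tied.size > 1:
        logger.info("rate tie between outputs %s; lowest class wins", tied)
    return min((class_of_output[int(o)] for o in tied), key=str)


def _as_image(item) -> np.ndarray:
    return item.image if isinstance(item, LabeledImage) else np.asarray(item)


def _present(
    net: RecognitionNetwork,
    sim: Simulator,
    image: np.ndarray,
    present_ms: float,
    seed: int,
    plastic: bool,
):
    sig = encode_image(image, net.coding)
    _, rates = signal_to_rate(sig, 0.0, present_ms, net.coding)
    ext = poisson_spikes(rates, net.coding.dt, net.pop.n_grid, seed=seed)
    return sim.run(present_ms, external=ext, plastic=plastic)


def train_unsupervised(
    net: RecognitionNetwork, images, schedule: TrainingSchedule
) -> RecognitionNetwork:
    """Present the (unlabeled) set for the scheduled epochs with STDP on.

    Patterns are reshuffled each epoch under the schedule seed; a silent
    ``blank_ms`` interval separates consecutive presentations so the dynamic
    state settles.  External input weights are never touched.
    """
    items = list(images)
    if not items:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(schedule.seed)
    sim = net.simulator()
    for epoch in range(schedule.n_train_epochs):
        order = rng.permutation(len(items))
        w_before = net.conn.weight.copy()
        for idx in order:
            _present(
                net,
                sim,
                _as_image(items[idx]),
                schedule.present_ms,
                seed=int(rng.integers(2**31)),
                plastic=True,
            )
            sim.run(schedule.blank_ms, external=None, plastic=True)
        dw = np.abs(net.conn.weight - w_before).mean()
        logger.info("epoch %d: mean |dw| = %.4g", epoch + 1, dw)
    return net


def assign_classes(
    net: RecognitionNetwork,
    labeled,
    schedule: TrainingSchedule,
) -> TrainedModel:
    """Labeling epoch: map each output neuron to its maximum-rate class.

    Weights are frozen.  An output neuron silent for every class is assigned
    class index 0 by the tie-break, with a warning.
    """
    items = [it for it in labeled]
    if not items:
        raise ValueError("labeling set is empty")
    classes = sorted({it.label for it in items}, key=str)
    rng = np.random.default_rng(schedule.seed + 1)
    sim = net.simulator()
    window = (schedule.transient_ms, schedule.present_ms)
    sums = np.zeros((net.pop.n_outputs, len(classes)))
    counts = np.zeros(len(classes))
    for it in items:
        sim.reset()
        res = _present(
            net,
            sim,
            _as_image(it),
            schedule.present_ms,
            seed=int(rng.integers(2**31)),
            plastic=False,
        )
        c = classes.index(it.label)
        sums[:, c] += presentation_rates(res.spikes, net.pop, window)
        counts[c] += 1
    mean_rates = sums / np.maximum(counts, 1)
    class_of_output = labels_from_rates(mean_rates, classes)
    return TrainedModel.from_network(
        net,
        class_of_output,
        metadata={
            "schedule": schedule,
            "classes": classes,
            "mean_rates": mean_rates,
        },
    )


def classify(
    model: TrainedModel,
    image,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
) -> object:
    """Class of the maximally firing output neuron for one presentation."""
    schedule = schedule or TrainingSchedule()
    net = RecognitionNetwork(
        pop=model.pop,
        conn=model.conn,
        syn=model.syn,
        coding=model.coding,
        plasticity=PlasticityParams(),
        dt=model.dt,
    )
    sim = net.simulator()
    sim.reset()
    res = _present(
        net, sim, _as_image(image), schedule.present_ms, seed=seed, plastic=False
    )
    rates = presentation_rates(
        res.spikes, model.pop, (schedule.transient_ms, schedule.present_ms)
    )
    return decide_class(rates, model.class_of_output)


def evaluate(
    model: TrainedModel,
    test_set,
    train_ids=None,
    schedule: TrainingSchedule | None = None,
    seed: int = 0,
):
    """Accuracy and confusion matrix over a labeled test set.

    If ``train_ids`` is given, any overlap of sample ids with the test set is
    rejected (train/test separation is part of the evaluation contract).
    """
    items = list(test_set)
    if train_ids is not None:
        overlap = {it.sample_id for it in items} & set(train_ids)
        if overlap:
            raise ValueError(f"test samples also in training set: {sorted(overlap)}")
    classes = sorted(set(model.class_of_output.values()), key=str)
    index = {c: k for k, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    rng = np.random.default_rng(seed)
    correct = 0
    for it in items:
        pred = classify(
            model, it, schedule=schedule, seed=int(rng.integers(2**31))
        )
        if it.label not in index:
            index[it.label] = len(index)  # unseen true class: widen matrix
            classes.append(it.label)
            confusion = np.pad(confusion, ((0, 1), (0, 1)))
        confusion[index[it.label], index[pred]] += 1
        correct += pred == it.label
    accuracy = correct / len(items) if items else float("nan")
    return accuracy, confusion, classes
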