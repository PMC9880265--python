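"""Continual learning with FN-synapse weights.

Every weight and bias of a small multi-layer perceptron is backed by one
FN-synapse instance.  An optimizer (SGD/Adam/Adagrad) proposes a step for
each parameter; the step is converted to an input pulse of proportional
width, the synapse integrates it, and the network weight is read back as
``gain * Wd``.  Because the per-pulse imprint is proportional to
``(1 - alpha)`` — which shrinks as a synapse accumulates usage — heavily
used parameters stiffen and later tasks overwrite them less: on-device
memory consolidation with no auxiliary importance estimates.  Elastic
weight consolidation (EWC) and its online variant are provided as
algorithmic baselines.

Task streams follow the incremental-domain conventions: ``split`` trains a
two-way classifier on successive disjoint class pairs ([0,1], [2,3], ...);
``permuted`` presents the full classification problem under fresh input
permutations.  The default data source is a synthetic Gaussian-blob
generator (10 classes on a sphere of radius 3 in 64 dimensions, unit
isotropic noise), which keeps the benchmark self-contained; an adapter for
IDX-format image files (MNIST layout: zero-padding to 32 x 32 and
per-pixel standardization) covers the image-scale variants.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import numpy as np

from .device import SynapseState, alpha_from_wc
from .params import DeviceParams

# ---------------------------------------------------------------------------
# task streams


@dataclasses.dataclass
class Task:
    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    classes: tuple


@dataclasses.dataclass
class TaskStream:
    tasks: list[Task]
    scheme: str
    seed: int
    n_outputs: int
    dim: int


def _synthetic_classes(
    rng: np.random.Generator,
    n_classes: int,
    dim: int,
    train_per_class: int,
    test_per_class: int,
    center_radius: float,
):
    """Gaussian blobs with centers uniform on a sphere of ``center_radius``.

    With unit isotropic noise the typical pairwise center distance is
    ``radius * sqrt(2)``, comfortably separable for a small MLP.
    """
    centers = rng.standard_normal((n_classes, dim))
    centers *= center_radius / np.linalg.norm(centers, axis=1, keepdims=True)
    xs_tr, xs_te = [], []
    for c in centers:
        xs_tr.append(c + rng.standard_normal((train_per_class, dim)))
        xs_te.append(c + rng.standard_normal((test_per_class, dim)))
    return xs_tr, xs_te


def load_idx(path: str | Path) -> np.ndarray:
    """Read one IDX-format array (the MNIST container format)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected IDX file at {path}")
    raw = path.read_bytes()
    zero, dtype_code, ndim = raw[0] << 8 | raw[1], raw[2], raw[3]
    if zero != 0:
        raise ValueError(f"{path} is not an IDX file (bad magic)")
    dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.dtype(">i2"),
              0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"), 0x0E: np.dtype(">f8")}
    shape = struct.unpack(">" + "I" * ndim, raw[4 : 4 + 4 * ndim])
    data = np.frombuffer(raw, dtype=dtypes[dtype_code], offset=4 + 4 * ndim)
    return data.reshape(shape).copy()


def _load_image_source(data_dir: str | Path):
    data_dir = Path(data_dir)
    names = {
        "x_train": "train-images-idx3-ubyte",
        "y_train": "train-labels-idx1-ubyte",
        "x_test": "t10k-images-idx3-ubyte",
        "y_test": "t10k-labels-idx1-ubyte",
    }
    missing = [str(data_dir / v) for v in names.values() if not (data_dir / v).exists()]
    if missing:
        raise FileNotFoundError("missing IDX files: " + ", ".join(missing))
    arr = {k: load_idx(data_dir / v) for k, v in names.items()}
    out = {}
    for split in ("train", "test"):
        x = arr[f"x_{split}"].astype(np.float64)
        pad = (32 - x.shape[1]) // 2
        if pad > 0:
            x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
        out[f"x_{split}"] = x.reshape(x.shape[0], -1)
        out[f"y_{split}"] = arr[f"y_{split}"].astype(np.int64)
    # standardize with train statistics; guard constant (padded) pixels
    mu = out["x_train"].mean(axis=0)
    sd = out["x_train"].std(axis=0)
    sd[sd == 0] = 1.0
    for split in ("train", "test"):
        out[f"x_{split}"] = (out[f"x_{split}"] - mu) / sd
    return out


def build_task_stream(
    source: str = "synthetic",
    scheme: str = "split",
    seed: int = 0,
    n_classes: int = 10,
    dim: int = 64,
    train_per_class: int = 500,
    test_per_class: int = 100,
    center_radius: float = 3.0,
    n_permuted_tasks: int = 10,
) -> TaskStream:
    """Assemble an ordered task stream.

    ``source`` is ``"synthetic"`` or a directory containing MNIST-layout IDX
    files.  ``split``: ``n_classes/2`` two-way tasks over successive class
    pairs.  ``permuted``: ``n_permuted_tasks`` copies of the full problem
    under fixed random input permutations (task 1 is the identity).
    """
    if scheme not in ("split", "permuted"):
        raise ValueError("scheme must be 'split' or 'permuted'")
    rng = np.random.default_rng(seed)
    if source == "synthetic":
        xs_tr, xs_te = _synthetic_classes(
            rng, n_classes, dim, train_per_class, test_per_class, center_radius
        )
        x_train = np.concatenate(xs_tr)
        y_train = np.repeat(np.arange(n_classes), train_per_class)
        x_test = np.concatenate(xs_te)
        y_test = np.repeat(np.arange(n_classes), test_per_class)
    else:
        d = _load_image_source(source)
        x_train, y_train, x_test, y_test = d["x_train"], d["y_train"], d["x_test"], d["y_test"]
        n_classes = int(y_train.max()) + 1
        dim = x_train.shape[1]

    tasks: list[Task] = []
    if scheme == "split":
        for a in range(0, n_classes - 1, 2):
            pair = (a, a + 1)
            tr = np.isin(y_train, pair)
            te = np.isin(y_test, pair)
            tasks.append(
                Task(
                    x_train=x_train[tr], y_train=(y_train[tr] == pair[1]).astype(np.int64),
                    x_test=x_test[te], y_test=(y_test[te] == pair[1]).astype(np.int64),
                    classes=pair,
                )
            )
        n_outputs = 2
    else:
        for t in range(n_permuted_tasks):
            perm = np.arange(dim) if t == 0 else rng.permutation(dim)
            tasks.append(
                Task(
                    x_train=x_train[:, perm], y_train=y_train.copy(),
                    x_test=x_test[:, perm], y_test=y_test.copy(),
                    classes=tuple(range(n_classes)),
                )
            )
        n_outputs = n_classes
    return TaskStream(tasks=tasks, scheme=scheme, seed=seed, n_outputs=n_outputs, dim=dim)


# ---------------------------------------------------------------------------
# MLP + optimizers


class MLP:
    """ReLU MLP with a softmax head; parameters live in ``self.params``."""

    def __init__(self, sizes: list[int], seed: int = 0):
        rng = np.random.default_rng(seed)
        self.sizes = list(sizes)
        self.params = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            self.params.append(
                {
                    "W": rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in),
                    "b": np.zeros(fan_out),
                }
            )

    def forward(self, x: np.ndarray):
        acts = [x]
        for i, layer in enumerate(self.params):
            z = acts[-1] @ layer["W"] + layer["b"]
            acts.append(np.maximum(z, 0.0) if i < len(self.params) - 1 else z)
        return acts

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(x)[-1], axis=1)

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == y))

    def loss_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy loss and its gradients."""
        acts = self.forward(x)
        logits = acts[-1]
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        n = x.shape[0]
        loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
        delta = p
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads = [None] * len(self.params)
        for i in range(len(self.params) - 1, -1, -1):
            grads[i] = {"W": acts[i].T @ delta, "b": delta.sum(axis=0)}
            if i > 0:
                delta = (delta @ self.params[i]["W"].T) * (acts[i] > 0)
        return loss, grads


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, grads):
        return [{k: -self.lr * g[k] for k in g} for g in grads]


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = None
        self.v = None

    def step(self, grads):
        if self.m is None:
            self.m = [{k: np.zeros_like(g[k]) for k in g} for g in grads]
            self.v = [{k: np.zeros_like(g[k]) for k in g} for g in grads]
        self.t += 1
        out = []
        for m, v, g in zip(self.m, self.v, grads):
            d = {}
            for k in g:
                m[k] = self.b1 * m[k] + (1 - self.b1) * g[k]
                v[k] = self.b2 * v[k] + (1 - self.b2) * g[k] ** 2
                mhat = m[k] / (1 - self.b1**self.t)
                vhat = v[k] / (1 - self.b2**self.t)
                d[k] = -self.lr * mhat / (np.sqrt(vhat) + self.eps)
            out.append(d)
        return out


class Adagrad:
    def __init__(self, lr: float, eps: float = 1e-10):
        self.lr, self.eps = lr, eps
        self.g2 = None

    def step(self, grads):
        if self.g2 is None:
            self.g2 = [{k: np.zeros_like(g[k]) for k in g} for g in grads]
        out = []
        for g2, g in zip(self.g2, grads):
            d = {}
            for k in g:
                g2[k] += g[k] ** 2
                d[k] = -self.lr * g[k] / (np.sqrt(g2[k]) + self.eps)
            out.append(d)
        return out


# ---------------------------------------------------------------------------
# FN-synapse weight backing


@dataclasses.dataclass
class FNWeightArray:
    """One FN-synapse per network parameter.

    ``weight == voltage_to_weight_gain * Wd`` at all times; a requested step
    ``s`` becomes a pulse of width ``pulse_gain * |s|`` and amplitude
    ``sign(s) * pulse_amplitude``, so the realized update is
    ``gain * (1 - alpha) * (x*sign(s) - Wd)``: proportional to the request
    on a fresh synapse (by calibration) and attenuated as usage accrues.
    """

    states: list[dict]  # per layer: {"W": SynapseState, "b": SynapseState}
    params: DeviceParams
    voltage_to_weight_gain: float
    pulse_gain: float
    pulse_amplitude: float

    @classmethod
    def create(
        cls,
        init_weights: list[dict],
        params: DeviceParams,
        weight_scale: float = 1.0,
        pulse_amplitude: float = 1.15,
        calibrate: bool = True,
    ) -> "FNWeightArray":
        """Build synapses programmed to the network's initial weights.

        Each synapse starts at the initial usage potential Wc0 with its
        differential component set to ``weight / gain`` (the hardware
        programming step); passing zero arrays gives fresh zero-weight
        synapses.
        """
        gain = weight_scale / pulse_amplitude
        states = []
        for layer in init_weights:
            st = {}
            for k in layer:
                wd0 = np.asarray(layer[k], dtype=float) / gain
                st[k] = SynapseState(
                    w_plus=params.Wc0 + wd0,
                    w_minus=params.Wc0 - wd0,
                    n_updates=np.zeros(wd0.shape, dtype=np.int64),
                )
            states.append(st)
        # first-order pulse gain: realized ~ gain * x * (1+2/lnK0) * k1*tau/K0
        k0 = params.k0
        ln0 = np.log(k0)
        pg = k0 / (params.k1 * pulse_amplitude * gain * (1.0 + 2.0 / ln0))
        obj = cls(
            states=states, params=params, voltage_to_weight_gain=gain,
            pulse_gain=pg, pulse_amplitude=pulse_amplitude,
        )
        if calibrate:
            obj.calibrate()
        return obj

    def calibrate(self, probe_step: float = 1e-3) -> float:
        """Adjust ``pulse_gain`` so a fresh synapse realizes its first request.

        Measures the realized weight change of a probe step on a scratch
        synapse and rescales; returns the post-calibration realized/requested
        ratio (1 to first order, since the response is linear in pulse
        width).
        """
        for _ in range(2):
            s = SynapseState.fresh(self.params)
            tau = self.pulse_gain * probe_step
            alpha, _ = alpha_from_wc(s.wc, self.params, width=tau)
            realized = self.voltage_to_weight_gain * (1.0 - alpha) * self.pulse_amplitude
            self.pulse_gain *= probe_step / realized
        return realized / probe_step

    def read_weights(self) -> list[dict]:
        g = self.voltage_to_weight_gain
        return [{k: g * st[k].wd for k in st} for st in self.states]

    def apply_gradient_step(self, deltas: list[dict]) -> None:
        """Realize optimizer-proposed steps as FN-synapse pulses.

        Parameters with an exactly zero step receive no pulse (their state,
        including usage, is untouched).
        """
        amp = self.pulse_amplitude
        for st, d in zip(self.states, deltas):
            for k in d:
                step = d[k]
                state = st[k]
                tau = self.pulse_gain * np.abs(step)
                alpha, wc_new = alpha_from_wc(state.wc, self.params, width=tau)
                v = amp * np.sign(step)
                wd_new = alpha * state.wd + (1.0 - alpha) * v
                pulsed = step != 0
                wc_new = np.where(pulsed, wc_new, state.wc)
                wd_new = np.where(pulsed, wd_new, state.wd)
                st[k] = SynapseState(
                    w_plus=wc_new + wd_new,
                    w_minus=wc_new - wd_new,
                    n_updates=state.n_updates + pulsed,
                )

    def layer_wc(self, layer: int, kind: str = "W") -> np.ndarray:
        return np.asarray(self.states[layer][kind].wc).ravel()

    def mean_alpha(self) -> float:
        vals = []
        for st in self.states:
            for k in st:
                a, _ = alpha_from_wc(st[k].wc, self.params)
                vals.append(np.mean(a))
        return float(np.mean(vals))


def usage_histogram(weights: FNWeightArray, layer: int, bins: int = 50, kind: str = "W"):
    """Per-layer histogram of the usage potentials Wc (consolidation map)."""
    wc = weights.layer_wc(layer, kind)
    counts, edges = np.histogram(wc, bins=bins)
    return counts, edges


# ---------------------------------------------------------------------------
# EWC baselines


class EWCPenalty:
    """Diagonal-Fisher quadratic penalty; ``online=True`` keeps one running
    Fisher (decayed by ``online_gamma``) and a single anchor."""

    def __init__(self, lam: float = 100.0, online: bool = False, online_gamma: float = 1.0):
        self.lam = lam
        self.online = online
        self.online_gamma = online_gamma
        self.terms = []  # list of (fisher, anchor); online keeps at most one

    def after_task(self, model: MLP, x: np.ndarray, y: np.ndarray, n_samples: int = 200, seed=0):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(x), size=min(n_samples, len(x)), replace=False)
        fisher = [{k: np.zeros_like(p[k]) for k in p} for p in model.params]
        for i in idx:
            _, g = model.loss_grads(x[i : i + 1], y[i : i + 1])
            for f, gi in zip(fisher, g):
                for k in f:
                    f[k] += gi[k] ** 2
        for f in fisher:
            for k in f:
                f[k] /= len(idx)
        anchor = [{k: p[k].copy() for k in p} for p in model.params]
        if self.online and self.terms:
            old_f, _ = self.terms[0]
            for f, of in zip(fisher, old_f):
                for k in f:
                    f[k] += self.online_gamma * of[k]
            self.terms = [(fisher, anchor)]
        elif self.online:
            self.terms = [(fisher, anchor)]
        else:
            self.terms.append((fisher, anchor))

    def add_penalty_grads(self, model: MLP, grads: list[dict]) -> None:
        for fisher, anchor in self.terms:
            for g, f, a, p in zip(grads, fisher, anchor, model.params):
                for k in g:
                    g[k] = g[k] + self.lam * f[k] * (p[k] - a[k])


# ---------------------------------------------------------------------------
# training harness


@dataclasses.dataclass
class Hyper:
    """Training hyper-parameters.

    Defaults are the synthetic-stream operating point (small MLP, plain-SGD
    learning rate 0.3, 5 epochs of batch-32 updates per task,
    weight scale 0.25); image-scale runs should pass the MNIST-style values
    (hidden 400/400, lr 1e-3, batch 128, 4 epochs) explicitly.
    ``weight_scale`` bounds the realizable weights to +/- its value and sets
    how quickly usage accrues per unit step (smaller = faster
    consolidation).  ``wc0`` overrides the synapses' initial plasticity.
    """

    lr: float = 0.3
    epochs: int = 5
    batch_size: int = 32
    hidden: tuple = (100, 100)
    seed: int = 0
    ewc_lambda: float = 100.0
    ewc_online_gamma: float = 1.0
    weight_scale: float = 0.25
    wc0: float | None = None  # initial plasticity knob for FN synapses
    fisher_samples: int = 200


def default_hyper(method: str, seed: int = 0) -> Hyper:
    """Synthetic-stream defaults per optimizer family: plain/FN SGD uses
    lr 0.3; Adam-family (incl. EWC baselines) 5e-3; Adagrad 5e-2."""
    base = method.removeprefix("fn_")
    lr = {"sgd": 0.3, "adam": 5e-3, "ewc": 5e-3, "online_ewc": 5e-3, "adagrad": 5e-2}[base]
    return Hyper(lr=lr, seed=seed)


@dataclasses.dataclass
class AccuracyMatrix:
    """acc[i][j]: accuracy on task j's test set after training task i."""

    matrix: np.ndarray  # (T, T), nan where j > i
    method: str
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def overall_average(self) -> float:
        last = self.matrix[-1]
        return float(np.nanmean(last))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "matrix": [[None if np.isnan(v) else v for v in row] for row in self.matrix],
                "overall_average": self.overall_average,
                "metadata": self.metadata,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


METHODS = ("sgd", "adam", "adagrad", "ewc", "online_ewc", "fn_sgd", "fn_adam", "fn_adagrad")


def _make_optimizer(method: str, lr: float):
    base = method.removeprefix("fn_")
    if base in ("sgd",):
        return SGD(lr)
    if base in ("adam", "ewc", "online_ewc"):
        return Adam(lr)
    if base == "adagrad":
        return Adagrad(lr)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def train_stream(
    stream: TaskStream,
    method: str,
    hyper: Hyper | None = None,
    device_params: DeviceParams | None = None,
    record_usage: bool = False,
) -> AccuracyMatrix:
    """Sequentially train on the task stream and score all seen tasks.

    FN methods route every optimizer step through the synapse array; EWC
    variants add the diagonal-Fisher quadratic penalty after each task.
    The optimizer is re-instantiated at each task boundary; FN-synapse state
    carries across tasks (that is the point).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    hyper = hyper or Hyper()
    sizes = [stream.dim, *hyper.hidden, stream.n_outputs]
    model = MLP(sizes, seed=hyper.seed)
    rng = np.random.default_rng(hyper.seed + 1)

    fn_weights = None
    if method.startswith("fn_"):
        dp = device_params or DeviceParams()
        if hyper.wc0 is not None:
            dp = dp.with_wc0(hyper.wc0)
        fn_weights = FNWeightArray.create(model.params, dp, weight_scale=hyper.weight_scale)
        # synapses are programmed to the random init; re-read to enforce the
        # weight == gain * Wd invariant exactly
        for p, w in zip(model.params, fn_weights.read_weights()):
            for k in p:
                p[k] = w[k]

    ewc = None
    if method in ("ewc", "online_ewc"):
        ewc = EWCPenalty(hyper.ewc_lambda, online=(method == "online_ewc"),
                         online_gamma=hyper.ewc_online_gamma)

    T = len(stream.tasks)
    acc = np.full((T, T), np.nan)
    usage = []
    for ti, task in enumerate(stream.tasks):
        opt = _make_optimizer(method, hyper.lr)
        n = len(task.x_train)
        for _ in range(hyper.epochs):
            order = rng.permutation(n)
            for s in range(0, n, hyper.batch_size):
                bi = order[s : s + hyper.batch_size]
                _, grads = model.loss_grads(task.x_train[bi], task.y_train[bi])
                if ewc is not None:
                    ewc.add_penalty_grads(model, grads)
                deltas = opt.step(grads)
                if fn_weights is None:
                    for p, d in zip(model.params, deltas):
                        for k in p:
                            p[k] += d[k]
                else:
                    fn_weights.apply_gradient_step(deltas)
                    for p, w in zip(model.params, fn_weights.read_weights()):
                        for k in p:
                            p[k] = w[k]
        if ewc is not None:
            ewc.after_task(model, task.x_train, task.y_train,
                           n_samples=hyper.fisher_samples, seed=hyper.seed + ti)
        for tj in range(ti + 1):
            acc[ti, tj] = model.accuracy(stream.tasks[tj].x_test, stream.tasks[tj].y_test)
        if record_usage and fn_weights is not None:
            usage.append([float(np.mean(fn_weights.layer_wc(li))) for li in range(len(sizes) - 1)])

    meta = {
        "scheme": stream.scheme, "seed": hyper.seed, "lr": hyper.lr,
        "epochs": hyper.epochs, "batch_size": hyper.batch_size,
        "hidden": list(hyper.hidden), "ewc_lambda": hyper.ewc_lambda if ewc else None,
        "mean_wc_per_layer_by_task": usage if record_usage else None,
    }
    out = AccuracyMatrix(matrix=acc, method=method, metadata=meta)
    out.fn_weights = fn_weights  # diagnostic handle; not serialized
    return out
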