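"""Bidirectional adversarial model over miRNA-disease pair feature vectors.

Three fully connected networks are trained jointly:

* an encoder ``E`` mapping a pair feature vector ``x`` (length nm + nd) to a
  latent code ``E(x)``;
* a generator ``G`` mapping latent noise ``z ~ N(0, I)`` back to feature
  space;
* a discriminator ``D`` that sees joint (feature, latent) pairs and must
  tell encoder pairs ``(x, E(x))`` from generator pairs ``(G(z), z)``.

The minimax objective is

    min_{G,E} max_D  E_x[log D(x, E(x))] + E_z[log(1 - D(G(z), z))]

optimized in the non-saturating form (the generator maximizes
``log D(G(z), z)`` and the encoder maximizes ``log(1 - D(x, E(x)))``), which
leaves the optimum unchanged but keeps early gradients alive.  At the
optimum E and G invert each other.  The association score of a pair is
``sigmoid(D(x, E(x)))``: how strongly the discriminator believes the pair
comes from the real (known-association) distribution.

Only known-association (label-1) feature vectors form the real data
distribution; unknown pairs are scored at inference time only.

Everything runs on CPU with numpy; gradients are hand-derived (the networks
are plain affine + LeakyReLU stacks, so backprop is a short chain rule).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import ScoredPair
from .similarity import PairFeatureSet

__all__ = [
    "DivergenceError",
    "NetworkSpec",
    "TrainConfig",
    "BganModel",
    "leaky_relu",
    "bce_loss",
    "sigmoid",
    "build_networks",
    "train",
    "score_pairs",
    "score_vectors",
    "save_model",
    "load_model",
]

_EPS = 1e-7  # clipping for all log terms


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def leaky_relu(x, eta: float = 0.01):
    """x for x >= 0, eta * x otherwise (elementwise)."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, eta * x)


def sigmoid(theta):
    theta = np.asarray(theta, dtype=float)
    out = np.empty_like(theta)
    pos = theta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-theta[pos]))
    e = np.exp(theta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_loss(predicted, labels) -> float:
    """Mean binary cross-entropy with predictions clipped to (eps, 1 - eps)."""
    p = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _geometric_hidden(d_in: int, d_out: int, n_hidden: int = 2) -> tuple[int, ...]:
    """Hidden widths interpolated geometrically between input and output."""
    lo, hi = np.log(max(d_out, 1)), np.log(max(d_in, 1))
    ws = np.exp(np.linspace(hi, lo, n_hidden + 2))[1:-1]
    return tuple(int(max(2, round(w))) for w in ws)


@dataclass
class NetworkSpec:
    """Architecture of the three networks.

    Each network has exactly three fully connected layers; the two hidden
    layers use LeakyReLU (slope ``eta``) followed by dropout.  When hidden
    widths are not given they interpolate geometrically between the input
    and output widths.
    """

    input_dim: int
    latent_dim: int = 100
    hidden_dims: tuple[int, int] | None = None
    disc_hidden_dims: tuple[int, int] | None = None
    eta: float = 0.01
    dropout: float = 0.5

    def __post_init__(self):
        if self.input_dim < 1 or self.latent_dim < 1:
            raise ValueError("input_dim and latent_dim must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.hidden_dims is None:
            self.hidden_dims = _geometric_hidden(self.input_dim, self.latent_dim)
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if len(self.hidden_dims) != 2:
            raise ValueError("hidden_dims must name exactly two hidden widths")
        if self.disc_hidden_dims is None:
            # the discriminator needs capacity comparable to the encoder's,
            # not a taper to scalar width
            self.disc_hidden_dims = _geometric_hidden(self.disc_input_dim, self.latent_dim)
        self.disc_hidden_dims = tuple(int(h) for h in self.disc_hidden_dims)
        if len(self.disc_hidden_dims) != 2:
            raise ValueError("disc_hidden_dims must name exactly two hidden widths")

    @property
    def disc_input_dim(self) -> int:
        return self.input_dim + self.latent_dim

    @property
    def encoder_dims(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_dims, self.latent_dim)

    @property
    def generator_dims(self) -> tuple[int, ...]:
        return (self.latent_dim, *reversed(self.hidden_dims), self.input_dim)

    @property
    def discriminator_dims(self) -> tuple[int, ...]:
        return (self.disc_input_dim, *self.disc_hidden_dims, 1)


@dataclass
class TrainConfig:
    """Optimization settings for adversarial training.

    Each repetition trains a fresh copy of the initial networks on a random
    (1 - holdout_fraction) subsample of the known-association vectors; the
    final score is the mean over repetitions.
    """

    lr: float = 2e-4
    batch_size: int = 128
    epochs: int = 20000
    holdout_fraction: float = 0.2
    n_repetitions: int = 5
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("lr, batch_size must be positive; epochs non-negative")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        # Adam state
        self.mW = np.zeros_like(self.W)
        self.vW = np.zeros_like(self.W)
        self.mb = np.zeros_like(self.b)
        self.vb = np.zeros_like(self.b)
        self.t = 0
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ gout
        self.gb += gout.sum(axis=0)
        return gout @ self.W.T

    def zero_grad(self):
        self.gW[:] = 0.0
        self.gb[:] = 0.0

    def adam_step(self, lr: float, b1: float, b2: float, eps: float = 1e-8):
        self.t += 1
        for p, g, m, v in ((self.W, self.gW, self.mW, self.vW),
                           (self.b, self.gb, self.mb, self.vb)):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class _MLP:
    """Three affine layers; LeakyReLU + dropout on the two hidden layers."""

    def __init__(self, dims, eta: float, dropout: float, rng: np.random.Generator):
        self.dims = tuple(dims)
        self.eta = eta
        self.dropout = dropout
        self.layers = [_Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self._cache = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = False) -> np.ndarray:
        pre_acts, masks = [], []
        h = np.asarray(x, dtype=float)
        last = len(self.layers) - 1
        for k, layer in enumerate(self.layers):
            h = layer.forward(h)
            if k < last:
                pre_acts.append(h)
                h = leaky_relu(h, self.eta)
                if train and self.dropout > 0:
                    mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
        self._cache = (pre_acts, masks)
        return h

    def backward(self, gout: np.ndarray) -> np.ndarray:
        pre_acts, masks = self._cache
        g = gout
        last = len(self.layers) - 1
        for k in range(last, -1, -1):
            if k < last:
                if masks[k] is not None:
                    g = g * masks[k]
                slope = np.where(pre_acts[k] >= 0, 1.0, self.eta)
                g = g * slope
            g = self.layers[k].backward(g)
        return g

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def step(self, lr: float, betas: tuple[float, float]):
        for layer in self.layers:
            layer.adam_step(lr, betas[0], betas[1])

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.W, layer.b])
        return out

    def load_state(self, arrays: list[np.ndarray]):
        for layer, (W, b) in zip(self.layers, zip(arrays[::2], arrays[1::2])):
            layer.W = np.array(W, dtype=float)
            layer.b = np.array(b, dtype=float)


@dataclass
class _Member:
    encoder: _MLP
    generator: _MLP
    discriminator: _MLP


@dataclass
class BganModel:
    """Encoder/generator/discriminator triple(s) plus training traces.

    ``members`` holds one network triple per training repetition; scoring
    averages over members.  ``loss_trace`` maps member id -> per-epoch
    (discriminator loss, encoder+generator loss) lists.
    """

    spec: NetworkSpec
    members: list[_Member]
    loss_trace: list[dict[str, list[float]]] = field(default_factory=list)
    trained: bool = False


def build_networks(spec: NetworkSpec, seed: int = 0) -> BganModel:
    """Deterministically initialized, untrained model (a single member)."""
    rng = np.random.default_rng(seed)
    member = _Member(
        encoder=_MLP(spec.encoder_dims, spec.eta, spec.dropout, rng),
        generator=_MLP(spec.generator_dims, spec.eta, spec.dropout, rng),
        discriminator=_MLP(spec.discriminator_dims, spec.eta, spec.dropout, rng),
    )
    return BganModel(spec=spec, members=[member])


def _train_member(member: _Member, X: np.ndarray, cfg: TrainConfig,
                  rng: np.random.Generator, spec: NetworkSpec) -> dict[str, list[float]]:
    E, G, D = member.encoder, member.generator, member.discriminator
    d_in = spec.input_dim
    n = len(X)
    trace = {"d_loss": [], "eg_loss": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        d_losses, eg_losses = [], []
        for start in range(0, n, cfg.batch_size):
            xb = X[order[start:start + cfg.batch_size]]
            b = len(xb)
            z = rng.standard_normal((b, spec.latent_dim))

            ex = E.forward(xb, rng, train=True)
            gz = G.forward(z, rng, train=True)

            # --- discriminator step: real = (x, E(x)) -> 1, fake = (G(z), z) -> 0
            D.zero_grad()
            logit_r = D.forward(np.hstack([xb, ex]), rng, train=True)
            p_r = sigmoid(logit_r)
            D.backward((p_r - 1.0) / b)
            logit_f = D.forward(np.hstack([gz, z]), rng, train=True)
            p_f = sigmoid(logit_f)
            D.backward(p_f / b)
            D.step(cfg.lr, cfg.betas)
            d_losses.append(0.5 * (bce_loss(p_r, np.ones(b)) + bce_loss(p_f, np.zeros(b))))

            # --- encoder/generator step (non-saturating): E -> 0 on real, G -> 1 on fake
            D.zero_grad()
            E.zero_grad()
            G.zero_grad()
            logit_r = D.forward(np.hstack([xb, ex]), rng, train=True)
            p_r = sigmoid(logit_r)
            gin = D.backward(p_r / b)  # target 0 for the encoder pair
            E.backward(gin[:, d_in:])
            logit_f = D.forward(np.hstack([gz, z]), rng, train=True)
            p_f = sigmoid(logit_f)
            gin = D.backward((p_f - 1.0) / b)  # target 1 for the generator pair
            G.backward(gin[:, :d_in])
            E.step(cfg.lr, cfg.betas)
            G.step(cfg.lr, cfg.betas)
            D.zero_grad()
            eg_losses.append(0.5 * (bce_loss(p_r, np.zeros(b)) + bce_loss(p_f, np.ones(b))))

        d_epoch = float(np.mean(d_losses))
        eg_epoch = float(np.mean(eg_losses))
        if not (np.isfinite(d_epoch) and np.isfinite(eg_epoch)):
            raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
        trace["d_loss"].append(d_epoch)
        trace["eg_loss"].append(eg_epoch)
    return trace


def train(model: BganModel, features: PairFeatureSet | np.ndarray,
          cfg: TrainConfig) -> BganModel:
    """Adversarial training on the known-association feature vectors.

    ``features`` may be a :class:`PairFeatureSet` (its label-1 pairs are
    used) or a pre-built array of real vectors.  Each of
    ``cfg.n_repetitions`` members starts from a copy of the given model's
    initial networks and trains on an independent random
    (1 - holdout_fraction) subsample.  Returns a new model; the input is
    untouched.  ``cfg.epochs == 0`` returns an identical copy.
    """
    if isinstance(features, PairFeatureSet):
        pos = [(i, j) for j, i in features.bm.positive_pairs()]
        if not pos:
            raise ValueError("no known associations to train on")
        X, _ = features.matrix(pos)
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"feature width {X.shape[-1] if X.ndim == 2 else '?'} does not match "
            f"model input {model.spec.input_dim}"
        )
    if len(X) == 0:
        raise ValueError("no known associations to train on")

    if cfg.epochs == 0:
        return copy.deepcopy(model)

    base = model.members[0]
    ss = np.random.SeedSequence(cfg.seed)
    out = BganModel(spec=model.spec, members=[], loss_trace=[], trained=True)
    for rep, child in enumerate(ss.spawn(cfg.n_repetitions)):
        rng = np.random.default_rng(child)
        member = copy.deepcopy(base)
        keep = max(1, int(round(len(X) * (1.0 - cfg.holdout_fraction))))
        subsample = rng.choice(len(X), size=keep, replace=False) if keep < len(X) else np.arange(len(X))
        trace = _train_member(member, X[subsample], cfg, rng, model.spec)
        out.members.append(member)
        out.loss_trace.append(trace)
    return out


def score_vectors(model: BganModel, X: np.ndarray, batch: int = 1024) -> np.ndarray:
    """Association scores sigmoid(D(x, E(x))) for pre-built feature vectors."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError("feature width does not match model input")
    scores = np.zeros(len(X))
    for start in range(0, len(X), batch):
        xb = X[start:start + batch]
        acc = np.zeros(len(xb))
        for member in model.members:
            ex = member.encoder.forward(xb, train=False)
            logit = member.discriminator.forward(np.hstack([xb, ex]), train=False)
            acc += sigmoid(logit).ravel()
        scores[start:start + len(xb)] = acc / len(model.members)
    return scores


def score_pairs(model: BganModel, features: PairFeatureSet) -> list[ScoredPair]:
    """Association score of every pair in the feature set.

    Score = mean over ensemble members of ``sigmoid(D(x, E(x)))``, dropout
    disabled; deterministic for a fixed model.
    """
    if features.n_features != model.spec.input_dim:
        raise ValueError(
            f"feature width {features.n_features} does not match model input "
            f"{model.spec.input_dim}"
        )
    pairs = features.pairs
    X, y = features.matrix(pairs)
    scores = score_vectors(model, X)
    mirnas = features.bm.mirna_index.names
    diseases = features.bm.disease_index.names
    return [
        ScoredPair(mirnas[i], diseases[j], float(s), int(label))
        for (i, j), s, label in zip(pairs, scores, y)
    ]


def save_model(model: BganModel, path) -> None:
    """Persist parameters to ``<path>`` (npz) with a JSON sidecar of the spec."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {}
    for mi, member in enumerate(model.members):
        for tag, net in (("E", member.encoder), ("G", member.generator),
                         ("D", member.discriminator)):
            for k, arr in enumerate(net.state()):
                arrays[f"m{mi}_{tag}_{k}"] = arr
    np.savez(path, **arrays)
    sidecar = {
        "spec": {
            "input_dim": model.spec.input_dim,
            "latent_dim": model.spec.latent_dim,
            "hidden_dims": list(model.spec.hidden_dims),
            "disc_hidden_dims": list(model.spec.disc_hidden_dims),
            "eta": model.spec.eta,
            "dropout": model.spec.dropout,
        },
        "n_members": len(model.members),
        "trained": model.trained,
        "loss_trace": model.loss_trace,
    }
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar))


def load_model(path) -> BganModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec_kwargs = dict(sidecar["spec"])
    spec_kwargs["hidden_dims"] = tuple(spec_kwargs["hidden_dims"])
    spec_kwargs["disc_hidden_dims"] = tuple(spec_kwargs["disc_hidden_dims"])
    spec = NetworkSpec(**spec_kwargs)
    data = np.load(path)
    model = BganModel(spec=spec, members=[], loss_trace=sidecar["loss_trace"],
                      trained=sidecar["trained"])
    for mi in range(sidecar["n_members"]):
        member = build_networks(spec, seed=0).members[0]
        for tag, net in (("E", member.encoder), ("G", member.generator),
                         ("D", member.discriminator)):
            n_arrays = 2 * len(net.layers)
            net.load_state([data[f"m{mi}_{tag}_{k}"] for k in range(n_arrays)])
        model.members.append(member)
    return model
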