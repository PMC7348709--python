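"""Fully connected sigmoid network grown by repeated structuring and learning.

The classifier is a small multilayer perceptron: 19 inputs, at most three
hidden layers of sigmoid units, one sigmoid output scoring AF membership in
(0, 1). Rather than fixing the architecture, the repeated structuring and
learning (RSL) procedure alternates

* a *learning* phase - full-batch scaled-conjugate-gradient training with
  validation-based early stopping, and
* a *structuring* phase - every single-neuron augmentation of the current
  ("primitive") architecture is generated under the constraints: at most
  three hidden layers, no layer wider than its predecessor, a new layer
  starts with one neuron. A candidate is *acceptable* only if some random
  initialisation of the new neuron lowers the validation loss after exactly
  one training epoch; acceptable candidates are trained fully and the best
  replaces the primitive if it improves the validation loss.

The search stops when no candidate is acceptable, when the primitive
survives ten consecutive structuring rounds, or when the primitive commits
no classification error on the training and validation sets (score
threshold 0.5). Because the whole construction depends on the random
initialisations, the outer loop restarts it from several seeds and keeps
the network with the smallest validation loss.

Classes are weighted inversely to prevalence in the cross-entropy loss, so
the rare AF class is not drowned by the non-AF majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .errors import ValidationError
from .scg import SCG

N_FEATURES = 19
MAX_HIDDEN_LAYERS = 3
_EPS = 1e-12


# ---------------------------------------------------------------------------
# architecture and model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Architecture:
    """Hidden-layer widths under the RSL constraints."""

    hidden_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.hidden_sizes)
        object.__setattr__(self, "hidden_sizes", sizes)
        if len(sizes) > MAX_HIDDEN_LAYERS:
            raise ValidationError(f"at most {MAX_HIDDEN_LAYERS} hidden layers")
        if any(s < 1 for s in sizes):
            raise ValidationError("layer sizes must be positive")
        for a, b in zip(sizes, sizes[1:]):
            if b > a:
                raise ValidationError(
                    "a layer may not be wider than its predecessor"
                )

    def layer_dims(self, n_inputs: int = N_FEATURES) -> list[tuple[int, int]]:
        """(n_out, n_in) for every weight matrix, output layer included."""
        widths = [n_inputs, *self.hidden_sizes, 1]
        return [(o, i) for i, o in zip(widths[:-1], widths[1:])]

    def n_params(self, n_inputs: int = N_FEATURES) -> int:
        return sum(o * i + o for o, i in self.layer_dims(n_inputs))


@dataclass
class NetworkModel:
    """Architecture plus concrete weights/biases (all layers sigmoid)."""

    architecture: Architecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    n_inputs: int = N_FEATURES
    seed: int | None = None

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            self.architecture,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.n_inputs,
            self.seed,
        )

    @property
    def n_params(self) -> int:
        return self.architecture.n_params(self.n_inputs)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    def from_vector(self, vec: np.ndarray) -> None:
        pos = 0
        for w in self.weights:
            w[...] = vec[pos : pos + w.size].reshape(w.shape)
            pos += w.size
        for b in self.biases:
            b[...] = vec[pos : pos + b.size]
            pos += b.size


def init_model(
    arch: Architecture,
    seed: int | np.random.Generator,
    n_inputs: int = N_FEATURES,
) -> NetworkModel:
    """All weights and biases i.i.d. uniform on [-1, 1] from the seeded RNG."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights, biases = [], []
    for o, i in arch.layer_dims(n_inputs):
        weights.append(rng.uniform(-1.0, 1.0, size=(o, i)))
        biases.append(rng.uniform(-1.0, 1.0, size=o))
    return NetworkModel(
        arch, weights, biases, n_inputs, seed if isinstance(seed, int) else None
    )


def forward(model: NetworkModel, features) -> np.ndarray | float:
    """Network score(s) in (0, 1); accepts one feature vector or a matrix."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.shape[1] != model.n_inputs:
        raise ValidationError(
            f"expected {model.n_inputs} features, got {a.shape[1]}"
        )
    for w, b in zip(model.weights, model.biases):
        a = expit(a @ w.T + b)
    out = a[:, 0]
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# loss and gradients
# ---------------------------------------------------------------------------


def class_weights(labels) -> dict[int, float]:
    """Inverse-prevalence weights w_c = N / (2 N_c); 1.0 on a balanced set."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValidationError("empty label set")
    out = {}
    for c in (0, 1):
        n_c = int(np.sum(y == c))
        out[c] = y.size / (2.0 * n_c) if n_c else 0.0
    return out


def weighted_loss(
    scores, labels, weights: dict[int, float] | None = None, loss: str = "cross_entropy"
) -> float:
    """Mean class-weighted loss of scores in (0,1) against 0/1 labels."""
    s = np.clip(np.asarray(scores, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    if s.size == 0:
        raise ValidationError("empty batch")
    if weights is None:
        weights = class_weights(y)
    w = np.where(y == 1, weights[1], weights[0])
    if loss == "cross_entropy":
        per = -(y * np.log(s) + (1.0 - y) * np.log(1.0 - s))
    elif loss == "squared_error":
        per = (s - y) ** 2
    else:
        raise ValidationError(f"unknown loss {loss!r}")
    return float(np.mean(w * per))


def _loss_and_grad(
    model: NetworkModel,
    vec: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    loss: str,
) -> tuple[float, np.ndarray]:
    """Full-batch loss and flattened gradient by backpropagation."""
    model.from_vector(vec)
    acts = [X]
    a = X
    for W, b in zip(model.weights, model.biases):
        a = expit(a @ W.T + b)
        acts.append(a)
    s = np.clip(acts[-1][:, 0], _EPS, 1.0 - _EPS)
    n = X.shape[0]
    if loss == "cross_entropy":
        f = float(np.mean(w * -(y * np.log(s) + (1 - y) * np.log(1 - s))))
        # d loss / d z_out for sigmoid + CE collapses to w (s - y) / n
        delta = (w * (s - y) / n)[:, None]
    else:
        f = float(np.mean(w * (s - y) ** 2))
        delta = (w * 2.0 * (s - y) * s * (1.0 - s) / n)[:, None]
    gw = [np.empty_like(W) for W in model.weights]
    gb = [np.empty_like(b) for b in model.biases]
    for layer in range(len(model.weights) - 1, -1, -1):
        gw[layer] = delta.T @ acts[layer]
        gb[layer] = delta.sum(axis=0)
        if layer > 0:
            a_prev = acts[layer]
            delta = (delta @ model.weights[layer]) * a_prev * (1.0 - a_prev)
    grad = np.concatenate([g.ravel() for g in gw] + [g.ravel() for g in gb])
    return f, grad


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Learning-phase settings (validation-based early stopping, SCG)."""

    max_epochs: int = 1000
    patience: int = 6
    loss: str = "cross_entropy"
    sigma0: float = 1e-4
    lambda0: float = 1e-6
    grad_tol: float = 1e-8
    screen_trials: int = 10
    confirm_limit: int = 10
    max_rounds: int = 25

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValidationError("patience must be at least 1")


@dataclass
class TrainResult:
    model: NetworkModel
    train_curve: list[float]
    validation_curve: list[float]
    stop_epoch: int
    best_epoch: int

    @property
    def validation_loss(self) -> float:
        return self.validation_curve[self.best_epoch]


def _as_sets(train, validation):
    Xtr, ytr = train
    Xva, yva = validation
    Xtr = np.asarray(Xtr, dtype=float)
    Xva = np.asarray(Xva, dtype=float)
    ytr = np.asarray(ytr, dtype=float)
    yva = np.asarray(yva, dtype=float)
    if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
        raise ValidationError("training and validation sets must be non-empty")
    return Xtr, ytr, Xva, yva


def _make_fun_grad(model, X, y, weights, loss):
    w = np.where(y == 1, weights[1], weights[0])
    scratch = model.copy()
    return lambda vec: _loss_and_grad(scratch, vec, X, y, w, loss)


def scg_train(
    model: NetworkModel,
    train: tuple,
    validation: tuple,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Full-batch SCG training with validation-based early stopping.

    Class weights are computed from training-set prevalence and applied to
    both the training objective and the monitored validation loss. Training
    stops when the validation loss has not improved for ``patience`` epochs
    (or at ``max_epochs``); the returned model carries the parameters of the
    best validation epoch.
    """
    config = config or TrainConfig()
    Xtr, ytr, Xva, yva = _as_sets(train, validation)
    cw = class_weights(ytr)
    fun_grad = _make_fun_grad(model, Xtr, ytr, cw, config.loss)
    opt = SCG(
        fun_grad,
        model.to_vector(),
        sigma0=config.sigma0,
        lambda0=config.lambda0,
        grad_tol=config.grad_tol,
    )

    def val_loss(vec: np.ndarray) -> float:
        model.from_vector(vec)
        return weighted_loss(forward(model, Xva), yva, cw, config.loss)

    train_curve = [opt.f]
    val_curve = [val_loss(opt.x)]
    best_epoch = 0
    best_vec = opt.x.copy()
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        f = opt.step()
        train_curve.append(f)
        vl = val_loss(opt.x)
        val_curve.append(vl)
        if vl < val_curve[best_epoch]:
            best_epoch = epoch
            best_vec = opt.x.copy()
        if epoch - best_epoch >= config.patience:
            break
        if opt.converged:
            break
    model.from_vector(best_vec)
    return TrainResult(model, train_curve, val_curve, epoch, best_epoch)


def _one_epoch_validation_loss(
    model: NetworkModel, train: tuple, validation: tuple, config: TrainConfig
) -> float:
    """Validation loss after exactly one SCG epoch (the screening probe)."""
    Xtr, ytr, Xva, yva = _as_sets(train, validation)
    cw = class_weights(ytr)
    fun_grad = _make_fun_grad(model, Xtr, ytr, cw, config.loss)
    opt = SCG(fun_grad, model.to_vector(), sigma0=config.sigma0, lambda0=config.lambda0)
    opt.step()
    probe = model.copy()
    probe.from_vector(opt.x)
    return weighted_loss(forward(probe, Xva), yva, cw, config.loss)


# ---------------------------------------------------------------------------
# structuring
# ---------------------------------------------------------------------------


def enumerate_alternatives(arch: Architecture) -> list[Architecture]:
    """Every legal single-neuron augmentation of ``arch``.

    A neuron may be added to an existing layer (if it stays no wider than
    its predecessor) or open a new layer of size one, up to three layers.
    """
    sizes = arch.hidden_sizes
    out: list[Architecture] = []
    for k in range(len(sizes)):
        grown = list(sizes)
        grown[k] += 1
        if k == 0 or grown[k] <= grown[k - 1]:
            out.append(Architecture(tuple(grown)))
    if len(sizes) < MAX_HIDDEN_LAYERS:
        out.append(Architecture((*sizes, 1)))
    return out


def _grow_model(
    primitive: NetworkModel, candidate: Architecture, rng: np.random.Generator
) -> NetworkModel:
    """Copy shape-preserved parameters; draw the new neuron's from U[-1, 1]."""
    new = init_model(candidate, rng, primitive.n_inputs)
    if len(candidate.hidden_sizes) > len(primitive.architecture.hidden_sizes):
        # a new hidden layer opened before the output: copy the untouched
        # hidden layers and the output bias; the new layer's parameters and
        # the re-shaped output weights keep their drawn values
        for layer in range(len(primitive.weights) - 1):
            new.weights[layer][...] = primitive.weights[layer]
            new.biases[layer][...] = primitive.biases[layer]
        new.biases[-1][...] = primitive.biases[-1]
        return new
    for layer, (w_old, b_old) in enumerate(zip(primitive.weights, primitive.biases)):
        w_new, b_new = new.weights[layer], new.biases[layer]
        if w_old.shape == w_new.shape:
            w_new[...] = w_old
        elif w_old.shape[1] == w_new.shape[1]:  # same inputs, one extra unit
            w_new[: w_old.shape[0], :] = w_old
        else:  # same units, one extra input from the grown layer below
            w_new[:, : w_old.shape[1]] = w_old
        if b_old.shape == b_new.shape:
            b_new[...] = b_old
        else:
            b_new[: b_old.size] = b_old
    return new


@dataclass
class CandidateRecord:
    architecture: Architecture
    accepted: bool
    trials_used: int
    screen_loss: float | None = None
    validation_loss: float | None = None
    misclassification: float | None = None


@dataclass
class SearchRound:
    index: int
    primitive: Architecture
    primitive_loss: float
    candidates: list[CandidateRecord] = field(default_factory=list)
    decision: str = ""


@dataclass
class SearchLog:
    seed: int
    rounds: list[SearchRound] = field(default_factory=list)
    stop_reason: str = ""
    final_architecture: Architecture | None = None
    final_validation_loss: float = np.inf

    def architectures_visited(self) -> list[Architecture]:
        seen = [r.primitive for r in self.rounds]
        seen += [c.architecture for r in self.rounds for c in r.candidates]
        return seen


def screen_candidate(
    candidate: Architecture,
    primitive: NetworkModel,
    primitive_loss: float,
    train: tuple,
    validation: tuple,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[NetworkModel | None, int, float | None]:
    """One-epoch acceptability screen for a candidate architecture.

    Up to ``config.screen_trials`` random initialisations of the new
    neuron's parameters are probed; the first whose validation loss after
    exactly one SCG epoch falls strictly below the primitive's current
    validation loss is accepted (the drawn initialisation, not the probe
    state, is returned for full training). Returns
    ``(model or None, trials used, best probe loss)``.
    """
    best_probe = None
    for trial in range(1, config.screen_trials + 1):
        drawn = _grow_model(primitive, candidate, rng)
        probe_loss = _one_epoch_validation_loss(drawn.copy(), train, validation, config)
        if best_probe is None or probe_loss < best_probe:
            best_probe = probe_loss
        if probe_loss < primitive_loss:
            return drawn, trial, best_probe
    return None, config.screen_trials, best_probe


def _misclassification(model: NetworkModel, X: np.ndarray, y: np.ndarray) -> int:
    pred = (np.asarray(forward(model, X)) >= 0.5).astype(int)
    return int(np.sum(pred != y.astype(int)))


def rsl_construct(
    train: tuple,
    validation: tuple,
    config: TrainConfig | None = None,
    seed: int = 0,
    n_inputs: int = N_FEATURES,
) -> tuple[NetworkModel, SearchLog]:
    """Grow and train a network by repeated structuring and learning."""
    config = config or TrainConfig()
    Xtr, ytr, Xva, yva = _as_sets(train, validation)
    rng = np.random.default_rng(seed)

    primitive = init_model(Architecture((1,)), rng, n_inputs)
    primitive.seed = seed
    result = scg_train(primitive, (Xtr, ytr), (Xva, yva), config)
    primitive, prim_loss = result.model, result.validation_loss

    log = SearchLog(seed=seed)
    confirmations = 0
    for round_idx in range(1, config.max_rounds + 1):
        rnd = SearchRound(round_idx, primitive.architecture, prim_loss)
        log.rounds.append(rnd)

        if (
            _misclassification(primitive, Xtr, ytr) == 0
            and _misclassification(primitive, Xva, yva) == 0
        ):
            rnd.decision = "stop"
            log.stop_reason = "zero_misclassification"
            break

        trained: list[tuple[float, NetworkModel]] = []
        for cand in enumerate_alternatives(primitive.architecture):
            drawn, trials, probe = screen_candidate(
                cand, primitive, prim_loss, (Xtr, ytr), (Xva, yva), config, rng
            )
            rec = CandidateRecord(cand, drawn is not None, trials, probe)
            rnd.candidates.append(rec)
            if drawn is None:
                continue
            res = scg_train(drawn, (Xtr, ytr), (Xva, yva), config)
            rec.validation_loss = res.validation_loss
            rec.misclassification = _misclassification(res.model, Xva, yva) / yva.size
            trained.append((res.validation_loss, res.model))

        if not trained:
            rnd.decision = "stop"
            log.stop_reason = "no_acceptable_alternatives"
            break

        best_loss, best_model = min(trained, key=lambda t: t[0])
        if best_loss < prim_loss:
            primitive, prim_loss = best_model, best_loss
            confirmations = 0
            rnd.decision = f"adopt {best_model.architecture.hidden_sizes}"
        else:
            confirmations += 1
            rnd.decision = f"confirm ({confirmations})"
            if confirmations >= config.confirm_limit:
                log.stop_reason = "primitive_confirmed"
                break
    else:
        log.stop_reason = "max_rounds"

    log.final_architecture = primitive.architecture
    log.final_validation_loss = prim_loss
    return primitive, log


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n distinct child seeds below 2**31 from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    seeds: list[int] = []
    state = ss.generate_state(4 * n + 16) % (2**31)
    for s in state:
        if int(s) not in seeds:
            seeds.append(int(s))
        if len(seeds) == n:
            break
    while len(seeds) < n:  # pragma: no cover - astronomically unlikely
        seeds.append((seeds[-1] + 1) % 2**31)
    return seeds


def multi_restart(
    train: tuple,
    validation: tuple,
    config: TrainConfig | None = None,
    n_restarts: int = 100,
    seed: int = 0,
    n_inputs: int = N_FEATURES,
) -> tuple[NetworkModel, list[SearchLog]]:
    """Repeat the construction from independent seeds; keep the best.

    The winner has the smallest validation loss; ties are broken by smaller
    parameter count, then by the lower restart seed.
    """
    if n_restarts < 1:
        raise ValidationError("need at least one restart")
    config = config or TrainConfig()
    logs: list[SearchLog] = []
    best: tuple[float, int, int, NetworkModel] | None = None
    for child_seed in derive_seeds(seed, n_restarts):
        model, log = rsl_construct(train, validation, config, child_seed, n_inputs)
        logs.append(log)
        key = (log.final_validation_loss, model.n_params, child_seed)
        if best is None or key < best[:3]:
            best = (*key, model)
    return best[3], logs
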