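"""Training loop, checkpointing, model selection and ensembling.

The standard protocol trains each network with Adam, saving a checkpoint
every 500 epochs up to 20,000 epochs.  For each of ten random 100/35
train/test splits several model replicates are trained; the checkpoint
with the best combination of R^2 and regression slope on the test set is
kept per split, and the final predictor is the ensemble average of the
per-split best models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..metrics import RegressionReport, regression_metrics
from .autodiff import Adam, Tensor
from .layers import Network
from .losses import combined_loss

DEFAULT_MAX_EPOCHS = 20_000
DEFAULT_CHECKPOINT_INTERVAL = 500


@dataclass
class TrainConfig:
    """Training settings.

    Defaults follow the standard protocol: Adam, learning rate 1e-4
    (1e-5 for sequence models), batch size 4, or the full training batch
    when the moment-KL term is active (the KL moments are then computed
    over the complete training set).
    """

    learning_rate: float = 1e-4
    max_epochs: int = DEFAULT_MAX_EPOCHS
    checkpoint_interval: int = DEFAULT_CHECKPOINT_INTERVAL
    batch_size: int = 4
    kl_loss: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.max_epochs % self.checkpoint_interval != 0:
            raise ValueError("checkpoint interval must divide max epochs")


@dataclass
class Checkpoint:
    epoch: int
    weights: list[np.ndarray]
    train_loss: float
    test_report: RegressionReport | None = None


@dataclass
class TrainResult:
    checkpoints: list[Checkpoint]
    loss_trajectory: list[float] = field(default_factory=list)


def train_with_checkpoints(model: Network, X: np.ndarray, y: np.ndarray,
                           config: TrainConfig,
                           X_test: np.ndarray | None = None,
                           y_test: np.ndarray | None = None) -> TrainResult:
    """Train ``model`` and return one checkpoint per interval.

    ``X`` may be a 2-D feature matrix or the 3-D one-hot stack for the
    sequence net.  With ``config.kl_loss`` the batch is the whole training
    set; otherwise mini-batches of ``config.batch_size`` are drawn in a
    shuffled order each epoch.  Divergent (non-finite) loss aborts with
    the epoch reported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValueError(f"label count {y.size} does not match {n} samples")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(trainable_only=True), lr=config.learning_rate)
    batch = n if config.kl_loss else min(config.batch_size, n)

    checkpoints: list[Checkpoint] = []
    trajectory: list[float] = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            yb = Tensor.const(y[idx].reshape(-1, 1))
            pred = model.forward(X[idx])
            loss = combined_loss(yb, pred, kl=config.kl_loss and idx.size >= 2)
            if not np.isfinite(loss.value):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value)
            n_batches += 1
        trajectory.append(epoch_loss / n_batches)
        if epoch % config.checkpoint_interval == 0:
            report = None
            if X_test is not None and y_test is not None:
                try:
                    report = regression_metrics(y_test, model.predict(X_test))
                except ValueError:
                    report = None
            checkpoints.append(Checkpoint(epoch=epoch, weights=model.get_weights(),
                                          train_loss=trajectory[-1],
                                          test_report=report))
    return TrainResult(checkpoints=checkpoints, loss_trajectory=trajectory)


def selection_score(report: RegressionReport) -> float:
    """Monotone combination of fit quality and calibration: R^2 - |slope - 1|."""
    return report.r2 - abs(report.slope - 1.0)


def select_best_checkpoint(model: Network, checkpoints: list[Checkpoint],
                           X_test: np.ndarray, y_test: np.ndarray,
                           score=selection_score) -> Checkpoint:
    """Pick the checkpoint maximising ``score`` on the test set.

    Ties are broken by the earliest epoch.  The model is left loaded with
    the winning weights.
    """
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    best: Checkpoint | None = None
    best_score = -np.inf
    for ckpt in checkpoints:
        model.set_weights(ckpt.weights)
        report = regression_metrics(y_test, model.predict(X_test))
        s = score(report)
        if s > best_score:
            best, best_score = replace(ckpt, test_report=report), s
    assert best is not None
    model.set_weights(best.weights)
    return best


class Ensemble:
    """Arithmetic-mean ensemble of trained networks."""

    def __init__(self, members: list[Network]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members])
        return preds.mean(axis=0)


@dataclass(frozen=True)
class EnsembleProtocol:
    """Split/replicate settings for the ensemble training protocol."""

    n_sets: int = 10
    train_size: int = 100
    test_size: int = 35
    models_per_set: int = 10


def make_splits(n: int, protocol: EnsembleProtocol,
                rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/test partitions of ``n`` samples (train+test = n)."""
    if protocol.train_size + protocol.test_size != n:
        raise ValueError(
            f"train {protocol.train_size} + test {protocol.test_size} must equal n={n}"
        )
    splits = []
    for _ in range(protocol.n_sets):
        perm = rng.permutation(n)
        splits.append((perm[:protocol.train_size], perm[protocol.train_size:]))
    return splits


@dataclass
class EnsembleResult:
    ensemble: Ensemble
    per_set_best: list[Checkpoint]
    per_set_test_report: list[RegressionReport]
    splits: list[tuple[np.ndarray, np.ndarray]]

    @property
    def mean_test_r2(self) -> float:
        return float(np.mean([r.r2 for r in self.per_set_test_report]))


def train_ensemble(build_model, X: np.ndarray, y: np.ndarray,
                   config: TrainConfig, protocol: EnsembleProtocol,
                   seed: int = 0) -> EnsembleResult:
    """Run the split/replicate/select/ensemble protocol.

    ``build_model(rng)`` constructs a fresh network.  For each split,
    ``protocol.models_per_set`` replicates are trained from different
    initialisations; the best checkpoint (R^2/slope score on the split's
    test set) across replicates becomes the split's member model.
    """
    rng = np.random.default_rng(seed)
    splits = make_splits(X.shape[0], protocol, rng)
    members: list[Network] = []
    per_set_best: list[Checkpoint] = []
    per_set_report: list[RegressionReport] = []
    for split_i, (train_idx, test_idx) in enumerate(splits):
        best_ckpt = None
        best_model = None
        best_score = -np.inf
        for rep in range(protocol.models_per_set):
            model_rng = np.random.default_rng(rng.integers(2**31))
            model = build_model(model_rng)
            rep_config = replace(config, seed=int(rng.integers(2**31)))
            result = train_with_checkpoints(model, X[train_idx], y[train_idx],
                                            rep_config)
            ckpt = select_best_checkpoint(model, result.checkpoints,
                                          X[test_idx], y[test_idx])
            s = selection_score(ckpt.test_report)
            if s > best_score:
                best_ckpt, best_model, best_score = ckpt, model, s
        best_model.set_weights(best_ckpt.weights)
        members.append(best_model)
        per_set_best.append(best_ckpt)
        per_set_report.append(best_ckpt.test_report)
    return EnsembleResult(ensemble=Ensemble(members), per_set_best=per_set_best,
                          per_set_test_report=per_set_report, splits=splits)
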