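"""Sequential network container, Adam, early stopping, checkpoints."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from whistlekit.nn.layers import Layer, Softmax, softmax_cross_entropy


@dataclass
class TrainingConfig:
    """How a detector is trained.

    Loss is cross-entropy over the 2-way softmax (the binary
    cross-entropy of the positive-class probability, written over
    one-hot targets); optimizer is Adam at ``learning_rate``.  Early
    stopping watches validation loss with the given patience and
    restores the best weights.
    """

    learning_rate: float = 1e-4
    max_epochs: int = 200
    batch_size: int = 32
    early_stopping_patience: int = 15
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class Adam:
    """Adam with the usual defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's loss; return True if training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


class Sequential:
    """An ordered stack of layers ending in a softmax head.

    Training runs on the logits (the softmax is fused into the loss);
    inference applies the softmax.  All randomness — weight init,
    shuffling, dropout — derives from the seed passed to ``build``/
    ``fit``, so identical seeds give identical models.
    """

    def __init__(self, layers: list[Layer]) -> None:
        if not layers:
            raise ValueError("need at least one layer")
        self.layers = layers
        self._has_softmax_head = isinstance(layers[-1], Softmax)
        self.built = False

    # -- construction -------------------------------------------------

    def build(self, input_shape: tuple, seed: int = 0) -> "Sequential":
        rng = np.random.default_rng(seed)
        shape = tuple(input_shape)
        for layer in self.layers:
            shape = layer.build(shape, rng)
        self.input_shape = tuple(input_shape)
        self.output_shape = shape
        self.built = True
        return self

    @property
    def trainable_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params and l.trainable]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for l in self.layers for p in l.params]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            p[...] = w

    # -- forward / backward -------------------------------------------

    def _forward(self, x: np.ndarray, training: bool, rng: np.random.Generator,
                 stop_before_softmax: bool) -> np.ndarray:
        layers = self.layers[:-1] if (stop_before_softmax and self._has_softmax_head) else self.layers
        out = x.astype(np.float32, copy=False)
        for layer in layers:
            out = layer.forward(out, training, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities, shape (n, n_classes)."""
        if not self.built:
            raise RuntimeError("model not built")
        rng = np.random.default_rng(0)  # unused in inference
        outs = [
            self._forward(x[i : i + batch_size], False, rng, stop_before_softmax=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def _train_batch(self, xb: np.ndarray, yb: np.ndarray, optimizer: Adam,
                     rng: np.random.Generator) -> tuple[float, int]:
        logits = self._forward(xb, True, rng, stop_before_softmax=True)
        loss, grad = softmax_cross_entropy(logits, yb)
        correct = int((logits.argmax(axis=1) == yb.argmax(axis=1)).sum())
        layers = self.layers[:-1] if self._has_softmax_head else self.layers
        for layer in reversed(layers):
            grad = layer.backward(grad)
        params = [p for l in self.trainable_layers for p in l.params]
        grads = [g for l in self.trainable_layers for g in l.grads]
        optimizer.step(params, grads)
        return loss, correct

    def evaluate_loss(self, x: np.ndarray, y_onehot: np.ndarray,
                      batch_size: int = 64) -> float:
        rng = np.random.default_rng(0)
        total, n = 0.0, len(x)
        for i in range(0, n, batch_size):
            logits = self._forward(x[i : i + batch_size], False, rng, True)
            loss, _ = softmax_cross_entropy(logits, y_onehot[i : i + batch_size])
            total += loss * len(logits)
        return total / n

    # -- training loop -------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        cfg: TrainingConfig,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        verbose: bool = False,
    ) -> dict:
        """Train with Adam, shuffled mini-batches and early stopping.

        ``y`` holds integer class labels.  If no validation set is
        given, ``validation_fraction`` of the data is held out
        (shuffled split, deterministic per seed).  The best-validation
        weights are restored at the end.  Returns a history dict with
        per-epoch train/val loss and accuracy and the stopping epoch.
        """
        if not self.built:
            raise RuntimeError("model not built; call build(input_shape, seed)")
        if len(x) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(cfg.seed + 1)
        n_classes = self.output_shape[-1]
        y = np.asarray(y, dtype=np.int64)

        if validation_data is None and cfg.validation_fraction > 0 and len(x) >= 5:
            idx = rng.permutation(len(x))
            n_val = max(1, int(round(cfg.validation_fraction * len(x))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            validation_data = (x[val_idx], y[val_idx])
            x, y = x[tr_idx], y[tr_idx]

        onehot = np.eye(n_classes, dtype=np.float32)[y]
        if validation_data is not None:
            xv, yv = validation_data
            yv = np.asarray(yv, dtype=np.int64)
            yv_onehot = np.eye(n_classes, dtype=np.float32)[yv]

        optimizer = Adam(cfg.learning_rate)
        stopper = EarlyStopping(cfg.early_stopping_patience)
        history: dict = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
        best_weights = self.get_weights()

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(x))
            epoch_loss, epoch_correct, seen = 0.0, 0, 0
            for i in range(0, len(x), cfg.batch_size):
                b = order[i : i + cfg.batch_size]
                loss, correct = self._train_batch(x[b], onehot[b], optimizer, rng)
                epoch_loss += loss * len(b)
                epoch_correct += correct
                seen += len(b)
            # running metrics over the epoch's batches (pre-update logits)
            history["train_loss"].append(epoch_loss / seen)
            history["train_acc"].append(epoch_correct / seen)

            if validation_data is not None:
                vloss = self.evaluate_loss(xv, yv_onehot)
                vpred = self.predict_proba(xv).argmax(axis=1)
                history["val_loss"].append(vloss)
                history["val_acc"].append(float((vpred == yv).mean()))
                monitored = vloss
            else:
                monitored = history["train_loss"][-1]

            if verbose:
                print(
                    f"epoch {epoch}: loss={history['train_loss'][-1]:.4f} "
                    f"acc={history['train_acc'][-1]:.3f}"
                    + (f" val_loss={monitored:.4f}" if validation_data is not None else "")
                )
            improved = monitored < stopper.best
            stop = stopper.update(monitored, epoch)
            if improved:
                best_weights = self.get_weights()
            if stop:
                break

        self.set_weights(best_weights)
        history["stopped_epoch"] = epoch
        history["best_epoch"] = stopper.best_epoch
        return history

    # -- persistence ---------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Save weights (npz) plus a JSON architecture manifest."""
        path = os.fspath(path)
        np.savez(path, *[p for l in self.layers for p in l.params])
        manifest = {
            "input_shape": list(self.input_shape),
            "layers": [type(l).__name__ for l in self.layers],
            "n_params": int(self.n_params),
        }
        with open(path + ".json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    def load_weights(self, path: str | os.PathLike) -> None:
        data = np.load(os.fspath(path))
        keys = sorted(data.files, key=lambda k: int(k.split("_")[-1]))
        self.set_weights([data[k] for k in keys])
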