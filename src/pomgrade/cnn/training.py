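"""Training loop (cross-entropy + Adam) and finite-difference verification.

Defaults mirror the reference training regime: learning rate 1e-4, batch
size 20, 3001 optimizer steps, 208x208x3 inputs scaled to [0, 1]. Training
is fully deterministic for a fixed seed (single-threaded NumPy kernels; BLAS
reductions are the only potential source of run-to-run variation and are
deterministic for a fixed thread count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..sample import ImageSample
from .arch import ArchitectureSpec
from .network import Network, Params


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 20
    max_steps: int = 3001
    input_size: int = 208
    seed: int = 0
    eval_every: int = 100          # validation cadence, in steps
    val_subset: Optional[int] = 500  # cap on images per validation pass
    stop_above_train_acc: Optional[float] = None  # early stop on the running
    # mean of the last 20 batch accuracies; None trains for max_steps
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.max_steps < 1:
            raise ValueError("batch_size and max_steps must be >= 1")


def samples_to_arrays(samples: Sequence[ImageSample], input_size: int
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Stack samples into (X in [0,1] float64 NHWC, integer labels)."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    xs, ys = [], []
    for s in samples:
        if s.pixels.shape[:2] != (input_size, input_size):
            raise ValueError(
                f"sample has shape {s.pixels.shape[:2]}, expected "
                f"({input_size}, {input_size}); resize upstream")
        xs.append(s.pixels.astype(np.float64) / 255.0)
        ys.append(s.label.code)
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


class Adam:
    """Standard Adam with bias correction, one slot pair per parameter."""

    def __init__(self, params: Params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: {n: np.zeros_like(v) for n, v in p.items()}
                  for k, p in params.items()}
        self.v = {k: {n: np.zeros_like(v) for n, v in p.items()}
                  for k, p in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            for n in p:
                g = grads[k][n]
                self.m[k][n] = self.b1 * self.m[k][n] + (1 - self.b1) * g
                self.v[k][n] = self.b2 * self.v[k][n] + (1 - self.b2) * g * g
                mhat = self.m[k][n] / bc1
                vhat = self.v[k][n] / bc2
                p[n] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _accuracy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(probs.argmax(axis=1) == y))


def evaluate_network(net: Network, x: np.ndarray, y: np.ndarray,
                     batch_size: int = 50) -> Tuple[float, float]:
    """(accuracy, mean cross-entropy) over a fixed array set."""
    n = x.shape[0]
    correct, loss_sum = 0, 0.0
    for i in range(0, n, batch_size):
        probs = net.forward(x[i:i + batch_size])
        yy = y[i:i + batch_size]
        correct += int((probs.argmax(axis=1) == yy).sum())
        loss_sum += float(-np.log(probs[np.arange(len(yy)), yy] + 1e-12).sum())
    return correct / n, loss_sum / n


def train(arch: ArchitectureSpec,
          train_samples: Sequence[ImageSample],
          val_samples: Sequence[ImageSample],
          config: TrainConfig,
          checkpoint_path: Optional[str] = None,
          ) -> Tuple[Network, pd.DataFrame]:
    """Train the network; returns (trained network, per-step curve table).

    The curve table has columns (step, train_acc, train_loss, val_acc,
    val_loss); validation columns are NaN except at ``eval_every``
    checkpoints and the final step. Raises RuntimeError naming the step if
    the loss diverges to a non-finite value.
    """
    config.validate()
    if len(train_samples) == 0 or len(val_samples) == 0:
        raise ValueError("train and validation sets must be non-empty")
    x_tr, y_tr = samples_to_arrays(train_samples, config.input_size)
    x_va, y_va = samples_to_arrays(val_samples, config.input_size)
    rng = np.random.default_rng(config.seed)
    if config.val_subset is not None and len(y_va) > config.val_subset:
        keep = rng.choice(len(y_va), size=config.val_subset, replace=False)
        x_va, y_va = x_va[keep], y_va[keep]

    net = Network(arch, seed=config.seed)
    opt = Adam(net.params, config.learning_rate,
               config.adam_beta1, config.adam_beta2, config.adam_eps)
    rows: List[Dict] = []
    recent: List[float] = []
    for step in range(config.max_steps):
        idx = rng.choice(len(y_tr), size=min(config.batch_size, len(y_tr)),
                         replace=False)
        try:
            loss, grads, probs = net.loss_and_grads(x_tr[idx], y_tr[idx])
        except FloatingPointError as e:
            raise RuntimeError(f"training diverged at step {step}: {e}") from e
        opt.step(net.params, grads)
        acc = _accuracy(probs, y_tr[idx])
        recent.append(acc)
        if len(recent) > 20:
            recent.pop(0)
        row = dict(step=step, train_acc=acc, train_loss=loss,
                   val_acc=np.nan, val_loss=np.nan)
        stop = (config.stop_above_train_acc is not None
                and len(recent) == 20
                and float(np.mean(recent)) > config.stop_above_train_acc)
        if step % config.eval_every == 0 or step == config.max_steps - 1 or stop:
            va, vl = evaluate_network(net, x_va, y_va)
            row["val_acc"], row["val_loss"] = va, vl
        rows.append(row)
        if stop:
            break
    curves = pd.DataFrame(rows)
    if checkpoint_path is not None:
        net.save(checkpoint_path)
    return net, curves


def gradient_check(net: Network, x: np.ndarray, y: np.ndarray,
                   epsilon: float = 1e-5, max_checks_per_tensor: int = 0
                   ) -> float:
    """Max relative deviation between analytic and central-difference grads.

    Intended for tiny networks (<= a few thousand parameters). With
    ``max_checks_per_tensor`` > 0, only that many deterministically chosen
    entries per tensor are probed. Relative deviation is
    |a - n| / max(|a| + |n|, 1e-8).
    """
    if not 1e-6 <= epsilon <= 1e-3:
        raise ValueError("epsilon must be in [1e-6, 1e-3]")
    _, grads, _ = net.loss_and_grads(x, y)
    worst = 0.0
    for lname, p in net.params.items():
        for pname, tensor in p.items():
            flat = tensor.reshape(-1)
            n_entries = flat.size
            if max_checks_per_tensor and n_entries > max_checks_per_tensor:
                probe = np.linspace(0, n_entries - 1, max_checks_per_tensor,
                                    dtype=int)
            else:
                probe = np.arange(n_entries)
            analytic = grads[lname][pname].reshape(-1)
            for i in probe:
                orig = flat[i]
                flat[i] = orig + epsilon
                lp, _, _ = net.loss_and_grads(x, y)
                flat[i] = orig - epsilon
                lm, _, _ = net.loss_and_grads(x, y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * epsilon)
                denom = max(abs(analytic[i]) + abs(numeric), 1e-8)
                worst = max(worst, abs(analytic[i] - numeric) / denom)
    return worst
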