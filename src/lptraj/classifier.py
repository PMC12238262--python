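"""Dilated-convolution trajectory classifier and weighted-F1 evaluation.

The classifier assigns a diffusion class (Brownian motion, the five
anomalous benchmark processes, and the liquid-cell class) to a fixed-length
trajectory.  It consumes the lag-1 displacement series of a *normalized*
trajectory — diffusion class is a property of the increments — through
three parallel convolution stacks with dilation rates 1, 2 and 4 (so the
receptive fields span short-, mid- and long-range temporal correlations),
pools each branch over a coarse temporal grid (preserving the slow
variance modulation that separates ageing processes), and maps the
concatenation through a 128-unit dense layer — the feature layer whose
activations feed the Fréchet-distance evaluation — onto class logits.

`weighted_f1` implements one-vs-rest precision/recall/F1 per class with
class-frequency weights, the standard multi-class summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabeledTrajectoryDataset
from .nn import Adam, Conv1d, Linear, Module, Tensor, concatenate

__all__ = ["ClassifierConfig", "TrajectoryClassifier", "F1Report",
           "train_classifier", "classify", "extract_features", "weighted_f1"]

FEATURE_DIM = 128


@dataclass(frozen=True)
class ClassifierConfig:
    T: int = 200
    n_filters: int = 32
    kernel_size: int = 5
    dilations: tuple[int, ...] = (1, 2, 4)
    n_pool_segments: int = 8
    feature_dim: int = FEATURE_DIM
    epochs: int = 12
    batch_size: int = 128
    learning_rate: float = 1e-3
    val_frac: float = 0.1
    seed: int = 0


@dataclass(frozen=True)
class F1Report:
    """Per-class one-vs-rest precision/recall/F1 and the weighted summary."""

    classes: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    counts: dict[str, int]
    weights: dict[str, float]
    weighted_f1: float


class TrajectoryClassifier(Module):
    def __init__(self, config: ClassifierConfig, classes: tuple[str, ...]):
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        self.config = config
        self.classes = tuple(classes)
        rng = np.random.default_rng(config.seed)
        F, K = config.n_filters, config.kernel_size
        self.branches = []
        for d in config.dilations:
            pad = d * (K - 1) // 2
            self.branches.append([
                Conv1d(2, F, K, rng, dilation=d, padding=pad),
                Conv1d(F, F, K, rng, dilation=d, padding=pad),
            ])
        pooled = len(config.dilations) * F * config.n_pool_segments
        self.fc_feat = Linear(pooled, config.feature_dim, rng)
        self.fc_out = Linear(config.feature_dim, len(self.classes), rng)

    def _displacements(self, pos: np.ndarray) -> np.ndarray:
        return np.diff(pos, axis=-1)

    def features_tensor(self, x: Tensor) -> Tensor:
        """(B, 2, T-1) displacement batch -> (B, feature_dim) activations."""
        B = x.shape[0]
        outs = []
        for conv1, conv2 in self.branches:
            h = conv2(conv1(x).relu()).relu()       # (B, F, L)
            outs.append(h)
        h = concatenate(outs, axis=1)               # (B, 3F, L)
        L = h.shape[-1]
        S = self.config.n_pool_segments
        seg = L // S
        h = h[:, :, :seg * S].reshape(B, h.shape[1], S, seg).mean(axis=-1)
        h = h.reshape(B, h.shape[1] * S)
        return self.fc_feat(h).relu()

    def forward(self, x: Tensor) -> Tensor:
        return self.fc_out(self.features_tensor(x))


def _check_batch(clf: TrajectoryClassifier, batch) -> np.ndarray:
    if isinstance(batch, LabeledTrajectoryDataset):
        pos = batch.positions()
    else:
        pos = np.asarray(batch, dtype=float)
        if pos.ndim == 2:
            pos = pos[None]
    if pos.shape[-1] != clf.config.T:
        raise ValueError(f"trajectory length {pos.shape[-1]} != classifier T "
                         f"{clf.config.T}")
    return pos


def train_classifier(dataset: LabeledTrajectoryDataset,
                     config: ClassifierConfig | None = None, *,
                     seed: int | None = None, verbose: bool = False,
                     ) -> tuple[TrajectoryClassifier, list[dict[str, float]]]:
    """Train on a labeled dataset with a stratified 90/10 validation split.

    Cross-entropy objective, Adam, fully seeded; returns the classifier and
    a per-epoch history of training loss and validation accuracy.
    """
    config = config or ClassifierConfig()
    if seed is not None:
        config = ClassifierConfig(**{**config.__dict__, "seed": seed})
    classes = tuple(sorted(set(dataset.labels)))
    if len(classes) < 2:
        raise ValueError("dataset must contain at least two classes")
    if dataset.T != config.T:
        raise ValueError("dataset trajectory length != config.T")
    clf = TrajectoryClassifier(config, classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_index[lab] for lab in dataset.labels])
    x = np.diff(dataset.positions(), axis=-1)

    rng = np.random.default_rng(config.seed + 1)
    # stratified split
    val_mask = np.zeros(len(y), dtype=bool)
    for c in range(len(classes)):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(config.val_frac * len(idx)))) if len(idx) > 1 else 0
        val_mask[idx[:n_val]] = True
    x_tr, y_tr = x[~val_mask], y[~val_mask]
    x_va, y_va = x[val_mask], y[val_mask]

    opt = Adam(clf.parameters(), lr=config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(y_tr))
        tot_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = clf(Tensor(x_tr[idx]))
            loss = _cross_entropy(logits, y_tr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += loss.item()
            n_batches += 1
        row = {"epoch": epoch, "train_loss": tot_loss / max(1, n_batches)}
        if len(y_va):
            pred = _predict_labels(clf, x_va)
            row["val_accuracy"] = float(np.mean(pred == y_va))
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: loss {row['train_loss']:.4f} "
                  f"val acc {row.get('val_accuracy', float('nan')):.3f}")
    return clf, history


def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    logp = _log_softmax(logits)
    picked = logp.take_along_last(y[:, None])
    return -picked.mean()


def _log_softmax(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    return shifted - shifted.exp().sum(axis=-1, keepdims=True).log()


def _predict_labels(clf: TrajectoryClassifier, x: np.ndarray,
                    batch: int = 512) -> np.ndarray:
    out = []
    for start in range(0, len(x), batch):
        logits = clf(Tensor(x[start:start + batch]))
        out.append(np.argmax(logits.data, axis=-1))
    return np.concatenate(out) if out else np.array([], dtype=int)


def classify(clf: TrajectoryClassifier, batch,
             batch_size: int = 512) -> tuple[np.ndarray, list[str]]:
    """Class probabilities (n, n_classes) and argmax labels for a batch.

    Probabilities are a valid simplex per trajectory; ties in the argmax
    resolve to the first class in ``clf.classes`` enumeration order.
    """
    pos = _check_batch(clf, batch)
    x = np.diff(pos, axis=-1)
    probs = []
    for start in range(0, len(x), batch_size):
        logits = clf(Tensor(x[start:start + batch_size])).data
        p = np.exp(logits - logits.max(axis=-1, keepdims=True))
        probs.append(p / p.sum(axis=-1, keepdims=True))
    probs = np.concatenate(probs) if probs else np.empty((0, len(clf.classes)))
    labels = [clf.classes[i] for i in np.argmax(probs, axis=-1)]
    return probs, labels


def extract_features(clf: TrajectoryClassifier, batch,
                     batch_size: int = 512) -> np.ndarray:
    """(n, 128) penultimate-layer activations — the inputs to the
    Fréchet-distance comparison."""
    pos = _check_batch(clf, batch)
    x = np.diff(pos, axis=-1)
    feats = []
    for start in range(0, len(x), batch_size):
        feats.append(clf.features_tensor(Tensor(x[start:start + batch_size])).data)
    return (np.concatenate(feats) if feats
            else np.empty((0, clf.config.feature_dim)))


def weighted_f1(predicted: list[str], true: list[str]) -> F1Report:
    """Class-frequency-weighted F1 over one-vs-rest per-class scores.

    F1_i = 2 P_i R_i / (P_i + R_i) (0 when the denominator is 0); the
    summary is sum_i w_i F1_i with w_i = n_i / sum_j n_j, where n_i counts
    the *true* members of class i.  Classes that appear only in the
    predictions get a report entry with weight 0.
    """
    if len(predicted) == 0 or len(predicted) != len(true):
        raise ValueError("need equal-length, nonempty label sequences")
    pred = np.asarray(predicted, dtype=object)
    truth = np.asarray(true, dtype=object)
    classes = tuple(sorted(set(truth) | set(pred)))
    precision, recall, f1, counts, wts = {}, {}, {}, {}, {}
    total = len(truth)
    wf1 = 0.0
    for c in classes:
        tp = int(np.sum((pred == c) & (truth == c)))
        fp = int(np.sum((pred == c) & (truth != c)))
        fn = int(np.sum((pred != c) & (truth == c)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        n_c = int(np.sum(truth == c))
        precision[c], recall[c], f1[c] = p, r, f
        counts[c] = n_c
        wts[c] = n_c / total
        wf1 += wts[c] * f
    return F1Report(classes=classes, precision=precision, recall=recall,
                    f1=f1, counts=counts, weights=wts, weighted_f1=wf1)
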