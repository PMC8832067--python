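"""Crash-predictor families and their train/predict contracts.

Seven families over (L x 4)-channel windows, all ending in a single
sigmoid output trained with binary cross-entropy:

* LINEAR — one affine map of the flattened window (the non-deep baseline);
* MLP — flatten, three ReLU hidden layers of 50 neurons;
* CNN — Conv1D(128 filters, size 3, stride 1, same padding) + max-pool 2,
  then Conv1D(128 filters, size 4) + max-pool 2, flatten, 100-neuron
  ReLU head;
* RNN_LSTM / RNN_GRU — one recurrent layer of hidden size 100, dropout
  0.5 on the final hidden state, 128-neuron ReLU head;
* STACKED_LSTM / STACKED_GRU — two recurrent layers of hidden size 100,
  then the same dropout + 128-neuron head.

Training uses Adam with early stopping on validation loss.  A scaled
profile (hidden 32, head 32, few epochs) keeps test-suite runs cheap;
the default profile matches the full-size architectures above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nnet
from .nnet import (Adam, Conv1D, Dense, Dropout, Flatten, GRU, LSTM,
                   MaxPool1D, ReLU, Sequential, bce_with_logits)
from .preprocess import WindowSet

FAMILIES = ("LINEAR", "MLP", "CNN", "RNN_LSTM", "RNN_GRU",
            "STACKED_LSTM", "STACKED_GRU")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture + training hyperparameters for one predictor."""

    family: str = "STACKED_GRU"
    hidden_size: int = 100          # recurrent hidden state width
    head_width: int = 128           # fully connected layer after RNN/CNN
    mlp_width: int = 50             # width of each of the three MLP layers
    cnn_filters: int = 128
    dropout_rate: float = 0.5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    precision: str = "float32"       # training dtype: float32 or float64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"expected one of {FAMILIES}")
        if min(self.hidden_size, self.head_width, self.mlp_width,
               self.cnn_filters) < 1:
            raise ValueError("widths must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def scaled(self, **overrides) -> "ModelSpec":
        """Small-profile copy for quick experiments and tests."""
        small = dict(hidden_size=32, head_width=32, mlp_width=16,
                     cnn_filters=16, max_epochs=14, patience=4,
                     batch_size=512, learning_rate=3e-3)
        small.update(overrides)
        return replace(self, **small)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PredictionRecord:
    """One scored window plus the metadata the failure analyses need."""

    index: int
    score: float
    label: int
    episode_id: int
    trial_id: int
    max_abs_theta: float
    end_time: float
    end_index: int


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1


def build_model(spec: ModelSpec, input_shape: Tuple[int, int]) -> Sequential:
    """Instantiate the family's layer stack for windows of shape (L, C)."""
    L, C = input_shape
    rng = np.random.default_rng(spec.seed)
    f = spec.family
    layers: List[nnet.Layer]
    if f == "LINEAR":
        layers = [Flatten(), Dense(L * C, 1, rng)]
    elif f == "MLP":
        w = spec.mlp_width
        layers = [Flatten(), Dense(L * C, w, rng), ReLU(),
                  Dense(w, w, rng), ReLU(), Dense(w, w, rng), ReLU(),
                  Dense(w, 1, rng)]
    elif f == "CNN":
        nf = spec.cnn_filters
        l_after = (L // 2) // 2
        if l_after < 1:
            raise ValueError("window too short for the CNN family")
        layers = [Conv1D(C, nf, 3, rng), ReLU(), MaxPool1D(2),
                  Conv1D(nf, nf, 4, rng), ReLU(), MaxPool1D(2),
                  Flatten(), Dense(l_after * nf, 100, rng), ReLU(),
                  Dense(100, 1, rng)]
    elif f in ("RNN_LSTM", "RNN_GRU", "STACKED_LSTM", "STACKED_GRU"):
        h, head = spec.hidden_size, spec.head_width
        cell = LSTM if "LSTM" in f else GRU
        layers = []
        if f.startswith("STACKED"):
            layers.append(cell(C, h, rng, return_sequences=True))
            layers.append(cell(h, h, rng, return_sequences=False))
        else:
            layers.append(cell(C, h, rng, return_sequences=False))
        layers += [Dropout(spec.dropout_rate, rng=np.random.default_rng(
                       spec.seed + 1)),
                   Dense(h, head, rng), ReLU(), Dense(head, 1, rng)]
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(f"unknown family {f!r}")
    return Sequential(layers)


def _epoch_pass(model: Sequential, X, y, opt: Adam, batch_size: int,
                rng: np.random.Generator) -> float:
    order = rng.permutation(len(y))
    total, count = 0.0, 0
    for s in range(0, len(y), batch_size):
        idx = order[s:s + batch_size]
        xb, yb = X[idx], y[idx]
        logits = model.forward(xb, train=True)
        loss, dlogit = bce_with_logits(logits, yb)
        if not np.isfinite(loss):
            raise FloatingPointError("NaN/inf training loss; aborting")
        model.zero_grad()
        model.backward(dlogit)
        opt.step()
        total += loss * len(idx)
        count += len(idx)
    return total / max(count, 1)


def _eval_loss(model: Sequential, X, y, batch_size: int = 4096) -> float:
    total = 0.0
    for s in range(0, len(y), batch_size):
        logits = model.forward(X[s:s + batch_size], train=False)
        loss, _ = bce_with_logits(logits, y[s:s + batch_size])
        total += loss * len(logits)
    return total / max(len(y), 1)


def train(model: Sequential, train_windows: WindowSet,
          val_windows: Optional[WindowSet], spec: ModelSpec
          ) -> Tuple[Sequential, TrainHistory]:
    """Fit with Adam + early stopping on validation loss.

    Deterministic given ``spec.seed`` (all shuffling and dropout derive
    from it).  The best-validation-epoch weights are restored before
    returning; with no validation set the final weights are kept.
    """
    if val_windows is not None and len(val_windows):
        overlap = (set(np.unique(train_windows.episode_id))
                   & set(np.unique(val_windows.episode_id)))
        if overlap:
            raise ValueError(
                f"episode leakage between train and validation: {sorted(overlap)[:5]}")
    dtype = np.float32 if spec.precision == "float32" else np.float64
    model.astype(dtype)
    X = train_windows.X.astype(dtype)
    y = train_windows.y.astype(dtype)
    val_X = val_y = None
    if val_windows is not None and len(val_windows):
        val_X = val_windows.X.astype(dtype)
        val_y = val_windows.y.astype(dtype)
    opt = Adam(model.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed)
    hist = TrainHistory()
    best_val = np.inf
    best_state: Optional[List[np.ndarray]] = None
    since_best = 0
    for epoch in range(spec.max_epochs):
        hist.train_loss.append(_epoch_pass(model, X, y, opt,
                                           spec.batch_size, rng))
        if val_X is not None:
            vl = _eval_loss(model, val_X, val_y)
            hist.val_loss.append(vl)
            if vl < best_val - 1e-6:
                best_val = vl
                best_state = [p.v.copy() for p in model.params()]
                hist.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best > spec.patience:
                    break
        else:
            hist.best_epoch = epoch
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.v[...] = v
    return model, hist


def predict(model: Sequential, windows: WindowSet) -> List[PredictionRecord]:
    """Score every window, order preserved, with analysis metadata."""
    if len(windows) == 0:
        return []
    if windows.X.ndim != 3:
        raise ValueError("windows.X must have shape (N, L, C)")
    scores = model.predict_proba(windows.X)
    maxima = windows.max_abs_theta
    return [PredictionRecord(index=i, score=float(scores[i]),
                             label=int(windows.y[i]),
                             episode_id=int(windows.episode_id[i]),
                             trial_id=int(windows.trial_id[i]),
                             max_abs_theta=float(maxima[i]),
                             end_time=float(windows.end_time[i]),
                             end_index=int(windows.end_index[i]))
            for i in range(len(windows))]
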