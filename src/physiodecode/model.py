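"""Joint RV/HR reconstruction model: estimator, training loop, CV, evaluation.

``PhysioReconstructor`` is a scikit-learn-style estimator wrapping the NumPy
bi-LSTM in :mod:`physiodecode.lstm`.  Its inputs are lists of variable-length
scans: ``X[i]`` is a (T_i, R) preprocessed ROI-by-time matrix (frames first),
``y[i]`` a (T_i, 2) matrix of z-scored [RV, HR] targets.  Scans inside a
batch are padded to the batch maximum with a validity mask; masked frames do
not enter the loss.

Training uses Adam with a plateau learning-rate schedule (decay factor 0.5
after ``patience`` epochs without validation improvement) and keeps the
weights of the epoch with the lowest validation loss.  Cross-validation is
subject-wise: all scans of a subject travel together, with a 68/12/20
train/validation/test partition per fold.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import lstm
from .lstm import recon_loss  # re-exported: loss contract lives with the model

__all__ = [
    "ReconConfig",
    "CVSplit",
    "PhysioReconstructor",
    "make_cv_splits",
    "train_model",
    "evaluate_scan",
    "recon_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ReconConfig:
    """Hyperparameters of the reconstruction network and its training."""

    hidden_size: int = 2000
    batch_size: int = 16
    dropout: float = 0.3
    lr: float = 1e-3
    lr_decay: float = 0.5
    patience: int = 2
    max_epochs: int = 100
    early_stop: int = 6
    seed: int = 0
    input_rois: list[int] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (0 < self.lr_decay < 1):
            raise ValueError("lr_decay must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class CVSplit:
    """Subject-wise folds with a 68/12/20 train/val/test partition."""

    folds: list[tuple[list, list, list]]
    fractions: tuple[float, float, float] = (0.68, 0.12, 0.20)

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_cv_splits(subject_ids, k: int = 5, seed: int = 0,
                   val_fraction_of_train: float = 0.15) -> CVSplit:
    """Deterministic subject-wise k-fold split.

    Subjects are shuffled once with ``seed`` and dealt into ``k`` disjoint
    test sets whose union is all subjects.  The remaining 80% of each fold is
    split into training and validation subjects (12% of the total, i.e. 15%
    of the non-test portion, mirroring a 68/12/20 partition).
    """
    subjects = list(dict.fromkeys(subject_ids))  # stable de-dup
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    test_sets = [order[i::k] for i in range(k)]
    folds = []
    for i in range(k):
        test = sorted(test_sets[i], key=order.index)
        rest = [s for s in order if s not in test_sets[i]]
        n_val = max(1, int(round(val_fraction_of_train * len(rest))))
        val = rest[:n_val]
        train = rest[n_val:]
        if not train:
            raise ValueError("too few subjects to form a training set")
        folds.append((train, val, test))
    return CVSplit(folds=folds)


def _pad_batch(Xs, ys=None):
    """Pad scans (T_i, R) to (T_max, B, R) + mask (T_max, B)."""
    B = len(Xs)
    T_max = max(x.shape[0] for x in Xs)
    R = Xs[0].shape[1]
    X = np.zeros((T_max, B, R))
    mask = np.zeros((T_max, B))
    rv = np.zeros((T_max, B))
    hr = np.zeros((T_max, B))
    for j, x in enumerate(Xs):
        T = x.shape[0]
        X[:T, j] = x
        mask[:T, j] = 1.0
        if ys is not None:
            rv[:T, j] = ys[j][:, 0]
            hr[:T, j] = ys[j][:, 1]
    return X, mask, rv, hr


class PhysioReconstructor(RegressorMixin, BaseEstimator):
    """Bidirectional-LSTM joint regressor for per-frame RV and HR.

    Parameters mirror :class:`ReconConfig`.  ``input_rois`` optionally
    restricts the model to a subset of input channels (by position in the
    channel axis), which reproduces single-ROI, top-percent and
    region-exclusion experiments purely through configuration.

    Fitted attributes
    -----------------
    params_ : dict of weight arrays (see :mod:`physiodecode.lstm`).
    history_ : list of per-epoch dicts (epoch, train_loss, val_loss, lr).
    best_epoch_ : epoch index of the restored (minimum validation loss) model.
    n_channels_ : number of input channels after any ROI subsetting.
    """

    def __init__(
        self,
        hidden_size: int = 2000,
        batch_size: int = 16,
        dropout: float = 0.3,
        lr: float = 1e-3,
        lr_decay: float = 0.5,
        patience: int = 2,
        max_epochs: int = 100,
        early_stop: int = 6,
        seed: int = 0,
        input_rois: list[int] | None = None,
        val_fraction: float = 0.15,
    ):
        self.hidden_size = hidden_size
        self.batch_size = batch_size
        self.dropout = dropout
        self.lr = lr
        self.lr_decay = lr_decay
        self.patience = patience
        self.max_epochs = max_epochs
        self.early_stop = early_stop
        self.seed = seed
        self.input_rois = input_rois
        self.val_fraction = val_fraction

    # -- helpers ----------------------------------------------------------
    def _subset(self, X):
        if self.input_rois is None:
            return [np.asarray(x, float) for x in X]
        idx = np.asarray(self.input_rois, int)
        return [np.asarray(x, float)[:, idx] for x in X]

    def _check_channels(self, X):
        for x in X:
            if x.shape[1] != self.n_channels_:
                raise ValueError(
                    f"channel mismatch: model expects {self.n_channels_} "
                    f"channels, received {x.shape[1]}"
                )

    def _epoch_loss(self, Xs, ys):
        total, n = 0.0, 0
        for start in range(0, len(Xs), self.batch_size):
            Xb = Xs[start : start + self.batch_size]
            yb = ys[start : start + self.batch_size]
            X, mask, rv, hr = _pad_batch(Xb, yb)
            rv_hat, hr_hat = lstm.forward(self.params_, X, mask=mask)
            total += lstm.masked_mse(rv_hat, rv, mask) + lstm.masked_mse(
                hr_hat, hr, mask
            )
            n += 1
        return total / max(n, 1)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on a list of scans.

        ``X``: list of (T_i, R) matrices; ``y``: list of (T_i, 2) [RV, HR]
        targets.  If no explicit validation set is given, the last
        ``val_fraction`` of scans is held out (the caller is responsible for
        subject-wise separation when that matters; :func:`train_model` does
        this from a CV split).
        """
        # validate config through the dataclass invariants
        ReconConfig(
            hidden_size=self.hidden_size,
            batch_size=self.batch_size,
            dropout=self.dropout,
            lr=self.lr,
            lr_decay=self.lr_decay,
            patience=self.patience,
            max_epochs=self.max_epochs,
            early_stop=self.early_stop,
            seed=self.seed,
        )
        X = self._subset(X)
        y = [np.asarray(t, float) for t in y]
        if len(X) == 0:
            raise ValueError("empty training set")
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * len(X))))
            if len(X) - n_val < 1:
                raise ValueError("too few scans to split off a validation set")
            X, X_val = X[:-n_val], X[-n_val:]
            y, y_val = y[:-n_val], y[-n_val:]
        else:
            X_val = self._subset(X_val)
            y_val = [np.asarray(t, float) for t in y_val]
        if len(X_val) == 0:
            raise ValueError("empty validation set")

        self.n_channels_ = X[0].shape[1]
        self._check_channels(X)
        self._check_channels(X_val)

        rng = np.random.default_rng(self.seed)
        self.params_ = lstm.init_params(self.n_channels_, self.hidden_size, rng)
        opt = lstm.AdamState(self.params_, lr=self.lr)

        best_val = np.inf
        best_params = copy.deepcopy(self.params_)
        best_epoch = -1
        bad_epochs = 0
        self.history_ = []

        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X))
            train_losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                Xb = [X[i] for i in idx]
                yb = [y[i] for i in idx]
                Xp, mask, rv, hr = _pad_batch(Xb, yb)
                loss, grads = lstm.loss_and_grads(
                    self.params_, Xp, rv, hr, mask=mask,
                    dropout=self.dropout, rng=rng,
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                opt.step(self.params_, grads)
                train_losses.append(loss)

            val_loss = self._epoch_loss(X_val, y_val)
            self.history_.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(train_losses)),
                    "val_loss": float(val_loss),
                    "lr": opt.lr,
                }
            )
            if val_loss < best_val:
                best_val = val_loss
                best_params = copy.deepcopy(self.params_)
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs % self.patience == 0:
                    opt.lr *= self.lr_decay
                if bad_epochs >= self.early_stop:
                    break

        self.params_ = best_params
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        return self

    def predict(self, X):
        """Per-scan (T_i, 2) [RV, HR] estimates; deterministic (no dropout)."""
        if not hasattr(self, "params_"):
            raise ValueError("model is not fitted")
        X = self._subset(X)
        self._check_channels(X)
        out = []
        for x in X:
            Xp = x[:, None, :]  # (T, 1, R)
            rv_hat, hr_hat = lstm.forward(self.params_, Xp)
            out.append(np.column_stack([rv_hat[:, 0], hr_hat[:, 0]]))
        return out

    def score(self, X, y):
        """Mean Pearson r over scans and both signals (higher is better)."""
        preds = self.predict(X)
        rs = []
        for p, t in zip(preds, y):
            t = np.asarray(t, float)
            rs.append(evaluate_scan(p[:, 0], t[:, 0]))
            rs.append(evaluate_scan(p[:, 1], t[:, 1]))
        return float(np.mean(rs))


def forward_recon(model: PhysioReconstructor, ts) -> tuple[np.ndarray, np.ndarray]:
    """Apply a fitted model to one ROI time-series (frames on axis 1).

    Accepts an ``ROITimeseries`` (R x T) or a bare (T, R) array and returns
    per-frame ``(rv_hat, hr_hat)`` of the same length as the input.
    """
    data = getattr(ts, "data", ts)
    data = np.asarray(data, float)
    if hasattr(ts, "data"):
        data = data.T  # ROITimeseries stores R x T
    pred = model.predict([data])[0]
    return pred[:, 0], pred[:, 1]


def train_model(dataset, config: ReconConfig, train_idx, val_idx):
    """Train from a list of (roi_matrix_T_by_R, target_T_by_2) pairs.

    ``train_idx``/``val_idx`` index scans (typically derived from a
    subject-wise CV fold).  Returns the fitted estimator; the per-epoch log
    is on ``model.history_``.
    """
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty train or validation set")
    model = PhysioReconstructor(
        hidden_size=config.hidden_size,
        batch_size=config.batch_size,
        dropout=config.dropout,
        lr=config.lr,
        lr_decay=config.lr_decay,
        patience=config.patience,
        max_epochs=config.max_epochs,
        early_stop=config.early_stop,
        seed=config.seed,
        input_rois=config.input_rois,
    )
    X_tr = [dataset[i][0] for i in train_idx]
    y_tr = [dataset[i][1] for i in train_idx]
    X_va = [dataset[i][0] for i in val_idx]
    y_va = [dataset[i][1] for i in val_idx]
    return model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)


def evaluate_scan(pred: np.ndarray, measured: np.ndarray) -> float:
    """Pearson correlation between a predicted and a measured series."""
    pred = np.asarray(pred, float)
    measured = np.asarray(measured, float)
    if pred.shape != measured.shape:
        raise ValueError("series must have equal length")
    if np.ptp(pred) == 0 or np.ptp(measured) == 0:
        raise ValueError("undefined correlation for a constant series")
    return float(np.corrcoef(pred, measured)[0, 1])


# ---------------------------------------------------------------------------
# Checkpointing: single-file npz holding weights + config + channel ids
# ---------------------------------------------------------------------------

def _data_hash(X) -> str:
    h = hashlib.sha256()
    for x in X:
        h.update(np.ascontiguousarray(np.asarray(x, float)).tobytes())
    return h.hexdigest()[:16]


def save_checkpoint(model: PhysioReconstructor, path, roi_ids=None,
                    data_hash: str | None = None) -> None:
    meta = {
        "config": model.get_params(),
        "roi_ids": [int(r) for r in roi_ids] if roi_ids is not None else None,
        "n_channels": int(model.n_channels_),
        "best_epoch": int(model.best_epoch_),
        "data_hash": data_hash,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.params_,
    )


def load_checkpoint(path) -> tuple[PhysioReconstructor, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = PhysioReconstructor(**meta["config"])
    model.params_ = params
    model.n_channels_ = meta["n_channels"]
    model.best_epoch_ = meta["best_epoch"]
    model.history_ = []
    return model, meta
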