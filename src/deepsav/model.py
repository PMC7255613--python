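"""The convolutional pathogenicity classifier and its evaluation helpers.

:class:`DeepSAVClassifier` is an sklearn-style estimator over flattened
21x90 feature windows.  The network is seven conv1d layers with two residual
skips and two max-pools, followed by two dense layers and a 2-class softmax;
the pathogenic-class probability is the DeepSAV score.  The +PG variant takes
an 18-value side input (transformed minor allele frequency plus 17 gene-level
features) concatenated before the dense layers.

Training uses Adam on softmax cross-entropy with optional early stopping on a
held-out validation split; given a ``random_state`` the whole procedure is
bit-reproducible.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import _net
from .features import N_FEATURES, WINDOW, WINDOW_SIZE

N_PG_FEATURES = 18  # -log10 MAF + 17 gene-level features
MAF_EPS = 1e-9


@dataclass
class NetworkConfig:
    """Hyperparameters of the convolutional classifier.

    Defaults follow the published architecture: 7 conv1d layers of 200
    filters with kernel 3, two max-pool layers, two residual links, two dense
    layers of 100 units with dropout 0.5, batch size 128.
    """

    filters: int = 200
    kernel: int = 3
    dense_units: int = 100
    dropout: float = 0.5
    batch_size: int = 128
    epochs: int = 20
    learning_rate: float = 1e-3
    early_stopping: bool = True
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int | None = None
    # architecture constants (informational; the layer plan is fixed in code)
    conv_layers: int = field(default=7, repr=False)
    max_pool_layers: int = field(default=2, repr=False)
    residual_links: int = field(default=2, repr=False)
    dense_layers: int = field(default=2, repr=False)

    def __post_init__(self) -> None:
        for name in ("filters", "kernel", "dense_units", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def to_estimator(self, pg: bool = False) -> "DeepSAVClassifier":
        return DeepSAVClassifier(
            filters=self.filters,
            kernel_size=self.kernel,
            dense_units=self.dense_units,
            dropout=self.dropout,
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            early_stopping=self.early_stopping,
            validation_fraction=self.validation_fraction,
            patience=self.patience,
            n_pg_features=N_PG_FEATURES if pg else 0,
            random_state=self.seed,
        )


def build_network(config: NetworkConfig, pg: bool = False) -> "DeepSAVClassifier":
    """An unfitted classifier for the given configuration (+PG when requested)."""
    return config.to_estimator(pg=pg)


class DeepSAVClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional missense-pathogenicity classifier over 21x90 windows.

    Input rows are flattened windows of ``WINDOW_SIZE`` (1890) values; with
    ``n_pg_features > 0`` each row carries that many extra side-input values
    appended after the window.  ``predict_proba[:, 1]`` is the DeepSAV score
    in [0, 1] for the positive (pathogenic) class.

    Parameters mirror :class:`NetworkConfig`; ``random_state`` seeds weight
    initialisation, batch shuffling, dropout, and the validation split, making
    two fits on identical data bit-identical.
    """

    def __init__(
        self,
        filters: int = 200,
        kernel_size: int = 3,
        dense_units: int = 100,
        dropout: float = 0.5,
        batch_size: int = 128,
        epochs: int = 20,
        learning_rate: float = 1e-3,
        n_pg_features: int = 0,
        early_stopping: bool = True,
        validation_fraction: float = 0.1,
        patience: int = 5,
        random_state: int | None = None,
        verbose: int = 0,
    ) -> None:
        self.filters = filters
        self.kernel_size = kernel_size
        self.dense_units = dense_units
        self.dropout = dropout
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.n_pg_features = n_pg_features
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _split_input(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        X = np.asarray(X, dtype=float)
        expected = WINDOW_SIZE + self.n_pg_features
        if X.ndim != 2 or X.shape[1] != expected:
            raise ValueError(
                f"expected input of shape (n, {expected}) "
                f"({WINDOW_SIZE} window values + {self.n_pg_features} side features), "
                f"got {X.shape}"
            )
        windows = X[:, :WINDOW_SIZE].reshape(-1, WINDOW, N_FEATURES)
        pg = X[:, WINDOW_SIZE:] if self.n_pg_features else None
        return windows, pg

    def fit(self, X, y) -> "DeepSAVClassifier":
        windows, pg = self._split_input(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly 2 classes for training, got {len(self.classes_)}"
            )
        yi = np.searchsorted(self.classes_, y)
        n = len(yi)
        rng = np.random.default_rng(self.random_state)

        params = _net.init_params(
            rng,
            n_channels=N_FEATURES,
            window=WINDOW,
            filters=self.filters,
            kernel=self.kernel_size,
            dense_units=self.dense_units,
            n_pg=self.n_pg_features,
        )
        opt = _net.Adam(params, lr=self.learning_rate)

        # optional stratified validation split for early stopping
        if self.early_stopping and self.validation_fraction > 0 and n >= 20:
            val_idx = []
            for c in (0, 1):
                idx_c = np.flatnonzero(yi == c)
                k = max(1, int(round(len(idx_c) * self.validation_fraction)))
                val_idx.append(rng.permutation(idx_c)[:k])
            val_idx = np.concatenate(val_idx)
            train_mask = np.ones(n, dtype=bool)
            train_mask[val_idx] = False
            tr_idx = np.flatnonzero(train_mask)
        else:
            tr_idx = np.arange(n)
            val_idx = None

        best_metric = -np.inf
        best_params = None
        bad_epochs = 0
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                bi = order[start : start + self.batch_size]
                probs, cache = _net.forward(
                    params,
                    windows[bi],
                    self.kernel_size,
                    pg=None if pg is None else pg[bi],
                    dropout_rate=self.dropout,
                    rng=rng,
                )
                epoch_loss += _net.cross_entropy(probs, yi[bi]) * len(bi)
                grads = _net.backward(params, cache, probs, yi[bi], self.kernel_size)
                opt.step(params, grads)
            epoch_loss /= len(order)
            record = {"epoch": epoch, "train_loss": epoch_loss}
            if val_idx is not None:
                val_probs = self._forward_batches(params, windows, pg, val_idx)
                record["val_loss"] = _net.cross_entropy(val_probs, yi[val_idx])
                # monitor ranking quality: the model's figure of merit is AUC,
                # which keeps improving after the loss degrades from overconfidence
                val_auc = roc_auc_score(yi[val_idx], val_probs[:, 1])
                record["val_auc"] = val_auc
                if val_auc > best_metric + 1e-6:
                    best_metric = val_auc
                    best_params = {k: v.copy() for k, v in params.items()}
                    bad_epochs = 0
                else:
                    bad_epochs += 1
            self.history_.append(record)
            if self.verbose:
                print(f"epoch {epoch}: {record}")
            if val_idx is not None and bad_epochs >= self.patience:
                break
        if best_params is not None:
            params = best_params
        self.params_ = params
        self.n_features_in_ = X.shape[1]
        self.n_parameters_ = int(sum(v.size for v in params.values()))
        return self

    def _forward_batches(self, params, windows, pg, idx=None, batch=512):
        if idx is None:
            idx = np.arange(len(windows))
        out = np.empty((len(idx), 2))
        for start in range(0, len(idx), batch):
            bi = idx[start : start + batch]
            out[start : start + len(bi)], _ = _net.forward(
                params,
                windows[bi],
                self.kernel_size,
                pg=None if pg is None else pg[bi],
            )
        return out

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        windows, pg = self._split_input(X)
        return self._forward_batches(self.params_, windows, pg)

    def decision_function(self, X) -> np.ndarray:
        """The DeepSAV score: softmax probability of the positive class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise ValueError("classifier is not fitted yet; call fit first")

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a single-file checkpoint (config JSON + weights); round-trips bit-exactly."""
        self._check_fitted()
        config = self.get_params()
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(config))
            zf.writestr("classes.json", json.dumps(np.asarray(self.classes_).tolist()))
            buf = io.BytesIO()
            np.savez(buf, **self.params_)
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "DeepSAVClassifier":
        with zipfile.ZipFile(path) as zf:
            config = json.loads(zf.read("config.json"))
            classes = json.loads(zf.read("classes.json"))
            with zf.open("weights.npz") as fh:
                npz = np.load(io.BytesIO(fh.read()))
                params = {k: npz[k] for k in npz.files}
        est = cls(**config)
        est.params_ = params
        est.classes_ = np.asarray(classes)
        est.n_features_in_ = WINDOW_SIZE + est.n_pg_features
        est.n_parameters_ = int(sum(v.size for v in params.values()))
        est.history_ = []
        return est


# ---------------------------------------------------------------------------
# functional wrappers


def train(X, y, config: NetworkConfig | None = None, pg: bool = False) -> DeepSAVClassifier:
    """Fit a classifier on a labelled window matrix; thin wrapper over the estimator."""
    config = config or NetworkConfig()
    return build_network(config, pg=pg).fit(X, y)


def predict(model: DeepSAVClassifier, X) -> np.ndarray:
    """DeepSAV scores in [0, 1] (positive-class softmax probability)."""
    return model.decision_function(X)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; equals P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CVResult:
    """Stratified k-fold cross-validation outcome."""

    fold_aucs: list[float]
    pooled_auc: float
    fold_assignment: np.ndarray
    scores: np.ndarray

    def __repr__(self) -> str:  # compact, notebook-friendly
        folds = ", ".join(f"{a:.3f}" for a in self.fold_aucs)
        return f"CVResult(folds=[{folds}], pooled={self.pooled_auc:.3f})"


def cross_validate(
    X,
    y,
    k: int = 4,
    config: NetworkConfig | None = None,
    estimator: DeepSAVClassifier | None = None,
    seed: int | None = None,
    pg: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation with per-fold and pooled ROC AUC.

    Every variant is validated exactly once; pooled AUC is computed on the
    out-of-fold scores of the whole dataset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("cross_validate needs both classes present")
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the smaller class size {counts.min()}")
    base = estimator if estimator is not None else build_network(config or NetworkConfig(), pg=pg)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.zeros(len(y))
    assignment = np.full(len(y), -1)
    fold_aucs = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        est = clone(base)
        est.fit(X[tr], y[tr])
        s = est.decision_function(X[va])
        scores[va] = s
        assignment[va] = fold
        fold_aucs.append(roc_auc(s, y[va]))
    return CVResult(fold_aucs, roc_auc(scores, y), assignment, scores)


# ---------------------------------------------------------------------------
# +PG side features


def pg_features(maf: np.ndarray, gene_level: np.ndarray) -> np.ndarray:
    """Assemble the 18-value side input: ``-log10(MAF + 1e-9)`` plus 17 gene features.

    Missing values (NaN) are left in place; impute them per training fold with
    :func:`median_impute` before fitting.
    """
    maf = np.asarray(maf, dtype=float)
    gene_level = np.asarray(gene_level, dtype=float)
    if gene_level.ndim != 2 or gene_level.shape[1] != 17:
        raise ValueError(f"gene_level must be (n, 17), got {gene_level.shape}")
    tmaf = -np.log10(np.clip(maf, 0.0, None) + MAF_EPS)
    return np.column_stack([tmaf, gene_level])


def median_impute(train: np.ndarray, *others: np.ndarray) -> list[np.ndarray]:
    """Replace NaNs by training-set column medians (medians computed on train only)."""
    train = np.array(train, dtype=float)
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    out = []
    for arr in (train, *others):
        arr = np.array(arr, dtype=float)
        nan = np.isnan(arr)
        arr[nan] = np.broadcast_to(med, arr.shape)[nan]
        out.append(arr)
    return out
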