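"""Scikit-learn style interface to the per-second apnea detector.

:class:`SpO2TransformerClassifier` wraps model construction and the
training protocol behind the familiar ``fit`` / ``predict_proba`` /
``predict`` surface so the detector composes with sklearn model selection
(`clone`, grid search, pipelines operating on fixed-length windows).

``X`` is an array of normalized SpO2 windows, shape ``(n_windows,
sequence_length)`` (a trailing singleton feature axis is accepted);
``y`` holds the aligned per-second 0/1 labels of the same shape. Both
``predict_proba`` and ``predict`` return per-second outputs of that shape
— this is sequence labeling, one decision per second, not per-window
classification.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split

from .encoding import CaeConfig
from .train import TrainConfig, train_model
from .transformer import ModelConfig, build_model


class SpO2TransformerClassifier(BaseEstimator):
    """Transformer encoder with selectable positional encoding.

    Parameters mirror :class:`~spo2former.transformer.ModelConfig` and
    :class:`~spo2former.train.TrainConfig`. The default learning rate here
    is 1e-3, a practical setting for the small synthetic workloads this
    package trains on CPU; pass ``learning_rate=1e-5`` for the
    conservative overnight-scale protocol.
    """

    def __init__(
        self,
        sequence_length: int = 120,
        pe: str = "learnable",
        n_encoder_layers: int = 4,
        d_model: int = 32,
        n_heads: int = 4,
        d_ff: int = 64,
        dropout_rate: float = 0.1,
        cae_filters: tuple[int, ...] = (32, 16),
        cae_dropout_rate: float = 0.1,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 10,
        lr_plateau_factor: float = 0.2,
        plateau_patience_epochs: int = 5,
        class_weighting: str = "off",
        validation_fraction: float = 0.15,
        early_stop_auc: float | None = None,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.sequence_length = sequence_length
        self.pe = pe
        self.n_encoder_layers = n_encoder_layers
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.dropout_rate = dropout_rate
        self.cae_filters = cae_filters
        self.cae_dropout_rate = cae_dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.lr_plateau_factor = lr_plateau_factor
        self.plateau_patience_epochs = plateau_patience_epochs
        self.class_weighting = class_weighting
        self.validation_fraction = validation_fraction
        self.early_stop_auc = early_stop_auc
        self.threshold = threshold
        self.random_state = random_state

    # -- config assembly ------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_encoder_layers=self.n_encoder_layers,
            d_model=self.d_model,
            n_heads=self.n_heads,
            d_ff=self.d_ff,
            dropout_rate=self.dropout_rate,
            sequence_length=self.sequence_length,
            pe=self.pe,
            cae=CaeConfig(
                n_down_layers=len(self.cae_filters),
                filters=tuple(self.cae_filters),
                dropout_rate=self.cae_dropout_rate,
            ),
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            initial_lr=self.learning_rate,
            lr_plateau_factor=self.lr_plateau_factor,
            plateau_patience_epochs=self.plateau_patience_epochs,
            max_epochs=self.max_epochs,
            class_weighting=self.class_weighting,
            threshold=self.threshold,
            early_stop_auc=self.early_stop_auc,
            seed=self.random_state,
        )

    @staticmethod
    def _check_xy(X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 2:
            raise ValueError("X must be (n_windows, sequence_length)")
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("y must align with X per second")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary")
        return X, y

    # -- estimator API ---------------------------------------------------------

    def fit(self, X, y):
        X, y = self._check_xy(X, y)
        if X.shape[1] != self.sequence_length:
            raise ValueError(
                f"windows of length {X.shape[1]} do not match sequence_length={self.sequence_length}"
            )
        model = build_model(self._model_config(), seed=self.random_state)
        if 0.0 < self.validation_fraction < 1.0 and X.shape[0] >= 5:
            x_tr, x_va, y_tr, y_va = train_test_split(
                X, y, test_size=self.validation_fraction, random_state=self.random_state
            )
        else:
            x_tr, y_tr, x_va, y_va = X, y, X[:0], y[:0]
        self.model_, self.history_ = train_model(
            model, (x_tr, y_tr), (x_va, y_va), self._train_config()
        )
        self.n_parameters_ = model.n_parameters()
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-second apnea probabilities, shape (n_windows, sequence_length)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3 and X.shape[-1] == 1:
            X = X[..., 0]
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        """Per-second 0/1 apnea decisions at the configured threshold."""
        return (self.predict_proba(X) >= self.threshold).astype(np.int64)

    def score(self, X, y) -> float:
        """Mean per-second accuracy (sklearn classifier convention)."""
        X, y = self._check_xy(X, y)
        return float((self.predict(X) == y).mean())

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this SpO2TransformerClassifier instance is not fitted yet")
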