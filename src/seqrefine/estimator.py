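"""scikit-learn style estimator facade over the refiner network.

``SequenceRefiner`` is the user-facing trainable object: ``fit`` runs the
masked-sequence training scheme, ``predict_proba`` returns per-residue
amino-acid distributions and ``predict`` returns designed sequences. X is a
list of :class:`BackboneStructure` and y a list of native sequences, so the
estimator composes with sklearn model-selection utilities that treat X as
an indexable collection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .alphabet import decode_sequence, encode_sequence
from .corruption import CorruptionConfig
from .model import ModelConfig, ModelParams, predict_profile
from .training import TrainConfig, train
from .types import BackboneStructure, PartialSequence, ProbabilityProfile


class SequenceRefiner(BaseEstimator):
    """Structure-conditioned sequence inpainting model.

    Parameters mirror the architecture (d, n_layers, k, attention_mode),
    the corruption scheme (mask_frac, replace_frac) and the optimizer
    (epochs, batch_size, learning_rate). Fitted state lives in ``params_``
    and ``loss_curve_``.
    """

    def __init__(self, d: int = 128, n_layers: int = 3, k: int = 30,
                 attention_mode: str = "global_pseudo",
                 mask_frac: float = 0.70, replace_frac: float = 0.03,
                 epochs: int = 10, batch_size: int = 8,
                 learning_rate: float = 1e-3,
                 loss_scope: str = "all_positions",
                 validation_fraction: float = 0.1,
                 random_state: int = 0):
        self.d = d
        self.n_layers = n_layers
        self.k = k
        self.attention_mode = attention_mode
        self.mask_frac = mask_frac
        self.replace_frac = replace_frac
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss_scope = loss_scope
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X: list[BackboneStructure], y: list[str]) -> "SequenceRefiner":
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        model_cfg = ModelConfig(d=self.d, n_layers=self.n_layers, k=self.k,
                                attention_mode=self.attention_mode,
                                seed=self.random_state)
        train_cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                                learning_rate=self.learning_rate,
                                seed=self.random_state,
                                attention_mode=self.attention_mode,
                                loss_scope=self.loss_scope,
                                validation_fraction=self.validation_fraction)
        corrupt_cfg = CorruptionConfig(mask_frac=self.mask_frac,
                                       replace_frac=self.replace_frac,
                                       seed=self.random_state)
        self.params_, self.loss_curve_ = train(list(zip(X, y)), train_cfg,
                                               corrupt_cfg, model_cfg)
        self.n_parameters_ = int(sum(t.data.size for t in self.params_.tensors.values()))
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X: list[BackboneStructure],
                      partials: list[PartialSequence] | None = None
                      ) -> list[ProbabilityProfile]:
        """Per-residue distributions, optionally conditioned on partial input."""
        self._check_fitted()
        profiles = []
        for idx, structure in enumerate(X):
            partial = (partials[idx] if partials is not None
                       else PartialSequence.fully_masked(structure.n_residues))
            profiles.append(predict_profile(structure, partial, self.params_))
        return profiles

    def predict(self, X: list[BackboneStructure],
                partials: list[PartialSequence] | None = None) -> list[str]:
        """Designed sequences (argmax per position; given residues kept)."""
        out = []
        for structure, profile in zip(X, self.predict_proba(X, partials)):
            tokens = profile.argmax_tokens()
            out.append(decode_sequence(tokens))
        if partials is not None:
            out = [
                "".join(p if not part.visible_mask[i] else part.to_string()[i]
                        for i, p in enumerate(seq))
                for seq, part in zip(out, partials)
            ]
        return out

    def score(self, X: list[BackboneStructure], y: list[str]) -> float:
        """Mean full-sequence recovery against the native sequences."""
        from .metrics import recovery

        preds = self.predict(X)
        return float(np.mean([recovery(p, n) for p, n in zip(preds, y)]))

    def save(self, path) -> None:
        self._check_fitted()
        self.params_.save(path)

    @classmethod
    def from_checkpoint(cls, path) -> "SequenceRefiner":
        params = ModelParams.load(path)
        cfg = params.config
        est = cls(d=cfg.d, n_layers=cfg.n_layers, k=cfg.k,
                  attention_mode=cfg.attention_mode, random_state=cfg.seed)
        est.params_ = params
        return est
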