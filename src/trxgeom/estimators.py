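"""scikit-learn style estimator façade over the functional pipeline.

``MSAFeaturizer`` is a stateless transformer (MSA -> 526-channel tensor);
``FMGeometryPredictor`` and ``TBMGeometryPredictor`` wrap network training
behind fit/predict with fitted attributes carrying the trailing underscore.
X is a list of :class:`~trxgeom.training.TrainingTarget` for ``fit`` and a
list of MSAs (or feature tensors) for ``predict``; the geometry labels ride
inside the targets, so ``y`` is accepted but ignored, as in other
structured-output estimators.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from trxgeom.containers import MSA, GeometryPosterior
from trxgeom.model_res2net import TINY, NetworkConfig, Res2NetTBM, symmetrize
from trxgeom.msa_features import featurize
from trxgeom.training import TrainingTarget, train_fm, train_tbm


class MSAFeaturizer(TransformerMixin, BaseEstimator):
    """Turn MSAs into (L, L, 526) input tensors; stateless."""

    def __init__(self, identity_cutoff: float = 0.8,
                 pseudocount: float | None = None,
                 shrinkage: float | None = None):
        self.identity_cutoff = identity_cutoff
        self.pseudocount = pseudocount
        self.shrinkage = shrinkage

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        return [
            featurize(msa, self.identity_cutoff, self.pseudocount,
                      self.shrinkage)
            for msa in X
        ]


def _as_features(item) -> np.ndarray:
    if isinstance(item, MSA):
        return featurize(item)
    return np.asarray(item)


class FMGeometryPredictor(BaseEstimator):
    """De novo inter-residue geometry predictor (trainable)."""

    def __init__(self, config: NetworkConfig = TINY, epochs: int = 20,
                 lr: float = 1e-3, subsample: bool = True,
                 augment: bool = True, seed: int = 0,
                 symmetrize_output: bool = True):
        self.config = config
        self.epochs = epochs
        self.lr = lr
        self.subsample = subsample
        self.augment = augment
        self.seed = seed
        self.symmetrize_output = symmetrize_output

    def fit(self, X: list[TrainingTarget], y=None):
        net, history = train_fm(
            X, config=self.config, seed=self.seed, epochs=self.epochs,
            lr=self.lr, subsample=self.subsample, augment=self.augment)
        self.network_ = net
        self.history_ = history
        return self

    def predict(self, X) -> list[GeometryPosterior]:
        out = []
        for item in X:
            posterior = self.network_.predict(_as_features(item))
            if self.symmetrize_output:
                posterior = symmetrize(posterior)
            out.append(posterior)
        return out

    def predict_one(self, msa_or_features) -> GeometryPosterior:
        return self.predict([msa_or_features])[0]


class TBMGeometryPredictor(BaseEstimator):
    """Template-based predictor; trains on top of a fitted FM predictor."""

    def __init__(self, fm: FMGeometryPredictor | None = None,
                 config: NetworkConfig | None = None, epochs: int = 10,
                 lr: float = 1e-3, seed: int = 1,
                 symmetrize_output: bool = True):
        self.fm = fm
        self.config = config
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.symmetrize_output = symmetrize_output

    def fit(self, X: list[TrainingTarget], y=None):
        if self.fm is None or not hasattr(self.fm, "network_"):
            raise ValueError("TBM training needs a fitted FMGeometryPredictor")
        net, history = train_tbm(
            X, self.fm.network_, config=self.config, seed=self.seed,
            epochs=self.epochs, lr=self.lr)
        self.network_: Res2NetTBM = net
        self.history_ = history
        return self

    def predict(self, X: list[TrainingTarget]) -> list[GeometryPosterior]:
        out = []
        for target in X:
            feats = featurize(target.msa)
            posterior, _ = self.network_.forward_with_templates(
                feats, target.templates)
            if self.symmetrize_output:
                posterior = symmetrize(posterior)
            out.append(posterior)
        return out
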