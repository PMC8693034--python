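"""Attention-based combination of multiple template feature maps.

Each of the N templates contributes an (L, L, 100) one-hot geometry map.
A learned 1x1 projection of the MSA embedding (the FM network's group-2
output) acts as the query; a shared 1x1 projection of each template map
acts as the key.  The per-pair logit for template k sums a pointwise
scaled dot product with row-axis and column-axis context passes (the key
averaged along each spatial axis), and a softmax over the *template* axis
turns logits into per-pair weights w_k(i, j).  The combined map is the
per-pair weighted sum of the template features.

The exact axial wiring of the original module is not published in the main
text; this lightweight single-head reconstruction keeps the documented
contracts: one template gets weight 1 everywhere, identical templates share
weight 1/N, and the weights are permutation-equivariant in template order.
Template confidences s_k deliberately do not enter the logits; they are
used only in the FM/TBM fusion weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from trxgeom.nn import Param, softmax


@dataclass
class TemplateFeatureStack:
    """N templates' one-hot maps plus their pair confidences."""

    features: np.ndarray  # (N, L, L, 100)
    s_pair: np.ndarray    # (N, L, L)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def length(self) -> int:
        return self.features.shape[1]


class TemplateAttention:
    """Single-head axial attention producing per-template pair weights."""

    def __init__(self, msa_channels: int, template_channels: int = 100,
                 dk: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.dk = dk
        self.Wq = Param(rng.normal(0, np.sqrt(1.0 / msa_channels),
                                   size=(dk, msa_channels)))
        self.Wk = Param(rng.normal(0, np.sqrt(1.0 / template_channels),
                                   size=(dk, template_channels)))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.Wq, self.Wk]

    def forward(self, msa_embedding: np.ndarray, features: np.ndarray
                ) -> np.ndarray:
        """Weights (N, L, L) from an embedding (C, L, L) and maps (N, L, L, 100).

        Raises if N = 0; the caller must route to FM-only mode instead.
        """
        if features.shape[0] == 0:
            raise ValueError("empty template stack; run FM-only instead")
        N, L = features.shape[0], features.shape[1]
        q = np.tensordot(self.Wq.v, msa_embedding, axes=([1], [0]))  # (dk,L,L)
        # (N, dk, L, L)
        key = np.einsum("dc,nijc->ndij", self.Wk.v, features)
        aug = key + key.mean(axis=3, keepdims=True) + key.mean(axis=2, keepdims=True)
        logits = (q[None] * aug).sum(axis=1) / np.sqrt(self.dk)  # (N,L,L)
        w = softmax(logits, axis=0)
        self._cache = (msa_embedding, features, q, aug, w)
        return w

    def backward_combined(self, dcombined: np.ndarray) -> np.ndarray:
        """Backprop from d(combined map) (100, L, L) through the weighted sum
        and the softmax into the projection weights.  Returns the gradient
        w.r.t. the MSA embedding (callers feeding a frozen trunk discard it).
        """
        msa_embedding, features, q, aug, w = self._cache
        # combined(c,i,j) = sum_k w_k(i,j) F_k(i,j,c)
        dw = np.einsum("cij,nijc->nij", dcombined, features)
        return self.backward_weights(dw)

    def backward_weights(self, dw: np.ndarray) -> np.ndarray:
        msa_embedding, features, q, aug, w = self._cache
        # softmax over template axis
        dlogits = w * (dw - (dw * w).sum(axis=0, keepdims=True))
        scale = 1.0 / np.sqrt(self.dk)
        dq = (dlogits[:, None] * aug).sum(axis=0) * scale        # (dk,L,L)
        daug = dlogits[:, None] * q[None] * scale                # (N,dk,L,L)
        L = daug.shape[2]
        dkey = (daug
                + daug.mean(axis=3, keepdims=True)
                + daug.mean(axis=2, keepdims=True))
        self.Wk.g += np.einsum("ndij,nijc->dc", dkey, features)
        self.Wq.g += np.tensordot(dq, msa_embedding, axes=([1, 2], [1, 2]))
        return np.tensordot(self.Wq.v.T, dq, axes=([1], [0]))


def attention_weights(msa_embedding: np.ndarray, stack: TemplateFeatureStack,
                      module: TemplateAttention | None = None,
                      seed: int = 0) -> np.ndarray:
    """Per-template, per-pair weights (N, L, L), softmax-normalized over N."""
    if module is None:
        module = TemplateAttention(msa_embedding.shape[0],
                                   stack.features.shape[-1],
                                   rng=np.random.default_rng(seed))
    return module.forward(msa_embedding, stack.features)


def combine_templates(features: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pair-wise weighted sum over templates: (N,L,L,100),(N,L,L) -> (L,L,100)."""
    if features.shape[0] != w.shape[0]:
        raise ValueError(
            f"{features.shape[0]} templates but {w.shape[0]} weight maps"
        )
    return np.einsum("nijc,nij->ijc", features, w)
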