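"""Pixel-wise combination of the de novo and template-based posteriors.

For each pair (i, j) the template-based prediction gets weight

    w_TBM(i, j) = sum_k w_k(i, j) * s_k(i, j)

where w_k are the attention weights (normalized over templates) and
s_k(i, j) = (s_k(i) + s_k(j)) / 2 are the pair confidences; the de novo
prediction gets w_FM = 1 - w_TBM.  With no good templates w_TBM is
identically zero and the fused posterior equals the FM posterior bit for
bit.  The same weight map is shared by all four geometry heads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from trxgeom.containers import MSA, GeometryPosterior


@dataclass
class FusionWeights:
    """Per-pair convex weights between TBM and FM predictions."""

    w_tbm: np.ndarray  # (L, L), in [0, 1]

    @property
    def w_fm(self) -> np.ndarray:
        return 1.0 - self.w_tbm


def tbm_weight(w: np.ndarray, s_pair: np.ndarray,
               length: int | None = None) -> FusionWeights:
    """w_TBM = sum_k w_k(i,j) s_k(i,j); empty template set -> all zero.

    ``w`` and ``s_pair`` are (N, L, L); for N = 0 pass ``length``.
    """
    if w.shape[0] == 0:
        if length is None:
            length = w.shape[1] if w.ndim == 3 and w.shape[1] else 0
        if not length:
            raise ValueError("empty template set: provide length")
        return FusionWeights(w_tbm=np.zeros((length, length)))
    if w.shape != s_pair.shape:
        raise ValueError(f"weight shape {w.shape} != confidence shape {s_pair.shape}")
    w_tbm = np.clip((w * s_pair).sum(axis=0), 0.0, 1.0)
    return FusionWeights(w_tbm=w_tbm)


def fuse_posteriors(p_fm: GeometryPosterior, p_tbm: GeometryPosterior,
                    fw: FusionWeights) -> GeometryPosterior:
    """Per-pixel convex combination w_FM * p_FM + w_TBM * p_TBM, per head."""
    if p_fm.length != p_tbm.length or p_fm.length != fw.w_tbm.shape[0]:
        raise ValueError("posterior / weight shapes disagree")
    a = fw.w_fm[:, :, None]
    b = fw.w_tbm[:, :, None]
    return GeometryPosterior(**{
        name: a * p_fm.heads()[name] + b * p_tbm.heads()[name]
        for name in ("dist", "omega", "theta", "phi")
    })


def ensemble_mean(posteriors: Sequence[GeometryPosterior]) -> GeometryPosterior:
    """Per-pixel arithmetic mean of posteriors (mean-ensemble prediction)."""
    if not posteriors:
        raise ValueError("empty posterior list")
    L = posteriors[0].length
    for p in posteriors:
        if p.length != L:
            raise ValueError("posterior shapes disagree")
    return GeometryPosterior(**{
        name: np.mean([p.heads()[name] for p in posteriors], axis=0)
        for name in ("dist", "omega", "theta", "phi")
    })


def select_msa(candidates: Sequence[MSA],
               predict: Callable[[MSA], GeometryPosterior],
               top_per_length: int = 2, min_separation: int = 6) -> int:
    """Pick the alignment whose prediction is most confident in its top
    contacts.

    Each candidate is scored by the mean contact probability over its
    top-scoring ``top_per_length * L`` pairs (i < j, |i - j| >=
    ``min_separation``); ties break to the lowest index.
    """
    from trxgeom.evaluation import contact_probability

    if not candidates:
        raise ValueError("no candidate MSAs")
    scores = []
    for msa in candidates:
        posterior = predict(msa)
        cp = contact_probability(posterior.dist)
        L = posterior.length
        iu, ju = np.triu_indices(L, k=min_separation)
        vals = np.sort(cp[iu, ju])[::-1]
        k = min(top_per_length * L, len(vals))
        scores.append(float(vals[:k].mean()) if k else 0.0)
    return int(np.argmax(scores))
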