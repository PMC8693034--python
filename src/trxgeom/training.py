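"""Training: crop/stitch augmentation, the categorical loss, and the loop.

Memory constraints cap network inputs at 260 residues.  Longer proteins are
reduced per epoch either to one random contiguous window or, to preserve
long-range information, to a stitch of one window from each sequence half;
MSA columns and label rows/columns are sliced by the same index set, so the
labels of a stitched pair are the true geometry of the original protein.
Augmentation and MSA subsampling are re-drawn every epoch.

The dataset splits 95/5 into training/validation (validation size is the
floor of 5%).  Optimization is Adam at batch size 1 (sample lengths vary).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from trxgeom.containers import MSA, GeometryPosterior
from trxgeom.model_res2net import (
    TINY,
    NetworkConfig,
    Res2NetFM,
    Res2NetTBM,
    make_optimizer,
)
from trxgeom.msa_features import featurize, subsample_msa

MAX_TRAIN_LENGTH = 260
HEAD_NAMES = ("dist", "omega", "theta", "phi")


@dataclass
class TrainingTarget:
    """One supervised example: alignment plus binned true geometry."""

    name: str
    msa: MSA
    labels: dict[str, np.ndarray]
    mask: np.ndarray
    templates: object | None = None  # TemplateFeatureStack for TBM training

    @property
    def length(self) -> int:
        return self.msa.length


def from_synthetic(target, with_templates: bool = False) -> TrainingTarget:
    """Adapt a synthetic target for training."""
    stack = None
    if with_templates:
        from trxgeom.template_geometry import build_template_stack

        stack = build_template_stack(target.templates, target.length)
    return TrainingTarget(
        name=target.name,
        msa=target.msa,
        labels=target.labels,
        mask=target.geometry.mask,
        templates=stack,
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def crop_or_stitch(target: TrainingTarget, max_len: int = MAX_TRAIN_LENGTH,
                   rng: np.random.Generator | None = None,
                   stitch_prob: float = 0.5, min_window: int = 64
                   ) -> tuple[TrainingTarget, np.ndarray]:
    """Reduce an over-long sample; returns (sample, original indices).

    Proteins shorter than ``max_len`` pass through unchanged.  Otherwise,
    with probability ``stitch_prob`` two windows -- one from each half of
    the sequence -- are stitched; else a single contiguous window is cut.
    Labels and mask are sliced by the same index set.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    L = target.length
    if L < max_len:
        return target, np.arange(L)
    rng = rng or np.random.default_rng(0)

    budget = max_len - 1  # emitted sample must be strictly shorter
    if rng.random() < stitch_prob:
        half = L // 2
        w1_max = min(half, budget - min_window)
        w1 = int(rng.integers(min_window, w1_max + 1))
        w2_max = min(L - half, budget - w1)
        w2 = int(rng.integers(min_window, max(min_window, w2_max) + 1))
        w2 = min(w2, w2_max)
        s1 = int(rng.integers(0, half - w1 + 1))
        s2 = half + int(rng.integers(0, (L - half) - w2 + 1))
        idx = np.concatenate([np.arange(s1, s1 + w1),
                              np.arange(s2, s2 + w2)])
    else:
        w = int(rng.integers(min_window, min(L, budget) + 1))
        s = int(rng.integers(0, L - w + 1))
        idx = np.arange(s, s + w)

    labels = {k: v[np.ix_(idx, idx)] for k, v in target.labels.items()}
    return (
        replace(
            target,
            msa=target.msa.take_columns(idx),
            labels=labels,
            mask=target.mask[np.ix_(idx, idx)],
            templates=None,
        ),
        idx,
    )


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def geometry_loss(posterior: GeometryPosterior, labels: dict[str, np.ndarray],
                  mask: np.ndarray) -> float:
    """Mean over valid pairs of the summed 4-head negative log-likelihood."""
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("mask selects no valid pairs")
    iu, ju = np.where(mask)
    total = 0.0
    for name in HEAD_NAMES:
        p = posterior.heads()[name][iu, ju, labels[name][iu, ju]]
        total += -np.log(np.maximum(p, 1e-300)).sum()
    return total / n_valid


# ---------------------------------------------------------------------------
# Split and loop
# ---------------------------------------------------------------------------

def split_dataset(n_items: int, val_fraction: float = 0.05,
                  rng: np.random.Generator | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (given rng) shuffled split; validation = floor(5%)."""
    rng = rng or np.random.default_rng(0)
    order = rng.permutation(n_items)
    n_val = int(np.floor(val_fraction * n_items))
    return np.sort(order[n_val:]), np.sort(order[:n_val])


@dataclass
class TrainingHistory:
    train_loss: list[float]
    val_loss: list[float]


def _epoch_features(target: TrainingTarget, rng, subsample: bool,
                    augment: bool, max_len: int, cache: dict, key
                    ) -> tuple[np.ndarray, TrainingTarget]:
    static = not subsample and (not augment or target.length < max_len)
    if static and key in cache:
        return cache[key], target
    sample = target
    if augment and target.length >= max_len:
        sample, _ = crop_or_stitch(target, max_len, rng)
    msa = subsample_msa(sample.msa, rng) if subsample else sample.msa
    feats = featurize(msa)
    if static:
        cache[key] = feats
    return feats, sample


def train_fm(dataset: list[TrainingTarget], config: NetworkConfig = TINY,
             seed: int = 0, epochs: int = 20, lr: float = 1e-3,
             subsample: bool = True, augment: bool = True,
             max_len: int = MAX_TRAIN_LENGTH
             ) -> tuple[Res2NetFM, TrainingHistory]:
    """Train the de novo network; returns (network, per-epoch history)."""
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    net = Res2NetFM(config, seed=seed)
    opt = make_optimizer(net, lr=lr)
    train_idx, val_idx = split_dataset(len(dataset), rng=rng)
    cache: dict = {}
    history = TrainingHistory([], [])
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        losses = []
        for idx in order:
            feats, sample = _epoch_features(
                dataset[idx], rng, subsample, augment, max_len, cache, idx)
            opt.zero_grad()
            loss = net.loss_and_grad(feats, sample.labels, sample.mask)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}, sample "
                    f"{dataset[idx].name!r}: {loss}"
                )
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(
            _validation_loss(net, dataset, val_idx, cache, max_len))
    return net, history


def _validation_loss(net, dataset, val_idx, cache, max_len) -> float:
    if len(val_idx) == 0:
        return float("nan")
    losses = []
    for idx in val_idx:
        target = dataset[idx]
        if target.length >= max_len:
            target, _ = crop_or_stitch(target, max_len,
                                       np.random.default_rng(idx))
        key = ("val", idx)
        if key in cache:
            feats = cache[key]
        else:
            feats = featurize(target.msa)
            cache[key] = feats
        if isinstance(net, Res2NetTBM):
            post, _ = net.forward_with_templates(feats, target.templates)
        else:
            post = net.predict(feats)
        losses.append(geometry_loss(post, target.labels, target.mask))
    return float(np.mean(losses))


def train_tbm(dataset: list[TrainingTarget], fm: Res2NetFM,
              config: NetworkConfig | None = None, seed: int = 1,
              epochs: int = 10, lr: float = 1e-3, subsample: bool = False
              ) -> tuple[Res2NetTBM, TrainingHistory]:
    """Train the template-based network on top of a frozen FM network.

    Every dataset item must carry a template feature stack.  Only the new
    groups, heads and attention projections are updated; the reused FM
    parameters receive no gradients.
    """
    if not dataset:
        raise ValueError("empty dataset")
    for t in dataset:
        if t.templates is None or t.templates.n == 0:
            raise ValueError(f"target {t.name!r} has no usable templates")
    rng = np.random.default_rng(seed)
    net = Res2NetTBM(fm, config, seed=seed)
    opt = make_optimizer(net, lr=lr)
    train_idx, val_idx = split_dataset(len(dataset), rng=rng)
    cache: dict = {}
    history = TrainingHistory([], [])
    for epoch in range(epochs):
        order = rng.permutation(train_idx)
        losses = []
        for idx in order:
            target = dataset[idx]
            msa = subsample_msa(target.msa, rng) if subsample else target.msa
            if not subsample and idx in cache:
                feats = cache[idx]
            else:
                feats = featurize(msa)
                if not subsample:
                    cache[idx] = feats
            opt.zero_grad()
            loss = net.loss_and_grad(feats, target.templates,
                                     target.labels, target.mask)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}, sample "
                    f"{target.name!r}: {loss}"
                )
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(
            _validation_loss(net, dataset, val_idx, cache, MAX_TRAIN_LENGTH))
    return net, history
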