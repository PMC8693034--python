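"""Desk-scale end-to-end experiments on synthetic data.

These are the scaled-down counterparts of the full benchmark protocol:
train the tiny de novo profile on synthetic targets and measure held-out
contact precision against the class contact-density baseline, and check
that a perfect template routed through encoding and fusion yields perfect
contacts.  Problem sizes (150 training + 20 held-out targets of length 48,
MSA depth 30-200) are the package's default fixture conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from trxgeom.evaluation import contact_density, contact_probability, topk_precision
from trxgeom.fusion import fuse_posteriors, tbm_weight
from trxgeom.model_res2net import TINY, NetworkConfig, Res2NetFM, symmetrize
from trxgeom.msa_features import featurize
from trxgeom.synthetic import gen_templates, make_dataset, make_target
from trxgeom.template_geometry import build_template_stack, labels_to_posterior
from trxgeom.training import from_synthetic, train_fm


@dataclass
class LearnabilityResult:
    precision: float        # held-out mean top-L/5 precision, separation >= 12
    baseline: float         # mean contact density of the same class
    ratio: float
    final_train_loss: float
    final_val_loss: float
    n_train: int
    n_test: int


def learnability_experiment(seed: int = 0, n_train: int = 150,
                            n_test: int = 20, L: int = 48,
                            epochs: int = 20, lr: float = 1e-3,
                            config: NetworkConfig = TINY
                            ) -> tuple[LearnabilityResult, Res2NetFM]:
    """Train the tiny FM profile and score held-out top-L/5 contacts.

    MSA subsampling is disabled for this scaled-down run: at fixture depth
    (<= 200 rows) log-uniform subsampling mostly erases the coupling signal
    the experiment is meant to detect.
    """
    train_targets = [
        from_synthetic(t)
        for t in make_dataset(n_train, L=L, seed=seed)
    ]
    test_targets = make_dataset(n_test, L=L, seed=seed + 1_000_003)

    net, history = train_fm(
        train_targets, config=config, seed=seed, epochs=epochs, lr=lr,
        subsample=False, augment=True,
    )

    precisions, densities = [], []
    for target in test_targets:
        feats = featurize(target.msa)
        posterior = symmetrize(net.predict(feats))
        cp = contact_probability(posterior.dist)
        k = max(1, target.length // 5)
        precisions.append(
            topk_precision(cp, target.geometry.d, k, sep="medium_long"))
        densities.append(
            contact_density(target.geometry.d, sep="medium_long"))
    precision = float(np.mean(precisions))
    baseline = float(np.mean(densities))
    return (
        LearnabilityResult(
            precision=precision,
            baseline=baseline,
            ratio=precision / baseline if baseline > 0 else float("inf"),
            final_train_loss=history.train_loss[-1],
            final_val_loss=history.val_loss[-1],
            n_train=n_train,
            n_test=n_test,
        ),
        net,
    )


def template_oracle_precision(seed: int = 0, L: int = 48,
                              n_targets: int = 5) -> float:
    """Top-L contact precision of a noise-free full-coverage template
    routed through encoding, smoothing and fusion with s_k = 1.

    The TBM posterior is the smoothed one-hot of the template's own binned
    geometry; with pair confidences identically 1 the fusion weight is 1
    everywhere, so the fused prediction must reproduce the true contacts
    exactly (precision 1.0).
    """
    precisions = []
    for k in range(n_targets):
        target = make_target(L=L, seed=seed + k, depth=30)
        templates = gen_templates(target.backbone, noise_sd=0.0,
                                  coverage=1.0, n_templates=1,
                                  rng=np.random.default_rng(seed + k))
        stack = build_template_stack(templates, target.length)
        p_tbm = labels_to_posterior(target.labels)
        # single template: attention weight is 1; s_k == 1 by construction
        fw = tbm_weight(np.ones((1, L, L)), np.ones((1, L, L)))
        p_fm = labels_to_posterior(
            {k2: np.zeros_like(v) for k2, v in target.labels.items()})
        fused = fuse_posteriors(p_fm, p_tbm, fw)
        cp = contact_probability(fused.dist)
        precisions.append(
            topk_precision(cp, target.geometry.d, L, sep="medium_long"))
        assert stack.n == 1
    return float(np.mean(precisions))
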