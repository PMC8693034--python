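"""Multi-scale residual networks for inter-residue geometry prediction.

The basic block splits its bottleneck channels into ``s`` subsets (s = 4
throughout) that pass through a hierarchy of 3x3 convolutions::

    y_1 = x_1
    y_2 = K_2(x_2)
    y_i = K_i(x_i + y_{i-1}),  2 < i <= s

and concatenates the outputs before a 1x1 expansion and the residual
addition.  A pre-activation layout is used: every convolution is preceded
by instance normalization and ELU, so a block whose expansion weights are
zero is an exact identity.  No down-sampling anywhere; spatial shape is
preserved.

Two networks share this block:

* the de novo (FM) network: 1x1 input convolution over the 526 MSA-derived
  channels, then the configured groups of blocks, then four 1x1 softmax
  heads (37/25/25/13 bins);
* the template-based (TBM) network: reuses the FM input convolution and its
  first two groups frozen, concatenates their output with the 100-channel
  combined template map, and continues through four newly trained groups
  and its own heads.

The ``full`` profile (4 FM groups, widths 64-512, 50 trunk convolutions)
mirrors the production-scale architecture; the ``tiny`` profile (2 groups,
width 16) is for desk-scale training and tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from trxgeom.containers import GeometryPosterior
from trxgeom.nn import (
    Adam,
    Conv2d,
    ELU,
    Identity,
    InstanceNorm,
    Layer,
    Param,
    Sequential,
    softmax,
)

HEAD_NAMES = ("dist", "omega", "theta", "phi")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture profile.

    ``fm_groups`` / ``tbm_groups`` are tuples of (block count, width); the
    TBM network prepends ``n_reuse_groups`` frozen FM groups to its own.
    """

    fm_groups: tuple = ((2, 16), (2, 16))
    tbm_groups: tuple = ((1, 16), (1, 16), (1, 16), (1, 16))
    scale: int = 4
    dilation_cycle: tuple = (1, 2, 4)
    in_channels: int = 526
    template_channels: int = 100
    attention_dim: int = 8
    head_bins: tuple = (37, 25, 25, 13)
    n_reuse_groups: int = 2


TINY = NetworkConfig()
FULL = NetworkConfig(
    fm_groups=((2, 64), (2, 128), (3, 256), (3, 512)),
    tbm_groups=((2, 64), (2, 128), (3, 256), (3, 512)),
    attention_dim=32,
)


class Res2NetBlock(Layer):
    """One multi-scale residual block (channel count preserved)."""

    def __init__(self, channels: int, scale: int = 4, dilation: int = 1,
                 rng: np.random.Generator | None = None, norm: bool = True,
                 activation: str = "elu"):
        if channels % scale != 0:
            raise ConfigurationError(
                f"channels {channels} not divisible by scale {scale}"
            )
        rng = rng or np.random.default_rng(0)

        def mk_pre(c: int) -> Sequential:
            layers: list[Layer] = []
            if norm:
                layers.append(InstanceNorm(c))
            layers.append(ELU() if activation == "elu" else Identity())
            return Sequential(*layers)

        self.scale = scale
        self.sub = channels // scale
        self.pre = mk_pre(channels)
        self.reduce = Conv2d(channels, channels, 1, rng=rng)
        self.sub_pre = [mk_pre(self.sub) for _ in range(scale - 1)]
        self.convs = [
            Conv2d(self.sub, self.sub, 3, dilation=dilation, rng=rng)
            for _ in range(scale - 1)
        ]
        self.post = mk_pre(channels)
        self.expand = Conv2d(channels, channels, 1, rng=rng)

    def params(self):
        out = self.pre.params() + self.reduce.params()
        for p, c in zip(self.sub_pre, self.convs):
            out += p.params() + c.params()
        return out + self.post.params() + self.expand.params()

    def forward(self, x):
        h = self.reduce(self.pre(x))
        xs = [h[i * self.sub:(i + 1) * self.sub] for i in range(self.scale)]
        ys = [xs[0]]  # y_1 = x_1, untransformed
        for i in range(1, self.scale):
            inp = xs[i] if i == 1 else xs[i] + ys[-1]
            ys.append(self.convs[i - 1](self.sub_pre[i - 1](inp)))
        z = np.concatenate(ys, axis=0)
        return x + self.expand(self.post(z))

    def backward(self, dy):
        dz = self.post.backward(self.expand.backward(dy))
        dys = [dz[i * self.sub:(i + 1) * self.sub].copy()
               for i in range(self.scale)]
        dxs: list[np.ndarray | None] = [None] * self.scale
        for i in range(self.scale - 1, 0, -1):
            dinp = self.sub_pre[i - 1].backward(self.convs[i - 1].backward(dys[i]))
            dxs[i] = dinp
            if i >= 2:
                dys[i - 1] += dinp
        dxs[0] = dys[0]
        dh = np.concatenate(dxs, axis=0)
        return dy + self.pre.backward(self.reduce.backward(dh))


class Res2NetGroup(Layer):
    """A width transition (1x1 projection if needed) plus a run of blocks
    with dilations cycling through the configured schedule."""

    def __init__(self, cin: int, width: int, n_blocks: int, scale: int,
                 dilation_cycle: tuple, rng: np.random.Generator):
        self.proj: Layer = (
            Conv2d(cin, width, 1, rng=rng) if cin != width else Identity()
        )
        self.blocks = [
            Res2NetBlock(width, scale,
                         dilation_cycle[b % len(dilation_cycle)], rng)
            for b in range(n_blocks)
        ]
        self.width = width

    def params(self):
        out = self.proj.params()
        for blk in self.blocks:
            out += blk.params()
        return out

    def forward(self, x):
        x = self.proj(x)
        for blk in self.blocks:
            x = blk.forward(x)
        return x

    def backward(self, dy):
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        return self.proj.backward(dy)


def categorical_loss_grad(logits: np.ndarray, labels: np.ndarray,
                          mask: np.ndarray, n_valid: int):
    """Masked cross-entropy of one head; returns (nll_sum, dlogits)."""
    p = softmax(logits, axis=0)
    idx_i, idx_j = np.where(mask)
    nll = -np.log(np.maximum(p[labels[idx_i, idx_j], idx_i, idx_j], 1e-300)).sum()
    grad = p * mask[None, :, :]
    grad[labels[idx_i, idx_j], idx_i, idx_j] -= 1.0
    return nll, grad / n_valid


class Res2NetFM:
    """De novo geometry-prediction network over the 526-channel MSA tensor."""

    def __init__(self, config: NetworkConfig = TINY, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        widths = [w for _, w in config.fm_groups]
        self.conv_in = Conv2d(config.in_channels, widths[0], 1, rng=rng)
        self.groups: list[Res2NetGroup] = []
        prev = widths[0]
        for n_blocks, w in config.fm_groups:
            self.groups.append(Res2NetGroup(
                prev, w, n_blocks, config.scale, config.dilation_cycle, rng))
            prev = w
        self.final = Sequential(InstanceNorm(prev), ELU())
        self.heads = {
            name: Conv2d(prev, nb, 1, rng=rng)
            for name, nb in zip(HEAD_NAMES, config.head_bins)
        }
        self.trunk_width = prev

    # -- parameter plumbing -------------------------------------------

    def parameters(self) -> list[Param]:
        out = self.conv_in.params()
        for g in self.groups:
            out += g.params()
        out += self.final.params()
        for name in HEAD_NAMES:
            out += self.heads[name].params()
        return out

    def reused_parameters(self) -> list[Param]:
        """Parameters shared (frozen) with the TBM network: the input
        convolution and the first ``n_reuse_groups`` groups."""
        out = self.conv_in.params()
        for g in self.groups[:self.config.n_reuse_groups]:
            out += g.params()
        return out

    @property
    def reuse_width(self) -> int:
        k = min(self.config.n_reuse_groups, len(self.groups)) - 1
        return self.groups[k].width

    def trunk_filter_counts(self) -> list[int]:
        """Output filter counts of each trunk convolution layer.

        The s-1 subset convolutions of a block jointly produce the block's
        bottleneck width and are counted as one split-convolution layer.
        Heads (task classifiers) are excluded.
        """
        counts = [self.conv_in.cout]
        for g in self.groups:
            if isinstance(g.proj, Conv2d):
                counts.append(g.proj.cout)
            for blk in g.blocks:
                counts.extend([blk.reduce.cout, blk.sub * blk.scale,
                               blk.expand.cout])
        return counts

    def n_conv_layers(self) -> int:
        """Total trunk convolution count, each subset convolution counted
        individually (the depth accounting behind the ~50-layer profile)."""
        n = 1  # input conv
        for g in self.groups:
            if isinstance(g.proj, Conv2d):
                n += 1
            for blk in g.blocks:
                n += 2 + len(blk.convs)
        return n

    # -- forward / backward -------------------------------------------

    def trunk_forward(self, features: np.ndarray, upto: int | None = None
                      ) -> np.ndarray:
        """Run input conv + the first ``upto`` groups; (L,L,526) -> (C,L,L)."""
        if features.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} feature channels, "
                f"got {features.shape[-1]}"
            )
        x = np.ascontiguousarray(features.transpose(2, 0, 1))
        x = self.conv_in(x)
        for g in self.groups[:upto]:
            x = g.forward(x)
        return x

    def forward(self, features: np.ndarray
                ) -> tuple[GeometryPosterior, np.ndarray]:
        """Posterior plus the intermediate map after the reused groups."""
        x = self.trunk_forward(features, upto=self.config.n_reuse_groups)
        intermediate = x
        for g in self.groups[self.config.n_reuse_groups:]:
            x = g.forward(x)
        h = self.final(x)
        self._head_logits = {name: self.heads[name](h) for name in HEAD_NAMES}
        post = GeometryPosterior(**{
            name: softmax(self._head_logits[name], axis=0).transpose(1, 2, 0)
            for name in HEAD_NAMES
        })
        return post, intermediate

    def predict(self, features: np.ndarray) -> GeometryPosterior:
        return self.forward(features)[0]

    def loss_and_grad(self, features: np.ndarray, labels: dict[str, np.ndarray],
                      mask: np.ndarray) -> float:
        """Forward + backward of the masked 4-head cross-entropy.

        Gradients accumulate into the parameters; call ``zero_grad`` on the
        optimizer first.
        """
        n_valid = int(mask.sum())
        if n_valid == 0:
            raise ValueError("mask selects no valid pairs")
        self.forward(features)  # leaves every layer cache in place
        total = 0.0
        dh = None
        for name in HEAD_NAMES:
            nll, dlogits = categorical_loss_grad(
                self._head_logits[name], labels[name], mask, n_valid)
            total += nll
            dhead = self.heads[name].backward(dlogits)
            dh = dhead if dh is None else dh + dhead
        dx = self.final.backward(dh)
        for g in reversed(self.groups):
            dx = g.backward(dx)
        self.conv_in.backward(dx)
        return total / n_valid


class Res2NetTBM:
    """Template-based network: frozen FM front end + attention-fused
    template features + four newly trained groups.

    Counting the reused FM groups, the network consists of six groups of
    blocks; only the four new groups (plus the attention projections and
    heads) receive gradient updates.
    """

    def __init__(self, fm: Res2NetFM, config: NetworkConfig | None = None,
                 seed: int = 1):
        from trxgeom.template_attention import TemplateAttention

        self.fm = fm
        self.config = config or fm.config
        cfg = self.config
        rng = np.random.default_rng(seed)
        self.attention = TemplateAttention(
            fm.reuse_width, cfg.template_channels, cfg.attention_dim, rng)
        cin = fm.reuse_width + cfg.template_channels
        widths = [w for _, w in cfg.tbm_groups]
        self.conv_in = Conv2d(cin, widths[0], 1, rng=rng)
        self.groups = [
            Res2NetGroup(
                widths[max(0, k - 1)] if k else widths[0], w, n_blocks,
                cfg.scale, cfg.dilation_cycle, rng)
            for k, (n_blocks, w) in enumerate(cfg.tbm_groups)
        ]
        prev = widths[-1]
        self.final = Sequential(InstanceNorm(prev), ELU())
        self.heads = {
            name: Conv2d(prev, nb, 1, rng=rng)
            for name, nb in zip(HEAD_NAMES, cfg.head_bins)
        }

    @property
    def n_groups_total(self) -> int:
        """Reused FM groups plus newly constructed groups."""
        return self.config.n_reuse_groups + len(self.groups)

    def parameters(self) -> list[Param]:
        """Trainable parameters only; the reused FM groups are frozen."""
        out = self.attention.params()
        out += self.conv_in.params()
        for g in self.groups:
            out += g.params()
        out += self.final.params()
        for name in HEAD_NAMES:
            out += self.heads[name].params()
        return out

    def forward(self, features: np.ndarray, combined: np.ndarray
                ) -> GeometryPosterior:
        """Posterior from MSA features and an already combined (L,L,100)
        template map."""
        g2 = self.fm.trunk_forward(features, upto=self.config.n_reuse_groups)
        if combined.shape[:2] != features.shape[:2]:
            raise ValueError(
                f"template map L {combined.shape[:2]} does not match "
                f"features L {features.shape[:2]}"
            )
        x = np.concatenate(
            [g2, np.ascontiguousarray(combined.transpose(2, 0, 1))], axis=0)
        self._split = g2.shape[0]
        x = self.conv_in(x)
        for g in self.groups:
            x = g.forward(x)
        h = self.final(x)
        self._head_logits = {name: self.heads[name](h) for name in HEAD_NAMES}
        return GeometryPosterior(**{
            name: softmax(self._head_logits[name], axis=0).transpose(1, 2, 0)
            for name in HEAD_NAMES
        })

    def forward_with_templates(self, features: np.ndarray, stack
                               ) -> tuple[GeometryPosterior, np.ndarray]:
        """Attention-combine a template stack, then predict.

        Returns (posterior, attention weights (N,L,L)).
        """
        from trxgeom.template_attention import combine_templates

        g2 = self.fm.trunk_forward(features, upto=self.config.n_reuse_groups)
        w = self.attention.forward(g2, stack.features)
        combined = combine_templates(stack.features, w)
        self._g2 = g2
        post = self.forward(features, combined)
        return post, w

    def loss_and_grad(self, features: np.ndarray, stack,
                      labels: dict[str, np.ndarray], mask: np.ndarray) -> float:
        """One training forward/backward; gradients reach only the new
        groups, heads and attention projections.  The reused FM parameters
        receive no gradient at all."""
        n_valid = int(mask.sum())
        if n_valid == 0:
            raise ValueError("mask selects no valid pairs")
        self.forward_with_templates(features, stack)
        total = 0.0
        dh = None
        for name in HEAD_NAMES:
            nll, dlogits = categorical_loss_grad(
                self._head_logits[name], labels[name], mask, n_valid)
            total += nll
            dhead = self.heads[name].backward(dlogits)
            dh = dhead if dh is None else dh + dhead
        dx = self.final.backward(dh)
        for g in reversed(self.groups):
            dx = g.backward(dx)
        dcat = self.conv_in.backward(dx)
        dcombined = dcat[self._split:]  # gradient into the template pathway
        self.attention.backward_combined(dcombined)
        # dcat[:split] is the gradient toward the frozen FM trunk; dropped.
        return total / n_valid


# ---------------------------------------------------------------------------
# Functional wrappers and utilities
# ---------------------------------------------------------------------------

def forward_fm(features: np.ndarray, net: Res2NetFM
               ) -> tuple[GeometryPosterior, np.ndarray]:
    return net.forward(features)


def forward_tbm(features: np.ndarray, combined: np.ndarray,
                net: Res2NetTBM) -> GeometryPosterior:
    return net.forward(features, combined)


def symmetrize(posterior: GeometryPosterior) -> GeometryPosterior:
    """Average the symmetric heads (d, omega) with their transposes.

    theta and phi are directional and left untouched; normalization is
    preserved because the operation is an average of two distributions.
    """
    return GeometryPosterior(
        dist=(posterior.dist + posterior.dist.transpose(1, 0, 2)) / 2.0,
        omega=(posterior.omega + posterior.omega.transpose(1, 0, 2)) / 2.0,
        theta=posterior.theta.copy(),
        phi=posterior.phi.copy(),
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _config_to_json(config: NetworkConfig) -> str:
    return json.dumps(dataclasses.asdict(config))


def _config_from_json(blob: str) -> NetworkConfig:
    raw = json.loads(blob)
    for key in ("fm_groups", "tbm_groups"):
        raw[key] = tuple(tuple(g) for g in raw[key])
    raw["dilation_cycle"] = tuple(raw["dilation_cycle"])
    raw["head_bins"] = tuple(raw["head_bins"])
    return NetworkConfig(**raw)


def save_checkpoint(net: Res2NetFM | Res2NetTBM, path) -> None:
    """Named-parameter archive with the embedded architecture config."""
    arrays = {f"p{i}": p.v for i, p in enumerate(net.parameters())}
    arrays["config"] = np.frombuffer(
        _config_to_json(net.config).encode(), dtype=np.uint8)
    arrays["kind"] = np.frombuffer(
        (b"tbm" if isinstance(net, Res2NetTBM) else b"fm"), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def _assign(net, archive) -> None:
    for i, p in enumerate(net.parameters()):
        val = archive[f"p{i}"]
        if val.shape != p.v.shape:
            raise ValueError("checkpoint does not match architecture")
        p.v = val.astype(np.float64)


def load_fm(path) -> Res2NetFM:
    with np.load(path) as archive:
        config = _config_from_json(bytes(archive["config"]).decode())
        net = Res2NetFM(config)
        _assign(net, archive)
    return net


def load_tbm(path, fm: Res2NetFM) -> Res2NetTBM:
    with np.load(path) as archive:
        config = _config_from_json(bytes(archive["config"]).decode())
        net = Res2NetTBM(fm, config)
        _assign(net, archive)
    return net


def make_optimizer(net, lr: float = 1e-3) -> Adam:
    return Adam(net.parameters(), lr=lr)
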