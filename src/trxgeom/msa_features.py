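"""MSA feature engineering: the 526-channel input tensor of the de novo net.

Channel layout of the pair tensor (L, L, 526):

* ``[0, 42)``   1D features of residue i, tiled along j
* ``[42, 84)``  1D features of residue j, tiled along i
* ``[84, 525)`` 441 coupling channels: the negated off-diagonal 21x21 block
  of the shrunken inverse covariance of the one-hot encoded alignment
* ``[525]``     APC-corrected Frobenius coupling norm (symmetric)

The 1D block per position is 20 one-hot channels of the query residue,
21 weighted frequency channels (20 amino acids + gap, additive pseudocount),
and 1 positional entropy channel.  The decomposition 2*42 + 441 + 1 = 526 is
this package's reconstruction of the published channel total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from trxgeom.alphabet import N_STATES
from trxgeom.containers import MSA

N_1D_CHANNELS = 42
N_COUPLING_CHANNELS = N_STATES * N_STATES  # 441
N_CHANNELS = 2 * N_1D_CHANNELS + N_COUPLING_CHANNELS + 1  # 526


@dataclass
class SequenceWeights:
    """Identity-based sequence reweighting; Neff is the effective depth."""

    w: np.ndarray  # (N_seq,), each in (0, 1]

    @property
    def neff(self) -> float:
        return float(self.w.sum())


def sequence_weights(msa: MSA, identity_cutoff: float = 0.8) -> SequenceWeights:
    """w_n = 1 / #{m : identity(n, m) >= cutoff}, self included.

    Pairwise identity is the fraction of positions with equal states over
    the full alignment length (gap treated as a state).
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError(f"identity cutoff {identity_cutoff} outside (0, 1]")
    X = msa.encoded()
    n, L = X.shape
    # pairwise identity via chunked comparisons; desk-scale depths are small
    counts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        ident = (X == X[i]).mean(axis=1)
        counts[i] = int((ident >= identity_cutoff).sum())
    return SequenceWeights(w=1.0 / counts)


def profile_and_entropy(
    msa: MSA,
    weights: SequenceWeights | None = None,
    pseudocount: float | None = None,
) -> np.ndarray:
    """Per-position 1D features: (L, 42) = 20 query one-hot + 21 PSSM + entropy.

    Frequencies use the sequence weights and an additive pseudocount c:
    f = (f0 + c) / (1 + 21 c), where f0 is the weighted frequency.  The
    default pseudocount is 1/N_seq.  Entropy is -sum f ln f over 21 states,
    so it lies in [0, ln 21].
    """
    L = msa.length
    if L == 0:
        raise ValueError("empty MSA")
    if weights is None:
        weights = sequence_weights(msa)
    if pseudocount is None:
        pseudocount = 1.0 / msa.depth
    X = msa.encoded()
    w = weights.w

    onehot = np.zeros((L, 20))
    q = X[0]
    valid = q < 20
    onehot[np.arange(L)[valid], q[valid]] = 1.0

    # weighted frequencies over the 21 states
    freq = np.zeros((L, N_STATES))
    for s in range(N_STATES):
        freq[:, s] = (w[:, None] * (X == s)).sum(axis=0)
    freq /= freq.sum(axis=1, keepdims=True)
    freq = (freq + pseudocount) / (1.0 + N_STATES * pseudocount)

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log(freq), 0.0)
    entropy = -plogp.sum(axis=1)

    return np.concatenate([onehot, freq, entropy[:, None]], axis=1)


def couplings(
    msa: MSA,
    weights: SequenceWeights | None = None,
    shrinkage: float | None = None,
) -> np.ndarray:
    """Inverse-covariance coupling features, (L, L, 442).

    The 21L-dimensional one-hot encoding's weighted covariance is shrunk by
    adding ``shrinkage`` to its diagonal (default 4.5 / sqrt(Neff)) and
    inverted; channel block (i, j) is the negated off-diagonal 21x21 block
    of the precision matrix, and the last channel is the APC-corrected
    Frobenius norm over the 20x20 non-gap sub-block.  A single-sequence MSA
    returns all-zero coupling channels.
    """
    L = msa.length
    out = np.zeros((L, L, N_COUPLING_CHANNELS + 1))
    if msa.depth < 2:
        return out
    if weights is None:
        weights = sequence_weights(msa)
    w = weights.w / weights.w.sum()
    if shrinkage is None:
        shrinkage = 4.5 / np.sqrt(weights.neff)
    if shrinkage < 0:
        raise ValueError("shrinkage must be nonnegative")

    X = msa.encoded()
    n = msa.depth
    onehot = np.zeros((n, L * N_STATES))
    cols = np.arange(L) * N_STATES
    onehot[np.arange(n)[:, None], cols[None, :] + X] = 1.0

    mu = w @ onehot
    centered = onehot - mu
    cov = (centered * w[:, None]).T @ centered
    cov[np.diag_indices_from(cov)] += shrinkage

    try:
        chol = cho_factor(cov)
        prec = cho_solve(chol, np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "covariance not positive definite; increase shrinkage"
        ) from exc

    blocks = prec.reshape(L, N_STATES, L, N_STATES).transpose(0, 2, 1, 3)
    coupling = -blocks
    out[:, :, :N_COUPLING_CHANNELS] = coupling.reshape(L, L, -1)

    # Frobenius norm over the non-gap 20x20 sub-block, then APC
    sub = blocks[:, :, :20, :20]
    S = np.sqrt((sub ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    out[:, :, -1] = apc(S)
    return out


def apc(S: np.ndarray) -> np.ndarray:
    """Average-product correction S_ij - S_i. * S_.j / S_.. (diagonal zeroed).

    Means are taken over off-diagonal entries.
    """
    L = S.shape[0]
    if L < 2:
        return np.zeros_like(S)
    off = ~np.eye(L, dtype=bool)
    row_mean = (S * off).sum(axis=1) / (L - 1)
    total_mean = (S * off).sum() / (L * (L - 1))
    if total_mean == 0:
        corrected = np.zeros_like(S)
    else:
        corrected = S - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    return corrected


def assemble_input_tensor(f1d: np.ndarray, f2d: np.ndarray) -> np.ndarray:
    """Tile 1D features and stack pair features into the (L, L, 526) tensor."""
    L = f1d.shape[0]
    if f1d.shape != (L, N_1D_CHANNELS):
        raise ValueError(f"1D features have shape {f1d.shape}, expected ({L}, 42)")
    if f2d.shape != (L, L, N_COUPLING_CHANNELS + 1):
        raise ValueError(
            f"pair features have shape {f2d.shape}, expected ({L}, {L}, 442)"
        )
    tensor = np.empty((L, L, N_CHANNELS))
    tensor[:, :, :N_1D_CHANNELS] = f1d[:, None, :]
    tensor[:, :, N_1D_CHANNELS:2 * N_1D_CHANNELS] = f1d[None, :, :]
    tensor[:, :, 2 * N_1D_CHANNELS:] = f2d
    return tensor


def featurize(msa: MSA, identity_cutoff: float = 0.8,
              pseudocount: float | None = None,
              shrinkage: float | None = None) -> np.ndarray:
    """Full pipeline MSA -> (L, L, 526) input tensor."""
    weights = sequence_weights(msa, identity_cutoff)
    f1d = profile_and_entropy(msa, weights, pseudocount)
    f2d = couplings(msa, weights, shrinkage)
    return assemble_input_tensor(f1d, f2d)


def subsample_msa(msa: MSA, rng: np.random.Generator) -> MSA:
    """Log-uniform MSA subsampling; the query row is always retained.

    Draws k = max(1, round(10^u)) with u ~ Uniform(0, log10 N_seq) and keeps
    the query plus k-1 further rows without replacement.
    """
    n = msa.depth
    if n <= 1:
        return msa
    u = rng.uniform(0.0, np.log10(n))
    k = min(n, max(1, int(round(10.0 ** u))))
    if k >= n:
        return msa
    others = 1 + rng.choice(n - 1, size=k - 1, replace=False)
    return msa.subset([0] + sorted(others.tolist()))
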