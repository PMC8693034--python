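"""Distance-geometry realization of predicted restraints.

A deliberately simplified stand-in for restraint-guided folding by energy
minimization: the predicted distance distributions are reduced to expected
Cb-Cb distances on confidently contacting pairs, the partial distance
matrix is completed by shortest paths, embedded by classical
multidimensional scaling, and polished by minimizing the masked quadratic
stress.  Orientation restraints are not used.  The decoy protocol mirrors
the coarse-grained search: 120 randomized embeddings, the 5 lowest-stress
models refined further, the single lowest-stress model returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from trxgeom.geometry_spec import DEFAULT_SPEC, GeometrySpec


@dataclass
class DistanceRestraints:
    """Expected distances (A) with a mask of restrained pairs."""

    expected: np.ndarray  # (L, L)
    mask: np.ndarray      # (L, L) bool; False = unrestrained


def expected_distance(p_dist: np.ndarray, tau: float = 0.5,
                      spec: GeometrySpec = DEFAULT_SPEC) -> DistanceRestraints:
    """Expected bin-midpoint distance on pairs with P(no contact) <= tau.

    The expectation renormalizes over the 36 contact bins; pairs whose
    no-contact probability exceeds tau are unrestrained.  The diagonal is
    never restrained.
    """
    if p_dist.shape[-1] != spec.n_dist_bins:
        raise ValueError(
            f"expected {spec.n_dist_bins} distance bins, got {p_dist.shape[-1]}"
        )
    L = p_dist.shape[0]
    mids = spec.dist_bin_midpoints()
    p_contact_bins = p_dist[:, :, 1:]
    norm = p_contact_bins.sum(axis=-1)
    mask = (p_dist[:, :, 0] <= tau) & (norm > 0)
    mask &= ~np.eye(L, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = (p_contact_bins * mids).sum(axis=-1) / norm
    exp = np.where(mask, exp, 0.0)
    # symmetrize for safety: restraints act on unordered pairs
    mask = mask | mask.T
    exp = np.where(exp > 0, exp, exp.T)
    exp = (exp + exp.T) / 2.0
    return DistanceRestraints(expected=exp, mask=mask)


def _stress_and_grad(flat: np.ndarray, iu, ju, target: np.ndarray):
    X = flat.reshape(-1, 3)
    diff = X[iu] - X[ju]
    dist = np.sqrt((diff ** 2).sum(axis=1))
    dist = np.maximum(dist, 1e-9)
    resid = dist - target
    stress = float((resid ** 2).sum())
    coef = (2.0 * resid / dist)[:, None] * diff
    grad = np.zeros_like(X)
    np.add.at(grad, iu, coef)
    np.add.at(grad, ju, -coef)
    return stress, grad.ravel()


def stress(coords: np.ndarray, restraints: DistanceRestraints) -> float:
    """Masked quadratic stress sum_{i<j restrained} (|xi-xj| - d_ij)^2."""
    iu, ju = np.where(np.triu(restraints.mask, k=1))
    value, _ = _stress_and_grad(coords.ravel(), iu, ju,
                                restraints.expected[iu, ju])
    return value


def _classical_mds(D: np.ndarray, ndim: int = 3) -> np.ndarray:
    L = D.shape[0]
    J = np.eye(L) - np.ones((L, L)) / L
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:ndim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def embed(restraints: DistanceRestraints,
          rng: np.random.Generator | None = None,
          init: np.ndarray | None = None,
          maxiter: int = 300) -> tuple[np.ndarray, float]:
    """Embed restraints into 3D coordinates; returns (coords, final stress).

    The restrained-pair graph must be connected: missing distances are
    completed by graph shortest paths before classical MDS, then the masked
    stress is minimized by L-BFGS.  The result's stress never exceeds the
    stress of its MDS initialization.
    """
    L = restraints.expected.shape[0]
    mask = np.triu(restraints.mask, k=1)
    iu, ju = np.where(mask)
    if len(iu) == 0:
        raise ValueError("no restrained pairs")
    graph = csr_matrix(
        (restraints.expected[iu, ju], (iu, ju)), shape=(L, L))
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"restraint graph has {n_comp} components; cannot embed"
        )
    if init is None:
        D = shortest_path(graph, directed=False)
        init = _classical_mds(D)
        if rng is not None:
            init = init + rng.normal(0.0, 0.1, size=init.shape)
    target = restraints.expected[iu, ju]
    res = minimize(
        _stress_and_grad, init.ravel(), args=(iu, ju, target),
        jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    init_stress, _ = _stress_and_grad(init.ravel(), iu, ju, target)
    if res.fun <= init_stress:
        return res.x.reshape(L, 3), float(res.fun)
    return init, float(init_stress)


def decoy_protocol(restraints: DistanceRestraints, n_decoys: int = 120,
                   n_keep: int = 5, rng: np.random.Generator | None = None,
                   maxiter_decoy: int = 60, maxiter_refine: int = 500
                   ) -> tuple[np.ndarray, float]:
    """Decoy search: many cheap embeddings, refine the best few.

    ``n_decoys`` randomized embeddings are generated (the first from the
    deterministic MDS start, the rest from jittered or random starts); the
    ``n_keep`` lowest-stress decoys receive extra refinement iterations and
    the single lowest-stress model is returned.
    """
    if n_decoys < 1:
        raise ValueError("need at least one decoy")
    if n_keep > n_decoys:
        raise ValueError("n_keep cannot exceed n_decoys")
    rng = rng or np.random.default_rng(0)
    L = restraints.expected.shape[0]

    decoys: list[tuple[float, np.ndarray]] = []
    coords0, s0 = embed(restraints, rng=None, maxiter=maxiter_decoy)
    decoys.append((s0, coords0))
    scale = max(1.0, float(restraints.expected[restraints.mask].mean()))
    for _ in range(n_decoys - 1):
        if rng.random() < 0.5:
            init = coords0 + rng.normal(0.0, 1.0, size=(L, 3))
        else:
            init = rng.normal(0.0, scale / 2.0, size=(L, 3))
        c, s = embed(restraints, init=init, maxiter=maxiter_decoy)
        decoys.append((s, c))

    decoys.sort(key=lambda t: t[0])
    best: tuple[float, np.ndarray] | None = None
    for s, c in decoys[:n_keep]:
        c2, s2 = embed(restraints, init=c, maxiter=maxiter_refine)
        if s2 > s:
            c2, s2 = c, s
        if best is None or s2 < best[0]:
            best = (s2, c2)
    return best[1], best[0]


def superposed_rmsd(a: np.ndarray, b: np.ndarray,
                    allow_reflection: bool = True) -> float:
    """RMSD after optimal superposition (Kabsch).

    Distance-geometry embeddings are defined only up to rigid motion and
    possibly a mirror flip, so by default the better of the proper and
    improper alignments is reported.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    H = a.T @ b
    U, S, Vt = np.linalg.svd(H)

    def _rmsd(det_sign: float) -> float:
        D = np.diag([1.0, 1.0, det_sign])
        R = Vt.T @ D @ U.T
        return float(np.sqrt(((a @ R.T - b) ** 2).sum(axis=1).mean()))

    proper = _rmsd(np.sign(np.linalg.det(Vt.T @ U.T)))
    if not allow_reflection:
        return proper
    return min(proper, _rmsd(-np.sign(np.linalg.det(Vt.T @ U.T))))
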