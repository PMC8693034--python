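"""Pairwise geometry from coordinates and 100-channel template encoding.

Geometries per residue pair (i, j):

* d(i,j)      = |CB_i - CB_j|                      (symmetric)
* omega(i,j)  = dihedral(CA_i, CB_i, CB_j, CA_j)   (symmetric)
* theta(i,j)  = dihedral(N_i, CA_i, CB_i, CB_j)    (asymmetric)
* phi(i,j)    = angle(CA_i, CB_i, CB_j)            (asymmetric)

Glycine (or any residue without a CB) uses a virtual CB built from N, CA, C
with the standard ideal-geometry linear combination.
"""

from __future__ import annotations

import numpy as np

from trxgeom.containers import BackboneStructure, GeometryMaps, TemplateHit
from trxgeom.geometry_spec import DEFAULT_SPEC, GeometrySpec

# Ideal-geometry coefficients for CB = CA + c1*a + c2*b + c3*c with
# b = CA - N, c = C - CA, a = b x c.
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place a virtual CB from backbone N, CA, C coordinates.

    Accepts single points (3,) or arrays (..., 3).  Raises on (near-)
    collinear inputs, where the cross product degenerates.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    norms = np.linalg.norm(a, axis=-1)
    if np.any(norms < 1e-8):
        raise ValueError("collinear N, CA, C: virtual CB undefined")
    c1, c2, c3 = _CB_COEFF
    return ca + c1 * a + c2 * b + c3 * cc


def effective_cb(structure: BackboneStructure) -> np.ndarray:
    """Real CB where present, virtual CB elsewhere (needs N and C there)."""
    cb = structure.cb.copy()
    missing = np.isnan(cb).any(axis=1)
    for i in np.where(missing)[0]:
        if np.isnan(structure.n[i]).any() or np.isnan(structure.c[i]).any():
            continue  # stays NaN; masked downstream
        cb[i] = virtual_cbeta(structure.n[i], structure.ca[i], structure.c[i])
    return cb


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle in degrees, in [-180, 180); broadcasts."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = (n1 * n2).sum(axis=-1)
    y = (np.cross(n1, n2)
         * (b1 / np.linalg.norm(b1, axis=-1, keepdims=True))).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.mod(ang + 180.0, 360.0) - 180.0


def planar_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Angle at p1 in degrees, in [0, 180]; broadcasts."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    dot = (v1 * v2).sum(axis=-1)
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def compute_geometries(structure: BackboneStructure) -> GeometryMaps:
    """d/omega/theta/phi maps of a backbone (virtual CB where needed)."""
    L = len(structure)
    if L < 2:
        raise ValueError("need at least two residues")
    cb = effective_cb(structure)
    ca, n = structure.ca, structure.n

    have_cb = ~np.isnan(cb).any(axis=1)
    have_n = ~np.isnan(n).any(axis=1)
    mask = have_cb[:, None] & have_cb[None, :]
    mask &= ~np.eye(L, dtype=bool)

    diff = cb[:, None, :] - cb[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)

    cb_f = np.where(have_cb[:, None], cb, 0.0)
    ca_i = np.broadcast_to(ca[:, None, :], (L, L, 3))
    ca_j = np.broadcast_to(ca[None, :, :], (L, L, 3))
    cb_i = np.broadcast_to(cb_f[:, None, :], (L, L, 3))
    cb_j = np.broadcast_to(cb_f[None, :, :], (L, L, 3))
    n_i = np.broadcast_to(np.where(have_n[:, None], n, 0.0)[:, None, :], (L, L, 3))

    eye = np.eye(L, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = dihedral(ca_i, cb_i, cb_j, ca_j)
        theta = dihedral(n_i, ca_i, cb_i, cb_j)
        phi = planar_angle(ca_i, cb_i, cb_j)
    for arr in (omega, theta, phi):
        arr[eye] = 0.0
        np.nan_to_num(arr, copy=False)

    theta_mask = mask & have_n[:, None]
    full_mask = mask.copy()
    full_mask &= theta_mask  # one shared mask: all four defined
    return GeometryMaps(d=d, omega=omega, theta=theta, phi=phi, mask=full_mask)


def bin_geometries(maps: GeometryMaps,
                   spec: GeometrySpec = DEFAULT_SPEC) -> dict[str, np.ndarray]:
    """Discretize geometry maps into four (L, L) label maps.

    Pairs with d >= 20 A, invalid pairs and the diagonal get label 0 in all
    four channel groups (shared no-contact convention).
    """
    contact = maps.mask & (maps.d < spec.d_max)
    labels = {
        "dist": spec.dist_labels(maps.d),
        "omega": spec.signed_angle_labels(maps.omega),
        "theta": spec.signed_angle_labels(maps.theta),
        "phi": spec.planar_angle_labels(maps.phi),
    }
    for arr in labels.values():
        arr[~contact] = 0
    return labels


def encode_template(
    labels: dict[str, np.ndarray],
    hit: TemplateHit,
    query_length: int,
    spec: GeometrySpec = DEFAULT_SPEC,
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode a template's binned geometry onto query indexing.

    Returns ``(features, s_pair)`` with ``features`` of shape (L, L, 100)
    and ``s_pair`` the (L, L) pair confidences s_k(i,j) = (s_k(i)+s_k(j))/2,
    using s_k = 0 at unaligned positions.  Pairs with either endpoint
    unaligned are all-zero in every channel.
    """
    L_t = labels["dist"].shape[0]
    q_idx = np.asarray([q - 1 for q, _ in hit.aligned_pairs], dtype=np.int64)
    t_idx = np.asarray([t - 1 for _, t in hit.aligned_pairs], dtype=np.int64)
    if len(q_idx) and (q_idx.min() < 0 or q_idx.max() >= query_length):
        raise ValueError(
            f"hit {hit.template_id!r}: query positions outside 1..{query_length}"
        )
    if len(t_idx) and (t_idx.min() < 0 or t_idx.max() >= L_t):
        raise ValueError(
            f"hit {hit.template_id!r}: template positions outside 1..{L_t}"
        )

    nb = [spec.n_dist_bins, spec.n_omega_bins, spec.n_theta_bins, spec.n_phi_bins]
    offsets = np.cumsum([0] + nb[:-1])
    features = np.zeros((query_length, query_length, spec.n_template_channels))

    qi = q_idx[:, None]
    qj = q_idx[None, :]
    ti = t_idx[:, None]
    tj = t_idx[None, :]
    for name, off in zip(("dist", "omega", "theta", "phi"), offsets):
        lab = labels[name][ti, tj]
        features[qi, qj, off + lab] = 1.0

    s1 = np.zeros(query_length)
    for q, _ in hit.aligned_pairs:
        s1[q - 1] = hit.confidence.get(q, 0.0)
    s_pair = (s1[:, None] + s1[None, :]) / 2.0
    return features, s_pair


def filter_and_rank_templates(hits: list[TemplateHit],
                              n_max: int = 10) -> list[TemplateHit]:
    """Keep good templates (probability > 60% or E-value < 0.001), top n_max.

    Hits arrive in search-rank order and that order is preserved.  An empty
    result signals FM-only mode.
    """
    good = [h for h in hits if h.probability > 60.0 or h.evalue < 0.001]
    return good[:n_max]


def build_template_stack(
    templates: list[tuple[TemplateHit, BackboneStructure]],
    query_length: int,
    n_max: int = 10,
    spec: GeometrySpec = DEFAULT_SPEC,
):
    """Filter hits, encode each good template, and stack the results.

    Returns a :class:`~trxgeom.template_attention.TemplateFeatureStack`
    with N <= ``n_max`` templates; N = 0 (empty stack) signals FM-only mode.
    """
    from trxgeom.template_attention import TemplateFeatureStack

    by_id = {hit.template_id: structure for hit, structure in templates}
    good = filter_and_rank_templates([h for h, _ in templates], n_max)
    feats, s_pairs = [], []
    for hit in good:
        structure = by_id[hit.template_id]
        labels = bin_geometries(compute_geometries(structure), spec)
        f, s = encode_template(labels, hit, query_length, spec)
        feats.append(f)
        s_pairs.append(s)
    if not feats:
        return TemplateFeatureStack(
            features=np.zeros((0, query_length, query_length,
                               spec.n_template_channels)),
            s_pair=np.zeros((0, query_length, query_length)),
        )
    return TemplateFeatureStack(
        features=np.stack(feats), s_pair=np.stack(s_pairs)
    )


def labels_to_posterior(labels: dict[str, np.ndarray], eps: float = 0.01,
                        spec: GeometrySpec = DEFAULT_SPEC):
    """Smoothed one-hot posterior from label maps (1-eps on the label bin,
    eps spread uniformly).  Used to treat a template as an oracle predictor."""
    from trxgeom.containers import GeometryPosterior

    def smooth(lab: np.ndarray, nb: int) -> np.ndarray:
        out = np.full(lab.shape + (nb,), eps / nb)
        idx_i, idx_j = np.meshgrid(
            np.arange(lab.shape[0]), np.arange(lab.shape[1]), indexing="ij"
        )
        out[idx_i, idx_j, lab] += 1.0 - eps
        return out

    return GeometryPosterior(
        dist=smooth(labels["dist"], spec.n_dist_bins),
        omega=smooth(labels["omega"], spec.n_omega_bins),
        theta=smooth(labels["theta"], spec.n_theta_bins),
        phi=smooth(labels["phi"], spec.n_phi_bins),
    )
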