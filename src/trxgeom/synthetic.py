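"""Synthetic fixtures: toy backbones, covariation-bearing MSAs, noisy templates.

Every stage of the pipeline (feature engineering, training, template
encoding, fusion, realization) can run on these fixtures without any
external data.  The generator emulates three properties of real inputs:

* compact self-avoiding backbones with many long-range contacts;
* alignments whose contacting columns co-vary through class-preserving
  joint substitutions, so inverse-covariance couplings are learnable;
* templates that are noisy, partially covering copies of the target with
  per-position confidences.

It makes no claim of physical realism (no force field, no phylogeny).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from trxgeom.alphabet import AA
from trxgeom.containers import MSA, BackboneStructure, GeometryMaps, TemplateHit
from trxgeom.geometry_spec import DEFAULT_SPEC, GeometrySpec
from trxgeom.template_geometry import (
    bin_geometries,
    compute_geometries,
    virtual_cbeta,
)

# Eight residue classes used for class-preserving covariation.
RESIDUE_CLASSES = (
    "AV",    # small hydrophobic
    "ILM",   # large hydrophobic
    "FWY",   # aromatic
    "KRH",   # positive
    "DE",    # negative
    "STNQ",  # polar
    "CP",    # special
    "G",     # glycine
)
# Compatibility pairing between classes: joint substitutions at a contacting
# column pair draw class c for one side and PARTNER[c] for the other.
PARTNER = (1, 0, 3, 2, 5, 4, 7, 6)

_CLASS_OF = {}
for ci, members in enumerate(RESIDUE_CLASSES):
    for aa in members:
        _CLASS_OF[aa] = ci


@dataclass
class SyntheticTarget:
    """A generated protein: backbone, MSA, templates, and true geometry."""

    name: str
    backbone: BackboneStructure
    msa: MSA
    templates: list[tuple[TemplateHit, BackboneStructure]]
    geometry: GeometryMaps
    labels: dict[str, np.ndarray] = field(repr=False, default=None)

    @property
    def length(self) -> int:
        return len(self.backbone)


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

_CA_STEP = 3.8
_MIN_NONLOCAL = 3.5


def _random_sequence(L: int, rng: np.random.Generator) -> str:
    # mild glycine rate so virtual-CB handling is exercised
    letters = []
    for _ in range(L):
        if rng.random() < 0.05:
            letters.append("G")
        else:
            letters.append(AA[rng.integers(0, 20)])
    return "".join(letters)


def _ca_walk(L: int, radius: float, rng: np.random.Generator
             ) -> np.ndarray | None:
    """One attempt at a confined self-avoiding CA walk; None on failure."""
    coords = np.zeros((L, 3))
    coords[0] = rng.normal(0.0, radius / 4.0, size=3)
    for i in range(1, L):
        placed = False
        for _ in range(60):
            direction = rng.normal(size=3)
            # inward bias keeps the chain compact near the boundary
            r = np.linalg.norm(coords[i - 1])
            if r > 0:
                direction -= 1.2 * (r / radius) ** 2 * coords[i - 1] / r
            direction /= np.linalg.norm(direction)
            cand = coords[i - 1] + _CA_STEP * direction
            if np.linalg.norm(cand) > radius:
                continue
            if i >= 3:
                d = np.linalg.norm(coords[:i - 2] - cand, axis=1)
                if d.min() < _MIN_NONLOCAL:
                    continue
            coords[i] = cand
            placed = True
            break
        if not placed:
            return None
    return coords


def _frames_to_backbone(ca: np.ndarray, sequence: str) -> BackboneStructure:
    """Place N, C (ideal bond lengths, ~111 deg N-CA-C) and CB from frames."""
    L = ca.shape[0]
    n = np.zeros((L, 3))
    c = np.zeros((L, 3))
    cb = np.full((L, 3), np.nan)
    theta = np.radians(111.0)
    for i in range(L):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[i] - ca[i + 1]
        next_dir = ca[i + 1] - ca[i] if i < L - 1 else ca[i] - ca[i - 1]
        u = prev_dir / np.linalg.norm(prev_dir)
        perp = np.cross(u, next_dir)
        if np.linalg.norm(perp) < 1e-6:
            helper = np.array([1.0, 0.0, 0.0])
            if abs(u @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            perp = np.cross(u, helper)
        v = perp / np.linalg.norm(perp)
        n[i] = ca[i] - 1.458 * u
        c[i] = ca[i] + 1.525 * (np.cos(theta) * (-u) + np.sin(theta) * v)
        if sequence[i] != "G":
            cb[i] = virtual_cbeta(n[i], ca[i], c[i])
    return BackboneStructure(
        residue_index=np.arange(1, L + 1),
        sequence=sequence,
        n=n, ca=ca, c=c, cb=cb,
    )


def count_long_range_contacts(structure: BackboneStructure,
                              cutoff: float = 8.0, min_sep: int = 12) -> int:
    maps = compute_geometries(structure)
    iu, ju = np.triu_indices(len(structure), k=min_sep)
    return int(((maps.d[iu, ju] < cutoff) & maps.mask[iu, ju]).sum())


def gen_backbone(L: int, rng: np.random.Generator,
                 max_attempts: int = 200) -> BackboneStructure:
    """Compact self-avoiding backbone with 3.8 A CA steps.

    Regenerates until the fold is compact (at least 2L pairs with
    d < 8 A and |i - j| >= 12); raises after ``max_attempts`` failures,
    which suggests trying a smaller L.
    """
    if L < 8:
        raise ValueError("need L >= 8")
    radius = 3.1 * L ** (1.0 / 3.0)
    # compactness bar: 2L long-range contacts, capped by what the chain
    # length makes geometrically possible (short chains have few pairs
    # with separation >= 12)
    n_eligible = max(0, (L - 12) * (L - 11) // 2)
    required = min(2 * L, int(0.4 * n_eligible))
    for _ in range(max_attempts):
        ca = _ca_walk(L, radius, rng)
        if ca is None:
            continue
        structure = _frames_to_backbone(ca, _random_sequence(L, rng))
        if count_long_range_contacts(structure) >= required:
            return structure
    raise RuntimeError(
        f"could not generate a compact backbone of length {L}; try smaller L"
    )


# ---------------------------------------------------------------------------
# MSAs with planted covariation
# ---------------------------------------------------------------------------

def contacting_column_pairs(structure: BackboneStructure,
                            cutoff: float = 8.0, min_sep: int = 6,
                            rng: np.random.Generator | None = None
                            ) -> list[tuple[int, int]]:
    """Disjoint contacting column pairs (greedy matching, random order)."""
    maps = compute_geometries(structure)
    L = len(structure)
    iu, ju = np.triu_indices(L, k=min_sep)
    keep = (maps.d[iu, ju] < cutoff) & maps.mask[iu, ju]
    pairs = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    if rng is not None:
        order = rng.permutation(len(pairs))
        pairs = [pairs[k] for k in order]
    used: set[int] = set()
    matched = []
    for i, j in pairs:
        if i in used or j in used:
            continue
        matched.append((i, j))
        used.update((i, j))
    return matched


def gen_msa(structure: BackboneStructure, n_rows: int,
            coupling_strength: float = 0.9, gap_rate: float = 0.05,
            rng: np.random.Generator | None = None,
            mutation_rate: float = 0.35) -> MSA:
    """Alignment whose contacting columns co-vary; row 0 is the target.

    Coupled column pairs (contacts with |i-j| >= 6, greedily matched so each
    column joins at most one pair) are jointly substituted with probability
    ``coupling_strength`` per row: one side draws a random residue class,
    the other its compatibility partner.  All other positions mutate
    independently at ``mutation_rate``; gaps are sprinkled at ``gap_rate``
    into non-query rows.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    rng = rng or np.random.default_rng(0)
    L = len(structure)
    query = structure.sequence
    pairs = contacting_column_pairs(structure, rng=rng)
    coupled_cols = {c for p in pairs for c in p}

    rows = [query]
    ids = ["query"]
    for r in range(1, n_rows):
        s = list(query)
        for i, j in pairs:
            if rng.random() < coupling_strength:
                ci = rng.integers(0, len(RESIDUE_CLASSES))
                cj = PARTNER[ci]
                s[i] = RESIDUE_CLASSES[ci][rng.integers(0, len(RESIDUE_CLASSES[ci]))]
                s[j] = RESIDUE_CLASSES[cj][rng.integers(0, len(RESIDUE_CLASSES[cj]))]
            else:
                for c in (i, j):
                    if rng.random() < mutation_rate:
                        s[c] = AA[rng.integers(0, 20)]
        for c in range(L):
            if c in coupled_cols:
                continue
            if rng.random() < mutation_rate:
                s[c] = AA[rng.integers(0, 20)]
        for c in range(L):
            if rng.random() < gap_rate:
                s[c] = "-"
        rows.append("".join(s))
        ids.append(f"seq{r}")
    return MSA(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def gen_templates(structure: BackboneStructure, noise_sd: float = 0.5,
                  coverage: float = 1.0, n_templates: int = 1,
                  rng: np.random.Generator | None = None,
                  good: bool = True
                  ) -> list[tuple[TemplateHit, BackboneStructure]]:
    """Noisy partial copies of the target as template hits.

    Each template covers one contiguous segment of ``ceil(coverage * L)``
    residues with identity alignment, Gaussian coordinate noise of
    ``noise_sd`` A, uniform confidence exp(-noise_sd), and scores chosen to
    pass (or fail, with ``good=False``) the good-template filter.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if n_templates < 1:
        raise ValueError("need at least one template")
    rng = rng or np.random.default_rng(0)
    L = len(structure)
    m = int(np.ceil(coverage * L))
    conf = float(np.exp(-noise_sd))
    out = []
    for t in range(n_templates):
        start = int(rng.integers(0, L - m + 1)) if m < L else 0
        sl = slice(start, start + m)

        def noisy(arr: np.ndarray) -> np.ndarray:
            seg = arr[sl].copy()
            present = ~np.isnan(seg).any(axis=1)
            if noise_sd > 0:
                seg[present] += rng.normal(0.0, noise_sd,
                                           size=(present.sum(), 3))
            return seg

        tmpl = BackboneStructure(
            residue_index=np.arange(1, m + 1),
            sequence=structure.sequence[sl],
            n=noisy(structure.n),
            ca=noisy(structure.ca),
            c=noisy(structure.c),
            cb=noisy(structure.cb),
        )
        pairs = [(start + k + 1, k + 1) for k in range(m)]
        hit = TemplateHit(
            template_id=f"tmpl{t}",
            probability=90.0 if good else 30.0,
            evalue=1e-6 if good else 0.5,
            aligned_pairs=pairs,
            confidence={start + k + 1: conf for k in range(m)},
        )
        out.append((hit, tmpl))
    return out


# ---------------------------------------------------------------------------
# Full targets
# ---------------------------------------------------------------------------

def make_target(L: int = 48, depth: int | None = None, seed: int = 0,
                coupling_strength: float = 0.9, gap_rate: float = 0.05,
                n_templates: int = 0, template_noise: float = 0.5,
                template_coverage: float = 1.0,
                spec: GeometrySpec = DEFAULT_SPEC,
                name: str | None = None) -> SyntheticTarget:
    """One synthetic target with MSA, optional templates and true labels.

    MSA depth defaults to a draw from the fixture range [30, 200].
    """
    rng = np.random.default_rng(seed)
    backbone = gen_backbone(L, rng)
    if depth is None:
        depth = int(rng.integers(30, 201))
    msa = gen_msa(backbone, depth, coupling_strength, gap_rate, rng)
    templates = (
        gen_templates(backbone, template_noise, template_coverage,
                      n_templates, rng)
        if n_templates else []
    )
    geometry = compute_geometries(backbone)
    labels = bin_geometries(geometry, spec)
    return SyntheticTarget(
        name=name or f"target{seed}",
        backbone=backbone,
        msa=msa,
        templates=templates,
        geometry=geometry,
        labels=labels,
    )


def make_dataset(n: int, L: int = 48, seed: int = 0,
                 **kwargs) -> list[SyntheticTarget]:
    """n targets with decorrelated per-target seeds derived from ``seed``."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    out = []
    for k, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        out.append(make_target(L=L, seed=sub_seed, name=f"target{k}", **kwargs))
    return out
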