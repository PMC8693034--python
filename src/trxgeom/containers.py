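"""Core in-memory containers for the geometry-prediction pipeline.

Residue numbering convention: 1-based at every file boundary (PDB, hit
tables), 0-based in every in-memory array.  The conversion happens exactly
once, inside :mod:`trxgeom.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from trxgeom import alphabet


@dataclass
class MSA:
    """A multiple sequence alignment; row 0 is the query.

    All rows share the query length L and are drawn from the 20 amino acids,
    the gap '-', and wildcard letters (treated as gap in statistics).
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        L = len(self.rows[0])
        if L < 1:
            raise ValueError("query row is empty")
        for name, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"row {name!r} has length {len(row)}, query has {L}"
                )

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[0]

    def encoded(self) -> np.ndarray:
        """(N_seq, L) integer states; gap/wildcards share the gap state."""
        return alphabet.encode_msa(self.rows)

    def subset(self, indices: np.ndarray | list[int]) -> "MSA":
        return MSA(
            ids=[self.ids[i] for i in indices],
            rows=[self.rows[i] for i in indices],
        )

    def take_columns(self, cols: np.ndarray | list[int]) -> "MSA":
        return MSA(
            ids=list(self.ids),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )


@dataclass
class BackboneStructure:
    """Backbone coordinates (N, CA, C, CB) of a single protein chain.

    Missing atoms (e.g. CB of glycine) are NaN rows.  CA is guaranteed
    present for every modeled residue.
    """

    residue_index: np.ndarray  # (L,) original 1-based residue numbers
    sequence: str              # one-letter codes, 'X' for unknown
    n: np.ndarray              # (L, 3)
    ca: np.ndarray             # (L, 3)
    c: np.ndarray              # (L, 3)
    cb: np.ndarray             # (L, 3); NaN where absent

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name in ("n", "ca", "c", "cb"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L, 3):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(L, 3)}")
            setattr(self, name, arr)
        if np.isnan(self.ca).any():
            raise ValueError("CA must be present for every residue")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TemplateHit:
    """One template hit: global scores plus a gapped local alignment.

    ``aligned_pairs`` holds 1-based (query_pos, template_pos) pairs, strictly
    increasing in both coordinates.  ``confidence`` maps 1-based query
    positions to per-position confidences s_k(i) in [0, 1].
    """

    template_id: str
    probability: float           # percent, in [0, 100]
    evalue: float                # >= 0
    aligned_pairs: list[tuple[int, int]]
    confidence: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 100.0:
            raise ValueError(
                f"hit {self.template_id!r}: probability {self.probability} "
                "outside [0, 100]"
            )
        if self.evalue < 0:
            raise ValueError(
                f"hit {self.template_id!r}: negative E-value {self.evalue}"
            )
        prev_q = prev_t = 0
        for q, t in self.aligned_pairs:
            if q <= prev_q or t <= prev_t:
                raise ValueError(
                    f"hit {self.template_id!r}: aligned pairs not strictly "
                    "increasing in both coordinates"
                )
            prev_q, prev_t = q, t


@dataclass
class GeometryMaps:
    """Real-valued pairwise geometry: d (A), omega/theta (deg, [-180,180)),
    phi (deg, [0,180]), plus a validity mask.

    d and omega are symmetric by construction; theta and phi are generally
    asymmetric because their atom quadruples are ordered.
    """

    d: np.ndarray       # (L, L)
    omega: np.ndarray   # (L, L)
    theta: np.ndarray   # (L, L)
    phi: np.ndarray     # (L, L)
    mask: np.ndarray    # (L, L) bool; False where any needed atom is missing


HEAD_BINS = {"dist": 37, "omega": 25, "theta": 25, "phi": 13}


@dataclass
class GeometryPosterior:
    """Four per-pair categorical distributions (37/25/25/13 bins)."""

    dist: np.ndarray    # (L, L, 37)
    omega: np.ndarray   # (L, L, 25)
    theta: np.ndarray   # (L, L, 25)
    phi: np.ndarray     # (L, L, 13)

    def __post_init__(self) -> None:
        L = self.dist.shape[0]
        for name, nb in HEAD_BINS.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L, L, nb):
                raise ValueError(
                    f"{name} head has shape {arr.shape}, expected {(L, L, nb)}"
                )
            setattr(self, name, arr)

    @property
    def length(self) -> int:
        return self.dist.shape[0]

    def heads(self) -> dict[str, np.ndarray]:
        return {
            "dist": self.dist,
            "omega": self.omega,
            "theta": self.theta,
            "phi": self.phi,
        }

    def check_normalized(self, atol: float = 1e-4) -> None:
        """Raise if any head is not a proper categorical distribution."""
        for name, arr in self.heads().items():
            if np.isnan(arr).any():
                raise ValueError(f"{name} head contains NaN")
            if (arr < 0).any():
                raise ValueError(f"{name} head contains negative probabilities")
            sums = arr.sum(axis=-1)
            if np.abs(sums - 1.0).max() > atol:
                raise ValueError(
                    f"{name} head pixel sums deviate from 1 by up to "
                    f"{np.abs(sums - 1.0).max():.3g} (tolerance {atol})"
                )
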