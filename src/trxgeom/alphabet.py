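"""The 21-state residue alphabet shared by all statistics.

Twenty standard amino acids plus the gap state.  Wildcard residues
(X, B, Z, J, O, U) are carried through file I/O unchanged but are counted as
gap in every frequency statistic, so they never inflate a 22nd state.
"""

from __future__ import annotations

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
GAP_STATE = 20
N_STATES = 21  # 20 amino acids + gap

WILDCARDS = set("XBZJOU")
_LEGAL = set(AA) | {GAP} | WILDCARDS

AA_INDEX = {a: i for i, a in enumerate(AA)}


def is_legal(ch: str) -> bool:
    return ch in _LEGAL


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer states; gap and wildcards -> GAP_STATE."""
    return np.asarray([AA_INDEX.get(c, GAP_STATE) for c in seq], dtype=np.int64)


def encode_msa(rows: list[str]) -> np.ndarray:
    """(N_seq, L) integer state matrix for an aligned set of rows."""
    return np.stack([encode_sequence(r) for r in rows])
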