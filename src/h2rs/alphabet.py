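"""Residue alphabet and ordered-pair state coding.

Pair states are the 400 ordered amino-acid pairs. The code of the pair
(r, u) — residue r at the first column, u at the second — is
``20 * index(r) + index(u)`` with residues ordered alphabetically by
one-letter code (A=0 … Y=19).
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: The 400 two-letter pair codes "AA", "AC", …, "YY" in canonical order.
PAIR_CODES: list[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]

GAP_CHARS: str = "-."
AMBIGUITY_CHARS: str = "BZXJUO"
ALLOWED_CHARS: frozenset[str] = frozenset(AMINO_ACIDS + "-" + AMBIGUITY_CHARS)

N_PAIR_STATES: int = 400

# Lookup from character ordinal to canonical residue index, -1 otherwise.
_CHAR_TO_CODE = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _CHAR_TO_CODE[ord(_aa)] = _i


def pair_code(first: str, second: str) -> int:
    """Canonical index of the ordered residue pair ``(first, second)``."""
    return 20 * AA_INDEX[first] + AA_INDEX[second]


def decode_pair(code: int) -> tuple[str, str]:
    """Inverse of :func:`pair_code`."""
    return AMINO_ACIDS[code // 20], AMINO_ACIDS[code % 20]


def encode_residues(chars: str) -> np.ndarray:
    """Encode a residue string as canonical indices (-1 for gap/ambiguity)."""
    raw = np.frombuffer(chars.encode("ascii"), dtype=np.uint8)
    return _CHAR_TO_CODE[raw].copy()


def swap_pair_permutation() -> np.ndarray:
    """Permutation of pair codes mapping (r, u) -> (u, r)."""
    idx = np.arange(N_PAIR_STATES)
    return 20 * (idx % 20) + idx // 20
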