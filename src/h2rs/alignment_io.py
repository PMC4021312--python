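"""Reading, validating and filtering multiple sequence alignments.

Columns are 1-based in every public function signature and in all files the
package writes; internally the alignment is a 0-based integer matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from .alphabet import ALLOWED_CHARS, N_PAIR_STATES, encode_residues
from .errors import AlignmentFormatError, AlphabetError, DegenerateColumnError

_FORMATS = {"fasta": "fasta", "stockholm": "stockholm"}


class Alignment:
    """An in-memory multiple sequence alignment.

    Rows are upper-case strings over the 20 canonical residues, the gap
    symbol '-' and the ambiguity codes B, Z, X, J, U, O. All rows share the
    same length ``L``; ``M`` is the number of sequences.
    """

    def __init__(self, ids: list[str], rows: list[str]):
        if len(ids) != len(rows):
            raise AlignmentFormatError("ids and rows differ in length")
        if len(rows) == 0:
            raise AlignmentFormatError("alignment is empty")
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("sequence identifiers are not unique")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        for sid, row in zip(ids, rows):
            for pos, ch in enumerate(row):
                if ch not in ALLOWED_CHARS:
                    raise AlphabetError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {pos + 1}"
                    )
        self.ids: list[str] = list(ids)
        self.rows: list[str] = list(rows)
        self._encoded: np.ndarray | None = None

    @property
    def M(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def usable(self) -> bool:
        """Whether the alignment is deep enough for correlation analysis."""
        return self.M >= 2

    def encoded(self) -> np.ndarray:
        """(M, L) int8 matrix of canonical residue indices, -1 elsewhere."""
        if self._encoded is None:
            self._encoded = np.vstack([encode_residues(r) for r in self.rows])
        return self._encoded

    def column(self, k: int) -> str:
        """Residue string of 1-based column ``k``."""
        return "".join(row[k - 1] for row in self.rows)

    def subset(self, indices: list[int]) -> "Alignment":
        """Row subset in the given order."""
        return Alignment([self.ids[i] for i in indices],
                         [self.rows[i] for i in indices])

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment(M={self.M}, L={self.L})"


@dataclass
class ColumnPairDistribution:
    """Joint residue-pair distribution of two alignment columns.

    ``p`` holds the 400 ordered-pair probabilities in canonical pair-code
    order; only sequences with a canonical residue at BOTH columns
    contribute (``n_valid`` of them).
    """

    k: int
    l: int
    p: np.ndarray
    n_valid: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_PAIR_STATES,):
            raise ValueError("p must have 400 entries")
        if self.n_valid > 0:
            if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
                raise ValueError("p must be a probability vector")

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        """Single-column distributions (first, second) over 20 residues."""
        joint = self.p.reshape(20, 20)
        return joint.sum(axis=1), joint.sum(axis=0)


def normalize_row(row: str) -> str:
    """Upper-case a row and map '.' gaps to '-'."""
    return row.upper().replace(".", "-")


def read_msa(path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Lower-case residues are upper-cased and '.' gaps normalized to '-'.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        records = list(AlignIO.read(str(path), _FORMATS[format]))
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise AlignmentFormatError(f"no sequences in {path}")
    aln = Alignment([r.id for r in records],
                    [normalize_row(str(r.seq)) for r in records])
    if not aln.usable:
        raise AlignmentFormatError("alignment must contain at least 2 sequences")
    return aln


def write_msa(aln: Alignment, path) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical residues between two aligned rows.

    The denominator counts columns where at least one row has a non-gap
    character; a gap aligned to a residue is a mismatch, dual-gap columns
    are ignored. Returns 0 when no column qualifies.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    a = np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)
    gap = ord("-")
    both_gap = (a == gap) & (b == gap)
    denom = int((~both_gap).sum())
    if denom == 0:
        return 0.0
    matches = int(((a == b) & ~both_gap).sum())
    return matches / denom


def _identity_matrix(aln: Alignment) -> np.ndarray:
    """All-against-all pairwise identity (vectorized over columns)."""
    raw = np.vstack([
        np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in aln.rows
    ])
    gap = raw == ord("-")
    m = aln.M
    ident = np.ones((m, m))
    for i in range(m):
        eq = raw[i][None, :] == raw
        both_gap = gap[i][None, :] & gap
        denom = (~both_gap).sum(axis=1)
        matches = (eq & ~both_gap).sum(axis=1)
        with np.errstate(invalid="ignore"):
            ident[i] = np.where(denom > 0, matches / np.maximum(denom, 1), 0.0)
    return ident


def filter_by_identity(aln: Alignment, min_id: float = 0.20,
                       max_id: float = 0.90) -> Alignment:
    """Remove sequences until all pairwise identities lie in [min_id, max_id].

    Ordered pairs (r, s), r < s, are scanned in input order; on a violation
    the later sequence s is removed and the scan restarts, which makes the
    reduction deterministic. Original row order is preserved.
    """
    if aln.M < 2:
        raise ValueError("need at least 2 sequences to filter")
    ident = _identity_matrix(aln)
    alive = list(range(aln.M))
    changed = True
    while changed and len(alive) > 1:
        changed = False
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                v = ident[alive[ai], alive[bi]]
                if v < min_id or v > max_id:
                    del alive[bi]
                    changed = True
                    break
            if changed:
                break
    result = aln.subset(alive)
    if result.M < 2:
        warnings.warn(
            "identity filtering left fewer than 2 sequences; "
            "alignment is unusable for correlation analysis",
            stacklevel=2,
        )
    return result


def column_pair_frequencies(aln: Alignment, k: int, l: int) -> ColumnPairDistribution:
    """Joint pair distribution of 1-based columns ``k`` and ``l``.

    Sequences with a gap or ambiguity code at either column are excluded
    and the probabilities renormalized over the canonical 400 pair states.
    """
    if not (1 <= k <= aln.L and 1 <= l <= aln.L):
        raise ValueError(f"columns must lie in [1, {aln.L}]")
    enc = aln.encoded()
    ck, cl = enc[:, k - 1].astype(np.int64), enc[:, l - 1].astype(np.int64)
    valid = (ck >= 0) & (cl >= 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegenerateColumnError(
            f"no sequence has canonical residues at both columns {k} and {l}"
        )
    codes = 20 * ck[valid] + cl[valid]
    counts = np.bincount(codes, minlength=N_PAIR_STATES)
    return ColumnPairDistribution(k=k, l=l, p=counts / n_valid, n_valid=n_valid)
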