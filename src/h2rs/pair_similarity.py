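"""Construction of the 400x400 pair-similarity matrix A.

A scores how exchangeable two ordered residue pairs are. It is built
BLOSUM-style: residue pairs in 3D contact are linked to their MSA columns,
substitutions between sequence pairs are counted into f(i, j), and each
entry is normalized as

    a_ij = f(i, j) / sqrt(f(i, i) f(j, j))

which yields a symmetric matrix with unit diagonal that is positive
semi-definite up to sampling noise (repaired by eigenvalue clipping).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .alignment_io import Alignment
from .alphabet import AMINO_ACIDS, N_PAIR_STATES, PAIR_CODES
from .errors import AnnotationError, MatrixConstructionError, MatrixValidationError

_SYM_TOL = 1e-9
_PSD_TOL = 1e-8


@dataclass
class ContactPair:
    """A residue pair of one chain whose closest heavy atoms are within cutoff."""

    chain: str
    k: int
    l: int
    distance: float
    cutoff: float

    def __post_init__(self):
        if self.k >= self.l:
            raise ValueError("contact requires k < l")
        if not (0.0 < self.distance <= self.cutoff):
            raise ValueError("distance must lie in (0, cutoff]")


@dataclass
class PairSubstitutionCounts:
    """Symmetric 400x400 table of pair-substitution counts f(i, j)."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_PAIR_STATES, N_PAIR_STATES))
    )

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def merge(self, other: "PairSubstitutionCounts") -> None:
        self.counts += other.counts


class SimilarityMatrix:
    """The validated 400x400 pair-similarity matrix A."""

    def __init__(self, values: np.ndarray, metadata: dict | None = None,
                 validated: bool = False):
        self.values = np.asarray(values, dtype=float)
        self.metadata = dict(metadata or {})
        self._validated = validated

    @classmethod
    def identity(cls) -> "SimilarityMatrix":
        return cls(np.eye(N_PAIR_STATES), {"source": "identity"}, validated=True)

    def validate(self) -> "SimilarityMatrix":
        if not self._validated:
            _validate_values(self.values)
            self._validated = True
        return self

    def permuted(self, permutation: np.ndarray) -> "SimilarityMatrix":
        """Row/column permutation of A (e.g. the pair-code swap)."""
        v = self.values[np.ix_(permutation, permutation)]
        return SimilarityMatrix(v, self.metadata, validated=self._validated)


def _validate_values(values: np.ndarray) -> None:
    if values.shape != (N_PAIR_STATES, N_PAIR_STATES):
        raise MatrixValidationError(
            f"similarity matrix must be 400x400, got {values.shape}"
        )
    asym = np.abs(values - values.T)
    if asym.max() > _SYM_TOL:
        i, j = np.unravel_index(int(asym.argmax()), asym.shape)
        raise MatrixValidationError(
            f"asymmetric at ({PAIR_CODES[i]}, {PAIR_CODES[j]}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    diag = np.diag(values)
    bad = np.flatnonzero(np.abs(diag - 1.0) > 1e-9)
    if bad.size:
        raise MatrixValidationError(
            f"diagonal entry {PAIR_CODES[bad[0]]} = {diag[bad[0]]!r}, expected 1"
        )
    out = (values < -1e-12) | (values > 1.0 + 1e-12)
    if out.any():
        i, j = np.argwhere(out)[0]
        raise MatrixValidationError(
            f"value at ({PAIR_CODES[i]}, {PAIR_CODES[j]}) = {values[i, j]!r} "
            "outside [0, 1]"
        )
    lam_min = float(np.linalg.eigvalsh(values).min())
    if lam_min < -_PSD_TOL:
        raise MatrixValidationError(
            f"matrix is not positive semi-definite (min eigenvalue {lam_min:.3e})"
        )


# ---------------------------------------------------------------------------
# contact extraction

def _heavy_protein_atoms(structure: struc.AtomArray) -> struc.AtomArray:
    mask = (
        struc.filter_amino_acids(structure)
        & ~structure.hetero
        & (structure.element != "H")
    )
    return structure[mask]


def extract_contacts(structure: struc.AtomArray, cutoff_A: float = 5.0,
                     min_seq_sep: int = 0) -> list[ContactPair]:
    """Residue pairs whose minimal heavy-atom distance is within ``cutoff_A``.

    Only intra-chain pairs (k < l, l - k > min_seq_sep) are reported;
    hydrogens, waters and hetero groups are excluded.
    """
    atoms = _heavy_protein_atoms(structure)
    if atoms.array_length() == 0:
        raise AnnotationError("structure contains no protein chain")
    contacts: list[ContactPair] = []
    for chain_id in np.unique(atoms.chain_id):
        chain = atoms[atoms.chain_id == chain_id]
        res_ids = np.unique(chain.res_id)
        coords = chain.coord
        if np.isnan(coords).any():
            ok = ~np.isnan(coords).any(axis=1)
            skipped = np.unique(chain.res_id[~ok])
            warnings.warn(
                f"chain {chain_id}: residues {skipped.tolist()} have missing "
                "coordinates and were skipped", stacklevel=2,
            )
            chain, coords = chain[ok], coords[ok]
        ridx = np.searchsorted(res_ids, chain.res_id)
        n_res = res_ids.size
        diff = coords[:, None, :] - coords[None, :, :]
        dmat = np.sqrt((diff * diff).sum(axis=-1))
        min_d = np.full((n_res, n_res), np.inf)
        n_at = coords.shape[0]
        flat_i = np.repeat(ridx, n_at)
        flat_j = np.tile(ridx, n_at)
        np.minimum.at(min_d, (flat_i, flat_j), dmat.ravel())
        for a in range(n_res):
            for b in range(a + 1, n_res):
                if res_ids[b] - res_ids[a] <= min_seq_sep:
                    continue
                if min_d[a, b] <= cutoff_A:
                    contacts.append(ContactPair(
                        chain=str(chain_id), k=int(res_ids[a]), l=int(res_ids[b]),
                        distance=float(min_d[a, b]), cutoff=cutoff_A,
                    ))
    return contacts


# ---------------------------------------------------------------------------
# substitution counting and Eq.-style normalization

def count_pair_substitutions(aln: Alignment,
                             contact_columns: list[tuple[int, int]],
                             counts: PairSubstitutionCounts | None = None,
                             ) -> PairSubstitutionCounts:
    """Accumulate pair-substitution counts f(i, j) over contacting columns.

    For each contact column pair (1-based) and each unordered pair of
    sequences, the two observed residue pairs i and j increment f(i, j)
    and f(j, i) (once each; identical pairs increment the diagonal once).
    Observations involving a gap or ambiguity code are skipped.
    """
    result = counts if counts is not None else PairSubstitutionCounts()
    enc = aln.encoded().astype(np.int64)
    for k, l in contact_columns:
        if not (1 <= k <= aln.L and 1 <= l <= aln.L):
            raise ValueError(f"contact columns ({k}, {l}) outside alignment")
        ck, cl = enc[:, k - 1], enc[:, l - 1]
        valid = (ck >= 0) & (cl >= 0)
        codes = 20 * ck[valid] + cl[valid]
        for i, j in itertools.combinations(codes, 2):
            result.counts[i, j] += 1
            if i != j:
                result.counts[j, i] += 1
    return result


def normalize_similarity(counts: PairSubstitutionCounts,
                         metadata: dict | None = None) -> SimilarityMatrix:
    """a_ij = f(i,j)/sqrt(f(i,i) f(j,j)), with PSD repair.

    Entries whose diagonal counts vanish carry no evidence and are set to
    0; the diagonal is forced to 1; the matrix is symmetrized by
    averaging, clipped to [0, 1] and, if sampling noise produced negative
    eigenvalues, repaired by clipping the spectrum at 0 and re-normalizing
    the diagonal back to 1.
    """
    f = counts.counts
    if counts.total <= 0:
        raise MatrixConstructionError("no substitution counts observed")
    diag = np.diag(f).copy()
    denom = np.sqrt(np.outer(diag, diag))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, f / np.where(denom > 0, denom, 1.0), 0.0)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    a = np.clip(a, 0.0, 1.0)
    a = _psd_repair(a)
    meta = {"n_observations": counts.total, **(metadata or {})}
    return SimilarityMatrix(a, meta).validate()


def _psd_repair(a: np.ndarray) -> np.ndarray:
    lam, vec = np.linalg.eigh(a)
    if lam.min() >= 0.0:
        return a
    lam = np.clip(lam, 0.0, None)
    repaired = (vec * lam) @ vec.T
    d = np.diag(repaired).copy()
    # a state annihilated by the repair keeps a unit self-similarity
    d[d <= 0] = 1.0
    scale = 1.0 / np.sqrt(d)
    repaired = scale[:, None] * repaired * scale[None, :]
    repaired = np.clip(0.5 * (repaired + repaired.T), 0.0, 1.0)
    np.fill_diagonal(repaired, 1.0)
    return repaired


# ---------------------------------------------------------------------------
# serialization (tab-separated, 401x401 with pair-code labels)

def save_matrix(A: SimilarityMatrix, path) -> None:
    """Write A as TSV: '#' metadata lines, then labeled 400x400 values."""
    with open(path, "w") as fh:
        for key, value in A.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t" + "\t".join(PAIR_CODES) + "\n")
        for i, code in enumerate(PAIR_CODES):
            row = "\t".join(repr(float(v)) for v in A.values[i])
            fh.write(f"{code}\t{row}\n")


def load_matrix(path) -> SimilarityMatrix:
    """Load and validate a similarity matrix written by :func:`save_matrix`.

    Also accepts any TSV in the same dialect (pair-labeled rows/columns),
    e.g. a spreadsheet export of an externally published matrix.
    """
    metadata = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = value.strip()
    # keep_default_na: the pair code "NA" is a label, not a missing value
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                        keep_default_na=False)
    if frame.shape != (N_PAIR_STATES, N_PAIR_STATES):
        raise MatrixValidationError(
            f"expected a 400x400 table, got {frame.shape[0]}x{frame.shape[1]}"
        )
    if list(frame.index) != PAIR_CODES or list(frame.columns) != PAIR_CODES:
        raise MatrixValidationError(
            "row/column labels must be the 400 pair codes in canonical order"
        )
    matrix = SimilarityMatrix(frame.to_numpy(dtype=float), metadata)
    matrix.validate()
    return matrix


# ---------------------------------------------------------------------------
# structure -> MSA column mapping and end-to-end construction

def chain_sequence(structure: struc.AtomArray, chain_id: str) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus the matching residue ids."""
    atoms = _heavy_protein_atoms(structure)
    chain = atoms[atoms.chain_id == chain_id]
    if chain.array_length() == 0:
        raise AnnotationError(f"no protein chain {chain_id!r} in structure")
    res_ids, res_names = struc.get_residues(chain)
    letters = []
    kept_ids = []
    for rid, rname in zip(res_ids, res_names):
        try:
            letters.append(bseq.ProteinSequence.convert_letter_3to1(rname.capitalize()))
            kept_ids.append(int(rid))
        except KeyError:
            warnings.warn(f"unknown residue {rname!r} skipped", stacklevel=2)
    return "".join(letters).upper(), kept_ids


def map_contacts_to_columns(contacts: list[ContactPair], structure: struc.AtomArray,
                            aln: Alignment) -> list[tuple[int, int]]:
    """Map structural contacts to 1-based MSA column pairs.

    The chain sequence is globally aligned (BLOSUM62) to the ungapped
    reference (first) row of the MSA; contacts whose residues do not map
    to a reference residue are skipped with a warning.
    """
    ref_row = aln.rows[0]
    ref_seq = ref_row.replace("-", "")
    ref_cols = [i + 1 for i, ch in enumerate(ref_row) if ch != "-"]
    col_of: dict[tuple[str, int], int] = {}
    for chain_id in sorted({c.chain for c in contacts}):
        seq, res_ids = chain_sequence(structure, chain_id)
        mat = balign.SubstitutionMatrix.std_protein_matrix()
        ali = balign.align_optimal(
            bseq.ProteinSequence(seq),
            bseq.ProteinSequence(ref_seq.replace("X", "A")),
            mat, gap_penalty=(-10, -1), terminal_penalty=False,
        )[0]
        for a, b in ali.trace:
            if a >= 0 and b >= 0:
                col_of[(chain_id, res_ids[a])] = ref_cols[b]
    pairs = []
    for c in contacts:
        ck = col_of.get((c.chain, c.k))
        cl = col_of.get((c.chain, c.l))
        if ck is None or cl is None:
            warnings.warn(
                f"contact ({c.chain}, {c.k}, {c.l}) has no MSA mapping; skipped",
                stacklevel=2,
            )
            continue
        pairs.append((min(ck, cl), max(ck, cl)))
    return pairs


def build_matrix(datasets: list[tuple[struc.AtomArray, Alignment]],
                 cutoff_A: float = 5.0, min_seq_sep: int = 0,
                 min_identity: float = 0.20, max_identity: float = 0.90,
                 ) -> SimilarityMatrix:
    """Build A from matched (structure, MSA) pairs.

    Each MSA is identity-filtered, contacts are extracted from the
    structure at ``cutoff_A``, mapped to MSA columns, and substitution
    counts are accumulated over all datasets before normalization.
    """
    from .alignment_io import filter_by_identity

    counts = PairSubstitutionCounts()
    n_contacts = 0
    for structure, aln in datasets:
        filtered = filter_by_identity(aln, min_identity, max_identity)
        if filtered.M < 2:
            continue
        contacts = extract_contacts(structure, cutoff_A, min_seq_sep)
        n_contacts += len(contacts)
        columns = map_contacts_to_columns(contacts, structure, filtered)
        count_pair_substitutions(filtered, columns, counts)
    return normalize_similarity(
        counts,
        {"cutoff_A": cutoff_A, "n_contacts": n_contacts,
         "source": f"{len(datasets)} structure/MSA pairs"},
    )


# ---------------------------------------------------------------------------
# built-in example matrix

_EXAMPLE_CACHE: SimilarityMatrix | None = None


def example_similarity_matrix() -> SimilarityMatrix:
    """A deterministic full-size example A derived from BLOSUM62.

    Single-residue similarities s_rt = 2^((b_rt - (b_rr + b_tt)/2)/2)
    (the BLOSUM log-odds score back-transformed into a normalized
    substitution ratio, clipped to [0, 1] and PSD-repaired) are combined
    into pair-state similarities as the Kronecker product S (x) S, which
    keeps unit diagonal and positive semi-definiteness. It stands in for
    a corpus-built matrix in examples and tests; real analyses should use
    a matrix built from contact data via :func:`build_matrix`.
    """
    global _EXAMPLE_CACHE
    if _EXAMPLE_CACHE is None:
        blosum = balign.SubstitutionMatrix.std_protein_matrix()
        b = np.zeros((20, 20))
        for i, aa in enumerate(AMINO_ACIDS):
            for j, bb in enumerate(AMINO_ACIDS):
                b[i, j] = blosum.get_score(aa, bb)
        s = 2.0 ** ((b - 0.5 * (np.diag(b)[:, None] + np.diag(b)[None, :])) / 2.0)
        s = np.clip(0.5 * (s + s.T), 0.0, 1.0)
        np.fill_diagonal(s, 1.0)
        s = _psd_repair(s)
        values = np.kron(s, s)
        _EXAMPLE_CACHE = SimilarityMatrix(
            values, {"source": "BLOSUM62-derived example (kron)"},
        ).validate()
    return _EXAMPLE_CACHE
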