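"""Seeded synthetic fixtures: alignments, toy structures, matrices.

The MSA generator draws independent background columns from per-column
categorical distributions (random residue subsets with Dirichlet weights,
so conserved, variable and near-degenerate columns all occur) and plants
covarying column pairs: with probability equal to the coupling strength a
row receives a residue pair drawn jointly from the pair vocabulary,
otherwise the two residues are drawn independently from the vocabulary's
marginals. Coupling 1.0 is deterministic pairing, 0.0 independence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .alignment_io import Alignment
from .alphabet import AMINO_ACIDS, N_PAIR_STATES
from .errors import SyntheticSpecError


@dataclass
class PlantedPair:
    """A covarying column pair with its joint residue vocabulary."""

    k: int
    l: int
    coupling: float
    vocabulary: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise SyntheticSpecError("coupling must lie in [0, 1]")
        if self.coupling > 0 and not self.vocabulary:
            raise SyntheticSpecError("non-zero coupling needs a vocabulary")
        for a, b in self.vocabulary:
            if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
                raise SyntheticSpecError(f"non-canonical vocabulary pair {(a, b)}")


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic MSA.

    Background columns use ``alphabet_size_range`` residues (inclusive
    bounds; size 1 yields a conserved column) with Dirichlet(concentration)
    frequencies. ``gap_fraction`` rows per column carry a gap.
    """

    L: int
    M: int
    seed: int
    planted: tuple[PlantedPair, ...] = ()
    alphabet_size_range: tuple[int, int] = (1, 6)
    concentration: float = 1.0
    gap_fraction: float = 0.0

    def __post_init__(self):
        positions = [p for pair in self.planted for p in (pair.k, pair.l)]
        if len(set(positions)) != len(positions):
            raise SyntheticSpecError("planted positions must be distinct")
        for pos in positions:
            if not 1 <= pos <= self.L:
                raise SyntheticSpecError(f"planted position {pos} outside [1, L]")
        lo, hi = self.alphabet_size_range
        if not 1 <= lo <= hi <= 20:
            raise SyntheticSpecError("alphabet sizes must lie in [1, 20]")

    def to_json(self) -> str:
        return json.dumps({
            "L": self.L, "M": self.M, "seed": self.seed,
            "alphabet_size_range": list(self.alphabet_size_range),
            "concentration": self.concentration,
            "gap_fraction": self.gap_fraction,
            "planted": [
                {"k": p.k, "l": p.l, "coupling": p.coupling,
                 "vocabulary": ["".join(v) for v in p.vocabulary]}
                for p in self.planted
            ],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        raw = json.loads(text)
        planted = tuple(
            PlantedPair(
                k=int(p["k"]), l=int(p["l"]), coupling=float(p["coupling"]),
                vocabulary=tuple((v[0], v[1]) for v in p["vocabulary"]),
            )
            for p in raw.get("planted", [])
        )
        return cls(
            L=int(raw["L"]), M=int(raw["M"]), seed=int(raw["seed"]),
            planted=planted,
            alphabet_size_range=tuple(raw.get("alphabet_size_range", (1, 6))),
            concentration=float(raw.get("concentration", 1.0)),
            gap_fraction=float(raw.get("gap_fraction", 0.0)),
        )


def generate_msa(spec: SyntheticSpec) -> Alignment:
    """Draw an alignment from a :class:`SyntheticSpec`, deterministically."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.alphabet_size_range
    columns = np.empty((spec.M, spec.L), dtype="U1")
    for col in range(spec.L):
        size = int(rng.integers(lo, hi + 1))
        residues = rng.choice(list(AMINO_ACIDS), size=size, replace=False)
        weights = rng.dirichlet(np.full(size, spec.concentration))
        columns[:, col] = rng.choice(residues, size=spec.M, p=weights)
    for pair in spec.planted:
        if not pair.vocabulary:
            continue
        vocab = np.array([list(v) for v in pair.vocabulary])
        joint_idx = rng.integers(0, len(vocab), size=spec.M)
        first = vocab[joint_idx, 0]
        second = vocab[joint_idx, 1]
        independent = rng.random(spec.M) >= pair.coupling
        n_ind = int(independent.sum())
        if n_ind:
            first[independent] = vocab[rng.integers(0, len(vocab), n_ind), 0]
            second[independent] = vocab[rng.integers(0, len(vocab), n_ind), 1]
        columns[:, pair.k - 1] = first
        columns[:, pair.l - 1] = second
    if spec.gap_fraction > 0:
        gaps = rng.random((spec.M, spec.L)) < spec.gap_fraction
        columns[gaps] = "-"
    ids = [f"seq{i + 1}" for i in range(spec.M)]
    return Alignment(ids, ["".join(row) for row in columns])


def empirical_coupling(aln: Alignment, pair: PlantedPair) -> float:
    """Estimate the realized coupling of a planted pair.

    The fraction of rows whose residue pair lies in the vocabulary is
    q + c(1 - q) where q is the in-vocabulary mass under independence;
    solving for c gives the estimator.
    """
    vocab = set(pair.vocabulary)
    rows = [(r[pair.k - 1], r[pair.l - 1]) for r in aln.rows]
    frac = sum(1 for rp in rows if rp in vocab) / len(rows)
    firsts = [v[0] for v in pair.vocabulary]
    seconds = [v[1] for v in pair.vocabulary]
    q = sum(
        (firsts.count(a) / len(firsts)) * (seconds.count(b) / len(seconds))
        for a, b in vocab
    )
    if q >= 1.0:
        return 1.0
    return (frac - q) / (1.0 - q)


def generate_toy_structure(n_residues: int, spacing: float = 3.8,
                           sequence: str | None = None) -> struc.AtomArray:
    """Collinear C-alpha chain with ``spacing`` Å between neighbors.

    All inter-residue distances are exact multiples of the spacing, so
    the contact list at any cutoff is known in closed form (see
    :func:`collinear_contacts`). ``sequence`` optionally sets the residue
    types (default poly-alanine).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if sequence is not None and len(sequence) != n_residues:
        raise ValueError("sequence length must match n_residues")
    atoms = struc.AtomArray(n_residues)
    atoms.coord = np.column_stack([
        spacing * np.arange(n_residues),
        np.zeros(n_residues),
        np.zeros(n_residues),
    ]).astype(np.float32)
    atoms.chain_id = np.full(n_residues, "A")
    atoms.res_id = np.arange(1, n_residues + 1)
    if sequence is None:
        atoms.res_name = np.full(n_residues, "ALA")
    else:
        from biotite.sequence import ProteinSequence

        atoms.res_name = np.array([
            ProteinSequence.convert_letter_1to3(ch).upper() for ch in sequence
        ])
    atoms.atom_name = np.full(n_residues, "CA")
    atoms.element = np.full(n_residues, "C")
    atoms.hetero = np.zeros(n_residues, dtype=bool)
    return atoms


def collinear_contacts(n_residues: int, spacing: float, cutoff: float,
                       min_seq_sep: int = 0) -> list[tuple[int, int]]:
    """Ground-truth contacts of the collinear chain (1-based residue ids)."""
    return [
        (k, l)
        for k in range(1, n_residues + 1)
        for l in range(k + 1, n_residues + 1)
        if (l - k) * spacing <= cutoff and (l - k) > min_seq_sep
    ]


def random_pair_distribution(rng: np.random.Generator,
                             max_support: int = 40):
    """A random sparse 400-state pair distribution (for entropy fixtures)."""
    from .alignment_io import ColumnPairDistribution

    size = int(rng.integers(2, max_support + 1))
    support = rng.choice(N_PAIR_STATES, size=size, replace=False)
    weights = rng.dirichlet(np.ones(size))
    p = np.zeros(N_PAIR_STATES)
    p[support] = weights
    p /= p.sum()
    return ColumnPairDistribution(k=1, l=2, p=p, n_valid=size)


def random_similarity_matrix(rng: np.random.Generator, rank: int = 50):
    """A random valid similarity matrix: Gram matrix of non-negative
    factors, normalized to unit diagonal (hence PSD, entries in [0, 1])."""
    from .pair_similarity import SimilarityMatrix

    b = rng.random((N_PAIR_STATES, rank))
    gram = b @ b.T
    d = np.sqrt(np.diag(gram))
    values = gram / np.outer(d, d)
    values = np.clip(0.5 * (values + values.T), 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, {"source": "random Gram"}).validate()
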